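# Methods and numerical notes

## Model definitions

All variants are mass-action coagulation–fragmentation systems truncated
at a maximal size `N`.  A model is specified by two piecewise-constant
kernels: `a[i,j]`, the rate constant at which the pair of sizes `(i, j)`
merges (the channel exists only if `i + j <= N`), and `f[i,j]`, the rate
constant at which an aggregate of size `i + j` splits into parts `i` and
`j`.

**Aggregation model** (3D aggregation in suspension):

```
a[1,1] = k2    a[1,j>1] = k1    a[i>1,j>1] = k_m2
f[1,j] = k_m1  f[i>1,j>1] = k3
```

**Clustering model** (2D receptor clustering; extended Becker–Döring —
only monomers and dimers attach/detach):

```
a[1,j] = k1    a[2,j] = k2    a[i>2,j>2] = 0
f[1,j] = k_m1  f[2,j] = k_m2  f[i>2,j>2] = 0
```

The monomer and dimer rows overlap on the mixed pair `(1, 2)`: that pair
carries two independent coagulation channels (one at `k1`, one at `k2`),
and the size-3 fission into `(1, 2)` carries both a `k_m1` and a `k_m2`
channel.  The self-pair `(1, 1)` belongs to the monomer row (`k1`).

**2-equation model** (reduction; `p` free monomers, `n` pooled
aggregates):

```
dp/dt = -k1*n*p - 2*k2*p^2 + k_m1*n
dn/dt =  k2*p^2 - k_m2*n^2 + k3*n
```

The reduction does not conserve mass exactly; its mean aggregate size
`s = (p0 - p)/n` flags a mass-balance violation whenever `s < 2`.

## Conventions

* **Self-coagulation.** For a pair `(i, i)` the event rate is
  `a[i,i] * [i]^2`; one event consumes two particles of size `i` and
  produces one of size `2i`.  This convention makes the dimerization gain
  in `d[2]/dt` exactly `k2*[1]^2` and conserves mass channel by channel.
* **Fragmentation multiplicity.** A size `s` splits through independent
  channels `s -> (i, s-i)` for `i = 1..floor(s/2)`, each at its kernel
  rate times `[s]`.
* **Truncation boundary.** Channels whose product would exceed `N` simply
  do not exist; nothing is clipped or redistributed.  Truncation error is
  a modeling property checked empirically (at the platelet parameter set,
  OD at `N = 10` vs `N = 100` differs by < 0.001%).
* **Written-out expansions.** The size-indexed written-out forms of both
  full systems are transcribed independently in `aggkin.printed` as a
  cross-check.  Six printed terms cannot be reconciled with the kernels
  (missing self-pair double counts, one spurious fission term, missing
  truncation guards); they are catalogued in
  `aggkin.printed.DISCREPANCIES`, and the corrected transcription agrees
  with the network right-hand side to round-off.  The kernel-derived
  network is normative.

## Observables

Normalized optical density of a stirred suspension (Beer–Lambert):

```
OD(t) = exp( ([1](1 + c1*b(t)) + sum_{i>=2} w(i)*[i] - p0) / p0 )
```

with `b(t) = t/(t + lag)` (defined as 0 at `t = 0`) modeling the
transient shape-change rise, and per-aggregate weight `w(i) = i/2` by
default (configurable: `floor_half`, `sqrt`).  For the 2-equation model
the aggregate term becomes `(p0 - p)/2`, i.e. pooled aggregates absorb
like mean-size/2 singles each.  Mean size is `sum(i*[i])/sum([i])` for
the full models and `(p0 - p)/n` for the reduction.

## Integration

Trajectories are integrated with `scipy.integrate.solve_ivp`, method
LSODA, `rtol = 1e-8`, `atol = 1e-10` by default.  Both full variants pass
an **analytic Jacobian** assembled from the channel index arrays; without
it, stiff parameter sets (fitted rates span ten orders of magnitude) make
the solver's internal finite-difference Jacobian thrash.  Negative
concentrations are never clipped — clipping silently breaks mass
conservation — instead every full-model trajectory's total mass is checked
after the fact (default tolerance: relative drift `1e-6` from the initial
mass).

## Steady states and the phase diagram

`steady_state` integrates from the all-monomer state and extends the
horizon geometrically (×10) until `||rhs||_inf < 1e-8 * p0`.  Steady-state
sweeps use the BDF method: on detailed-balance grid cells with extreme
rate ratios, LSODA's stiffness switching can burn tens of millions of
right-hand-side evaluations where BDF with the analytic Jacobian takes
milliseconds.  When integration is within `1e-4 * p0` of the criterion, a
mass-constrained Newton polish (hybrid Powell, mass row replacing the
redundant first equation) removes the integrator's residual noise; the
polished root is accepted only if it is non-negative, within `0.05 * p0`
of the integration endpoint, satisfies the residual criterion, and is
linearly stable — so the trajectory, not the root-finder, selects the
steady state.

Classification assigns the regime holding the largest mass fraction
(monomer, dimer, or sizes >= 3), with ties broken toward the larger-cluster
class.  The phase diagram fixes `p0 = 1`, `k_m1 = k_m2 = 1` and scans the
association ratios `k1/k_m1`, `k2/k_m2` log-spaced over `[1e-3, 1e3]`;
under the detailed-balance restriction `k_m2` is re-derived per cell as
`k2*k_m1/k1`.

**Ratio-invariance caveat.**  Scaling all four rates by one constant is a
pure time rescale and leaves the steady state exactly unchanged.  Scaling
the monomer pair `(k1, k_m1)` and dimer pair `(k2, k_m2)` by *different*
constants preserves both ratios but not, in general, the steady state:
the truncated two-exchange system is not detailed-balanced, so near regime
boundaries the label can flip under independent scaling (observed for a
boundary dimer cell at `k1/k_m1 ≈ 3.4`, `k2/k_m2 ≈ 0.01`).  Interior
cells are robust; the phase diagram's axes should be read with this
caveat at the regime boundaries.

## Fitting

Parameters are searched in log10 space (default bounds `[1e-9, 1e2]`).
Optimizers: log-uniform random search, Hooke–Jeeves pattern search, gbest
particle swarm, and a bounded trust-region-reflective least-squares polish
(the bounded analogue of Levenberg–Marquardt); the default `multistart`
pipeline polishes the best few random starts.  All randomness derives from
one seed.  Failed or overflowing simulations at trial parameters yield
penalty residuals so global search can cross pathological regions.

Constraints: `mobility` (`k2 = k1/2`, dimer mobility is half the monomer's)
and `detailed_balance` (`k_m2 = k2*k_m1/k1`).  Constrained parameters are
derived, not searched, and do not count toward `K` in
`AIC = 2K + n*ln(RSS)`.  AIC values are meaningful only as differences
between fits of the same data.  A warning is raised when distinct
parameter vectors (more than one decade apart) reach RSS within 1% of the
best — the parameter-identifiability problem these models are known for.

## Synthetic data

The generator emulates four measurement types: OD traces (LTA, one sample
per second), monomer-fraction time courses, mean-cluster-size time
courses, and cluster-size-distribution snapshots expressed as percentages
of total receptor mass per size bin.  Noise is additive i.i.d. Gaussian
with standard deviation `sigma * range(clean signal)`, applied after the
observable map (where instrument noise acts), and every series carries a
ground-truth sidecar.  Out of scope: baseline drift, donor-to-donor
variability, optical nonlinearity, and count statistics of imaging assays.

## Known limitations

* The clustering model's `(1,2)` channel overlap is a modeling choice
  consistent with the written-out system; other resolutions (e.g. assigning
  the mixed pair to one row only) change the dimer regime's extent.
* The 2-equation model's detachment term returns monomers without
  shrinking `n`, so it is not the `N = 2` truncation of the full model
  unless all reverse rates vanish.
* Steady-state classification near regime boundaries depends on rate
  magnitudes, not only ratios (see the ratio-invariance caveat above).
* The fitted parameters of these models are often non-identifiable from a
  single observable; joint fits over several observables and the two
  physical constraints mitigate but do not remove this.
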