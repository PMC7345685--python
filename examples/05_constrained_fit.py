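"""Physically constrained estimation for the clustering model.

Two restrictions reduce the number of free parameters:

* mobility: dimers diffuse half as fast as monomers, so k2 = k1/2;
* detailed balance: attachment must not change the free-energy balance,
  so k2/k_m2 = k1/k_m1 (k_m2 is derived).

Constrained parameters are derived rather than searched and do not count
toward K in the AIC, so a constrained model is penalized less.
"""

import numpy as np

from aggkin import (
    FitProblem,
    KineticParams,
    OptimizerSpec,
    SyntheticSpec,
    Variant,
    apply_constraints,
    fit,
    generate,
)

# ground truth that satisfies both constraints exactly
base = KineticParams(variant=Variant.CLUSTERING, k1=0.02, k_m1=0.05, p0=1.0)
truth = apply_constraints(base, {"mobility", "detailed_balance"})
print(f"truth: k1={truth.k1}, k2={truth.k2} (=k1/2), "
      f"k_m1={truth.k_m1}, k_m2={truth.k_m2} (=k2*k_m1/k1)")

series, _ = generate(SyntheticSpec(
    true_params=truth, observable="monomers", N=10,
    t_grid=np.arange(0.0, 601.0, 10.0), sigma=0.005, seed=11,
))

for flags in (frozenset(), frozenset({"mobility", "detailed_balance"})):
    problem = FitProblem(
        datasets=[(series, 1.0)], params=truth,
        free=("k1", "k2", "k_m1", "k_m2"),
        constraints=flags,
        optimizer=OptimizerSpec(method="multistart", n_starts=24, n_polish=3,
                                seed=11),
    )
    result = fit(problem)
    tag = "+".join(sorted(flags)) or "unconstrained"
    print(f"\n{tag}: K = {result.K}, RSS = {result.rss:.4e}, "
          f"AIC = {result.aic:.2f}")
    for name in ("k1", "k2", "k_m1", "k_m2"):
        print(f"  {name:>5} = {getattr(result.params, name):.4e}")
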