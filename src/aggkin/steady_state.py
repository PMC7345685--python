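"""Steady states of the clustering model and the three-regime phase diagram.

Started from free monomers, the clustering model always settles into one of
three regimes, set not by the rate constants themselves but by the two
association ratios (inverse dissociation constants) K1 = k1/k_m1 (monomer
exchange) and K2 = k2/k_m2 (dimer exchange):

* ``unclustered``     — most receptor mass stays monomeric,
* ``dimers``          — most mass sits in dimers (strong monomer binding,
  weak dimer binding),
* ``full_clustering`` — most mass accumulates in the largest clusters.

Imposing the detailed-balance restriction k2/k_m2 = k1/k_m1 collapses the
two ratios onto the diagonal of the phase plane, and the dimer regime
disappears: affinity-driven clustering alone cannot park a cell in a
mostly-dimeric state.

Steady states are found by long-time integration with geometric extension
of the horizon (not by root-finding), mirroring how the regimes are
observed on trajectories and avoiding unstable algebraic roots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import root

from .network import ReactionNetwork, SizeDistribution, build_clustering_network
from .params import KineticParams, Variant
from .simulate import SolverError, simulate

STEADY_TOL = 1e-8  # ||rhs||_inf < STEADY_TOL * p0
TIE_TOL = 1e-9


class SteadyStateLabel(str, Enum):
    UNCLUSTERED = "unclustered"
    DIMERS = "dimers"
    FULL_CLUSTERING = "full_clustering"


#: tie-break order: ties go to the larger-cluster class
_RANK = {
    SteadyStateLabel.UNCLUSTERED: 0,
    SteadyStateLabel.DIMERS: 1,
    SteadyStateLabel.FULL_CLUSTERING: 2,
}


class NonSteadyError(RuntimeError):
    """The system did not reach steady state by t_max; carries the last state."""

    def __init__(self, message: str, last_state: SizeDistribution):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class SteadyStateClass:
    label: SteadyStateLabel
    mass_fractions: tuple[float, float, float]  # (monomer, dimer, cluster >= 3)


@dataclass
class PhaseDiagram:
    ratio_monomer: np.ndarray  # k1/k_m1 axis
    ratio_dimer: np.ndarray  # k2/k_m2 axis
    labels: np.ndarray  # object array of SteadyStateLabel, shape (len r1, len r2)
    N: int
    p0: float
    detailed_balance: bool = False
    convergence: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def label_set(self) -> set[SteadyStateLabel]:
        return {lab for lab in self.labels.ravel() if lab is not None}

    def to_records(self) -> list[dict]:
        out = []
        for a, r1 in enumerate(self.ratio_monomer):
            for b, r2 in enumerate(self.ratio_dimer):
                lab = self.labels[a, b]
                out.append(
                    {
                        "k1_over_k_m1": float(r1),
                        "k2_over_k_m2": float(r2),
                        "label": lab.value if lab is not None else "non_steady",
                    }
                )
        return out


def steady_state(
    params: KineticParams,
    N: int,
    t_init: float = 1.0,
    t_max: float = 1e12,
    tol: float = STEADY_TOL,
    rtol: float = 1e-8,
    atol: float | None = None,
) -> SizeDistribution:
    """Integrate from the all-monomer state until ||rhs||_inf < tol*p0.

    The horizon grows geometrically (x10) until the criterion holds or
    ``t_max`` is exceeded, in which case :class:`NonSteadyError` carries the
    last state reached (genuinely transient systems are a legitimate
    outcome, not a bug).
    """
    params.require_variant(Variant.CLUSTERING)
    network = build_clustering_network(N, params)
    state = SizeDistribution.all_monomer(N, params.p0)
    if atol is None:
        atol = 1e-12 * params.p0
    t_now = 0.0
    horizon = t_init
    while True:
        res = float(np.max(np.abs(network.rhs(state.c))))
        if res < tol * params.p0:
            return state
        # Once integration has nearly converged, a mass-constrained Newton
        # polish of the endpoint removes the integrator's residual noise
        # (stiff cells can amplify sub-atol concentrations above tol).
        # Only a linearly stable root close to the endpoint is accepted, so
        # the trajectory still selects the steady state.
        if res < 1e-4 * params.p0:
            polished = _newton_polish(network, state.c, params.p0, tol)
            if polished is not None:
                return SizeDistribution(c=polished, t=state.t)
        if t_now >= t_max:
            raise NonSteadyError(
                f"no steady state by t = {t_now:g} (||rhs|| still above tolerance)",
                state,
            )
        t_end = min(t_now + horizon, t_max)
        # BDF rather than LSODA: detailed-balance sweeps produce cells with
        # rates spanning ~10 orders of magnitude where LSODA's stiffness
        # switching thrashes (tens of millions of RHS calls); a pure BDF
        # method with the analytic Jacobian stays fast on every cell.
        traj = simulate(
            params, N=N, t_grid=np.array([t_now, t_end]),
            initial=state.c, rtol=rtol, atol=atol, method="BDF",
        )
        state = SizeDistribution(c=traj.states[-1], t=t_end)
        t_now = t_end
        horizon *= 10.0


def _newton_polish(
    network: ReactionNetwork, c: np.ndarray, p0: float, tol: float
) -> np.ndarray | None:
    """Solve rhs(c) = 0 subject to the mass constraint, starting from the
    integration endpoint.  Accepted only if the root is non-negative, close
    to the endpoint (so the trajectory, not the solver, selects the steady
    state) and satisfies the residual criterion; otherwise returns None and
    integration continues."""
    weights = np.arange(1, network.N + 1, dtype=float)

    def objective(x: np.ndarray) -> np.ndarray:
        f = network.rhs(x)
        f[0] = weights @ x - p0  # rhs rows sum to zero mass; pin it explicitly
        return f

    sol = root(objective, c, method="hybr", tol=1e-15)
    x = sol.x
    if not (
        sol.success
        and np.all(x > -1e-9 * p0)
        and np.max(np.abs(x - c)) < 0.05 * p0
        and np.max(np.abs(network.rhs(x))) < tol * p0
    ):
        return None
    if not _is_stable(network, x, p0):
        return None
    return x


def _is_stable(network: ReactionNetwork, x: np.ndarray, p0: float) -> bool:
    """Linear stability of a root: no eigenvalue of the Jacobian with a
    genuinely positive real part (the conserved-mass mode sits at zero)."""
    N = network.N
    J = np.empty((N, N))
    for k in range(N):
        h = 1e-7 * max(p0, abs(x[k]))
        e = np.zeros(N)
        e[k] = h
        J[:, k] = (network.rhs(x + e) - network.rhs(x - e)) / (2.0 * h)
    re = np.linalg.eigvals(J).real
    scale = float(np.max(np.abs(re))) or 1.0
    return bool(np.all(re <= 1e-7 * scale))


def classify(dist: SizeDistribution) -> SteadyStateClass:
    """Assign a converged state to the regime holding most receptor mass."""
    M = dist.total_mass
    if M <= 0:
        raise ValueError("cannot classify an empty system (zero total mass)")
    m_mono = dist.c[0] / M
    m_dimer = 2.0 * dist.c[1] / M if dist.N >= 2 else 0.0
    m_cluster = float(
        np.dot(np.arange(3, dist.N + 1), dist.c[2:]) / M
    ) if dist.N >= 3 else 0.0
    fractions = {
        SteadyStateLabel.UNCLUSTERED: m_mono,
        SteadyStateLabel.DIMERS: m_dimer,
        SteadyStateLabel.FULL_CLUSTERING: m_cluster,
    }
    top = max(fractions.values())
    # ties (within TIE_TOL) break toward the larger-cluster class
    label = max(
        (lab for lab, frac in fractions.items() if frac >= top - TIE_TOL),
        key=lambda lab: _RANK[lab],
    )
    return SteadyStateClass(label=label, mass_fractions=(m_mono, m_dimer, m_cluster))


def phase_diagram(
    ratio_monomer: np.ndarray,
    ratio_dimer: np.ndarray,
    N: int = 15,
    p0: float = 1.0,
    k_m1: float = 1.0,
    k_m2: float = 1.0,
    detailed_balance: bool = False,
    t_max: float = 1e12,
    rtol: float = 1e-8,
) -> PhaseDiagram:
    """Classify the steady state over a grid of association ratios.

    Each cell sets k1 = ratio_monomer*k_m1 and k2 = ratio_dimer*k_m2 with
    the detachment rates held fixed.  Under ``detailed_balance`` the dimer
    detachment rate is re-derived per cell as k_m2 = k2*k_m1/k1, which
    forces k2/k_m2 = k1/k_m1.
    """
    r1 = np.asarray(ratio_monomer, dtype=float)
    r2 = np.asarray(ratio_dimer, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("ratio grids must be positive")
    labels = np.empty((r1.size, r2.size), dtype=object)
    conv = np.zeros((r1.size, r2.size), dtype=bool)
    for a, ra in enumerate(r1):
        for b, rb in enumerate(r2):
            k1 = ra * k_m1
            k2 = rb * k_m2
            km2 = k2 * k_m1 / k1 if detailed_balance else k_m2
            params = KineticParams(
                variant=Variant.CLUSTERING, k1=k1, k2=k2, k_m1=k_m1, k_m2=km2, p0=p0
            )
            try:
                dist = steady_state(params, N, t_max=t_max, rtol=rtol)
            except (NonSteadyError, SolverError):
                labels[a, b] = None
                continue
            labels[a, b] = classify(dist).label
            conv[a, b] = True
    return PhaseDiagram(
        ratio_monomer=r1,
        ratio_dimer=r2,
        labels=labels,
        N=N,
        p0=p0,
        detailed_balance=detailed_balance,
        convergence=conv,
        meta={"k_m1": k_m1, "k_m2": k_m2},
    )
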