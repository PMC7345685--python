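"""Time integration of the kinetic models.

All three variants are stiff for parts of their parameter ranges (rates in
the fitted tables span more than ten orders of magnitude), so integration
uses the LSODA method, which switches automatically between Adams and BDF
steps.  Negative concentrations are never clipped: clipping silently breaks
mass conservation, so instead tolerances are tight by default and the mass
drift of every full-model trajectory is checked after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import ReactionNetwork, SizeDistribution, build_network
from .observables import (
    ObservableSeries,
    TwoEqState,
    mean_size_full,
    mean_size_two_eq,
    optical_density,
    rhs_two_equation,
)
from .params import KineticParams, Variant

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: tolerated relative drift of the conserved total mass along a trajectory
MASS_DRIFT_TOL = 1e-6


class SolverError(RuntimeError):
    """Integration failed; carries the solver report."""

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


@dataclass
class Trajectory:
    """Solution of one model on a time grid, one state per grid point."""

    variant: Variant
    times: np.ndarray
    states: np.ndarray  # shape (n_times, N) or (n_times, 2) for two_equation
    params: KineticParams
    N: int
    solver_report: dict = field(default_factory=dict)
    network: ReactionNetwork | None = None

    def distribution(self, k: int) -> SizeDistribution:
        if self.variant is Variant.TWO_EQUATION:
            raise ValueError("two_equation trajectories carry no size distribution")
        return SizeDistribution(c=self.states[k], t=float(self.times[k]))

    def two_eq_state(self, k: int) -> TwoEqState:
        if self.variant is not Variant.TWO_EQUATION:
            raise ValueError("not a two_equation trajectory")
        p, n = self.states[k]
        return TwoEqState(p=float(p), n=float(n), t=float(self.times[k]))

    @property
    def mass(self) -> np.ndarray:
        """Total particle count sum(i*[i]) at every grid point (full models)."""
        if self.variant is Variant.TWO_EQUATION:
            raise ValueError("mass is not conserved by construction in two_equation")
        return self.states @ np.arange(1, self.N + 1)

    def max_mass_drift(self) -> float:
        """Relative drift of total mass from its initial value (the conserved
        quantity is the trajectory's own starting mass, not necessarily p0)."""
        m = self.mass
        return float(np.max(np.abs(m - m[0])) / m[0])

    def observable(self, name: str, weight_rule: str = "half") -> ObservableSeries:
        """Derive a named observable series from the trajectory."""
        vals = self.observable_values(name, weight_rule)
        return ObservableSeries(
            name=name, times=self.times.copy(), values=vals, weight_rule=weight_rule,
            meta={"variant": self.variant.value, "N": self.N,
                  "time_unit": self.params.time_unit},
        )

    def observable_values(self, name: str, weight_rule: str = "half") -> np.ndarray:
        """Raw observable values (may contain NaN sentinels, e.g. the
        two_equation mean size before any aggregate exists)."""
        p0 = self.params.p0
        if self.variant is Variant.TWO_EQUATION:
            p, n = self.states[:, 0], self.states[:, 1]
            if name == "od":
                vals = np.array(
                    [
                        optical_density(self.two_eq_state(k), self.params,
                                        weight_rule=weight_rule)
                        for k in range(len(self.times))
                    ]
                )
            elif name == "mean_size":
                vals = np.array(
                    [mean_size_two_eq(pk, nk, p0)[0] for pk, nk in zip(p, n)]
                )
            elif name == "monomers":
                vals = p.copy()
            elif name == "cluster_count":
                vals = n.copy()
            else:
                raise ValueError(f"observable {name!r} undefined for two_equation")
        else:
            if name == "od":
                vals = np.array(
                    [
                        optical_density(self.distribution(k), self.params,
                                        weight_rule=weight_rule)
                        for k in range(len(self.times))
                    ]
                )
            elif name == "mean_size":
                vals = np.array(
                    [mean_size_full(self.distribution(k)) for k in range(len(self.times))]
                )
            elif name == "monomers":
                vals = self.states[:, 0].copy()
            elif name == "cluster_count":
                vals = self.states[:, 1:].sum(axis=1)
            elif name == "size_distribution":
                vals = self.states.copy()
            else:
                raise ValueError(f"unknown observable {name!r}")
        return vals


def simulate(
    params: KineticParams,
    N: int = 10,
    t_grid: np.ndarray | None = None,
    initial: SizeDistribution | np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    check_mass: bool = True,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate a model variant on a time grid.

    The default initial condition is the all-monomer state ``[1](0) = p0``.
    For the two_equation variant ``initial`` may be a length-2 array
    ``(p, n)``; ``N`` is ignored.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 601.0, 1.0)  # LTA default: one sample per second
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("time grid must be non-empty and strictly increasing")

    network: ReactionNetwork | None = None
    if params.variant is Variant.TWO_EQUATION:
        y0 = np.array([params.p0, 0.0]) if initial is None else np.asarray(initial, float)
        if y0.shape != (2,):
            raise ValueError("two_equation initial state must be (p, n)")

        def fun(t: float, y: np.ndarray) -> list[float]:
            dp, dn = rhs_two_equation(params, y[0], y[1])
            return [dp, dn]

        def jac(t: float, y: np.ndarray) -> np.ndarray:
            p, n = y
            return np.array([
                [-params.k1 * n - 4.0 * params.k2 * p, -params.k1 * p + params.k_m1],
                [2.0 * params.k2 * p, -2.0 * params.k_m2 * n + params.k3],
            ])

        dim = 2
    else:
        network = build_network(N, params)
        if initial is None:
            y0 = SizeDistribution.all_monomer(N, params.p0).c
        elif isinstance(initial, SizeDistribution):
            y0 = initial.c.copy()
        else:
            y0 = np.asarray(initial, dtype=float)
        if y0.shape != (N,):
            raise ValueError(f"initial state must have length N = {N}")
        # tolerate integrator-level negatives (restart chains), reject real ones
        if np.any(y0 < -1e-9 * params.p0):
            raise ValueError("initial concentrations must be non-negative")

        def fun(t: float, y: np.ndarray) -> np.ndarray:
            return network.rhs(y)

        def jac(t: float, y: np.ndarray) -> np.ndarray:
            return network.jacobian(y)

        dim = N

    if t_grid.size == 1:
        states = y0[None, :].copy()
        report = {"success": True, "nfev": 0, "rtol": rtol, "atol": atol,
                  "message": "initial state only"}
    else:
        sol = solve_ivp(
            fun,
            (t_grid[0], t_grid[-1]),
            y0,
            method=method,
            t_eval=t_grid,
            rtol=rtol,
            atol=atol,
            jac=jac,
        )
        report = {
            "success": bool(sol.success),
            "message": sol.message,
            "nfev": int(sol.nfev),
            "rtol": rtol,
            "atol": atol,
            "method": method,
        }
        if not sol.success:
            raise SolverError(f"{method} failed: {sol.message}", report)
        states = sol.y.T

    traj = Trajectory(
        variant=params.variant,
        times=t_grid,
        states=states,
        params=params,
        N=dim if params.variant is Variant.TWO_EQUATION else N,
        solver_report=report,
        network=network,
    )
    if check_mass and params.variant is not Variant.TWO_EQUATION:
        drift = traj.max_mass_drift()
        report["max_mass_drift"] = drift
        if drift > MASS_DRIFT_TOL:
            raise SolverError(
                f"mass conservation violated: relative drift {drift:.2e}", report
            )
    return traj
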