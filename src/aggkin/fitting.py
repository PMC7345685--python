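"""Constrained least-squares estimation of kinetic parameters.

Parameters are searched in log10 space because fitted rate constants in
this class of models span many orders of magnitude.  The optimizer
repertoire combines global searches (uniform random sampling over the
log-box, a gbest particle swarm, Hooke-Jeeves pattern search) with a local
least-squares polish (trust-region reflective, the bounded analogue of
Levenberg-Marquardt).  All randomness is driven by a single seed, so a fit
is bit-reproducible.

Two physically motivated constraints can be imposed (derived for the
clustering model, where receptor mobility in the membrane scales as the
inverse particle radius and attachment must not alter the total free
energy):

* ``mobility``:          k2 = k1/2
* ``detailed_balance``:  k2/k_m2 = k1/k_m1, i.e. k_m2 = k2*k_m1/k1

A constrained parameter is derived, not free, and does not count toward K
in the Akaike information criterion ``AIC = 2K + n*ln(RSS)``.  AIC values
are only meaningful as differences between fits of the same data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .observables import ObservableSeries
from .params import KineticParams, RATE_NAMES
from .simulate import SolverError, simulate

DEFAULT_BOUNDS = (1e-9, 1e2)
PENALTY = 1e6
CONSTRAINT_NAMES = ("mobility", "detailed_balance")


class ConstraintError(ValueError):
    """A constraint cannot be evaluated (e.g. detailed balance with k1 = 0)."""


class FitFailure(RuntimeError):
    """No optimizer start produced a successful simulation."""


def apply_constraints(params: KineticParams, flags: set[str] | frozenset[str]) -> KineticParams:
    """Return a copy of ``params`` with the flagged restrictions enforced."""
    unknown = set(flags) - set(CONSTRAINT_NAMES)
    if unknown:
        raise ValueError(f"unknown constraint flags: {sorted(unknown)}")
    updates: dict[str, float] = {}
    if "mobility" in flags:
        updates["k2"] = params.k1 / 2.0
    if "detailed_balance" in flags:
        if params.k1 == 0:
            raise ConstraintError("detailed balance undefined when k1 = 0")
        k2 = updates.get("k2", params.k2)
        updates["k_m2"] = k2 * params.k_m1 / params.k1
    return replace(params, **updates) if updates else params


def constrained_names(flags: set[str] | frozenset[str]) -> set[str]:
    out: set[str] = set()
    if "mobility" in flags:
        out.add("k2")
    if "detailed_balance" in flags:
        out.add("k_m2")
    return out


@dataclass
class OptimizerSpec:
    method: str = "multistart"  # random | hooke_jeeves | pso | lm | multistart
    n_starts: int = 32
    iterations: int = 60
    swarm_size: int = 40
    n_polish: int = 4
    seed: int = 0


@dataclass
class FitProblem:
    """One or several observable series fitted jointly by a single model."""

    datasets: list[tuple[ObservableSeries, float]]
    params: KineticParams  # variant, fixed rates, p0, c1, lag
    N: int = 10
    free: tuple[str, ...] = RATE_NAMES
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    constraints: frozenset[str] = frozenset()
    optimizer: OptimizerSpec = field(default_factory=OptimizerSpec)
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one dataset is required")
        for _, w in self.datasets:
            if w <= 0:
                raise ValueError("dataset weights must be positive")
        self.constraints = frozenset(self.constraints)
        # constrained parameters are derived, never searched
        derived = constrained_names(self.constraints)
        self.free = tuple(name for name in self.free if name not in derived)
        for name in self.free:
            lo, hi = self.bounds.get(name, DEFAULT_BOUNDS)
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name} must be positive and ordered")
            self.bounds[name] = (lo, hi)

    @property
    def n_obs(self) -> int:
        return sum(len(series) for series, _ in self.datasets)

    @property
    def K(self) -> int:
        return len(self.free)

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([math.log10(self.bounds[n][0]) for n in self.free])
        hi = np.array([math.log10(self.bounds[n][1]) for n in self.free])
        return lo, hi

    def params_from_theta(self, theta: np.ndarray) -> KineticParams:
        updates = {name: 10.0 ** t for name, t in zip(self.free, theta)}
        return apply_constraints(replace(self.params, **updates), self.constraints)


@dataclass
class FitResult:
    params: KineticParams
    rss: float
    K: int
    n_obs: int
    aic: float
    converged: bool
    seed: int
    constraints: frozenset[str]
    free: tuple[str, ...]
    trace: list[dict] = field(default_factory=list)
    identifiability_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "rss": self.rss,
            "K": self.K,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "converged": self.converged,
            "seed": self.seed,
            "constraints": sorted(self.constraints),
            "free": list(self.free),
            "derived": sorted(constrained_names(self.constraints)),
            "identifiability_warning": self.identifiability_warning,
            "trace": self.trace,
        }


def residuals(problem: FitProblem, params: KineticParams) -> np.ndarray:
    """Weighted residual vector, concatenated over datasets.

    A failed simulation yields penalty residuals rather than an exception,
    so global optimizers can step over pathological parameter regions.
    """
    chunks: list[np.ndarray] = []
    for series, weight in problem.datasets:
        times = series.times
        grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
        try:
            # pathological trial parameters can blow up the reduced model;
            # the numpy warnings are expected noise on the penalty path
            with np.errstate(all="ignore"):
                traj = simulate(
                    params, N=problem.N, t_grid=grid,
                    rtol=problem.rtol, atol=problem.atol,
                )
                model = traj.observable_values(series.name, series.weight_rule)
        except (SolverError, ValueError, ArithmeticError):
            # ArithmeticError covers e.g. exp overflow in the OD map at
            # pathological trial parameters
            chunks.append(np.full(len(series), PENALTY))
            continue
        if times[0] != 0.0:
            model = model[1:]
        r = weight * (model - series.values)
        r[~np.isfinite(r)] = PENALTY
        np.clip(r, -PENALTY, PENALTY, out=r)
        chunks.append(r)
    return np.concatenate(chunks)


def rss_of(problem: FitProblem, params: KineticParams) -> float:
    r = residuals(problem, params)
    return float(r @ r)


def aic(K: int, n_obs: int, rss: float) -> float:
    """Akaike information criterion, AIC = 2K + n*ln(RSS)."""
    if rss <= 0:
        raise ValueError("AIC requires a strictly positive RSS")
    if n_obs < 1:
        raise ValueError("AIC requires at least one observation")
    return 2.0 * K + n_obs * math.log(rss)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two 1-D vectors of equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------- optimizers


def random_search(cost, lo, hi, n, rng):
    """Best of n log-uniform samples over the bounding box."""
    best_x, best_f = None, np.inf
    for _ in range(n):
        x = rng.uniform(lo, hi)
        f = cost(x)
        if f < best_f:
            best_x, best_f = x, f
    return best_x, best_f


def hooke_jeeves(cost, x0, lo, hi, step=0.5, shrink=0.5, tol=1e-4, max_iter=200):
    """Classic pattern search: exploratory moves along each axis, then a
    pattern move through the improved point; the step halves on failure."""
    x = np.clip(np.asarray(x0, float), lo, hi)
    fx = cost(x)
    base, fbase = x.copy(), fx

    def explore(center, fc, h):
        pt, fpt = center.copy(), fc
        for k in range(pt.size):
            for sign in (1.0, -1.0):
                trial = pt.copy()
                trial[k] = np.clip(trial[k] + sign * h, lo[k], hi[k])
                ft = cost(trial)
                if ft < fpt:
                    pt, fpt = trial, ft
                    break
        return pt, fpt

    h = step
    for _ in range(max_iter):
        new, fnew = explore(base, fbase, h)
        if fnew < fbase - 1e-15:
            # pattern move: keep going in the successful direction
            while True:
                cand = np.clip(new + (new - base), lo, hi)
                base, fbase = new, fnew
                cand, fcand = explore(cand, cost(cand), h)
                if fcand < fbase - 1e-15:
                    new, fnew = cand, fcand
                else:
                    break
        else:
            h *= shrink
            if h < tol:
                break
    return base, fbase


def particle_swarm(cost, lo, hi, swarm_size, iterations, rng,
                   inertia=0.7, c_personal=1.5, c_global=1.5):
    """gbest particle swarm over the bounding box."""
    dim = lo.size
    x = rng.uniform(lo, hi, size=(swarm_size, dim))
    v = rng.uniform(-(hi - lo), hi - lo, size=(swarm_size, dim)) * 0.1
    f = np.array([cost(xi) for xi in x])
    pbest, fpbest = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest, fgbest = x[g].copy(), float(f[g])
    for _ in range(iterations):
        r1 = rng.uniform(size=(swarm_size, dim))
        r2 = rng.uniform(size=(swarm_size, dim))
        v = inertia * v + c_personal * r1 * (pbest - x) + c_global * r2 * (gbest - x)
        x = np.clip(x + v, lo, hi)
        f = np.array([cost(xi) for xi in x])
        better = f < fpbest
        pbest[better], fpbest[better] = x[better], f[better]
        g = int(np.argmin(fpbest))
        if fpbest[g] < fgbest:
            gbest, fgbest = pbest[g].copy(), float(fpbest[g])
    return gbest, fgbest


def _lm_polish(problem: FitProblem, theta0, lo, hi):
    def resid(theta):
        return residuals(problem, problem.params_from_theta(theta))

    sol = least_squares(
        resid, np.clip(theta0, lo, hi), bounds=(lo, hi),
        method="trf", x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    return sol.x, float(sol.cost * 2.0), bool(sol.success)


def fit(problem: FitProblem) -> FitResult:
    """Estimate the free parameters of a FitProblem.

    The default ``multistart`` pipeline samples the log-box at random,
    polishes the best few candidates with bounded least squares and keeps
    the overall best.  ``pso`` and ``hooke_jeeves`` run their global stage
    first and polish the winner.  Identical problems and seeds give
    bit-identical results.
    """
    spec = problem.optimizer
    rng = np.random.default_rng(spec.seed)
    lo, hi = problem.log_bounds()
    trace: list[dict] = []

    def cost(theta):
        return rss_of(problem, problem.params_from_theta(theta))

    candidates: list[tuple[np.ndarray, float]] = []
    polished_ok = False

    if spec.method in ("random", "multistart"):
        samples = rng.uniform(lo, hi, size=(spec.n_starts, lo.size))
        scored = sorted(
            ((s, cost(s)) for s in samples), key=lambda t: t[1]
        )
        trace.append({"stage": "random_search", "best_rss": scored[0][1]})
        if spec.method == "random":
            candidates = [scored[0]]
        else:
            for theta0, f0 in scored[: spec.n_polish]:
                x, f, ok = _lm_polish(problem, theta0, lo, hi)
                polished_ok = polished_ok or ok
                candidates.append((x, f))
                trace.append({"stage": "lm_polish", "start_rss": f0, "rss": f})
    elif spec.method == "pso":
        x, f = particle_swarm(cost, lo, hi, spec.swarm_size, spec.iterations, rng)
        trace.append({"stage": "pso", "rss": f})
        xp, fp, ok = _lm_polish(problem, x, lo, hi)
        polished_ok = ok
        candidates = [(x, f), (xp, fp)]
        trace.append({"stage": "lm_polish", "rss": fp})
    elif spec.method == "hooke_jeeves":
        x0, f0 = random_search(cost, lo, hi, max(spec.n_starts, 1), rng)
        x, f = hooke_jeeves(cost, x0, lo, hi, max_iter=spec.iterations)
        trace.append({"stage": "hooke_jeeves", "start_rss": f0, "rss": f})
        candidates = [(x, f)]
    elif spec.method == "lm":
        theta0 = rng.uniform(lo, hi) if spec.n_starts else (lo + hi) / 2.0
        x, f, ok = _lm_polish(problem, theta0, lo, hi)
        polished_ok = ok
        candidates = [(x, f)]
        trace.append({"stage": "lm", "rss": f})
    else:
        raise ValueError(f"unknown optimizer method {spec.method!r}")

    candidates.sort(key=lambda t: t[1])
    best_theta, best_rss = candidates[0]
    if not math.isfinite(best_rss) or best_rss >= PENALTY**2:
        raise FitFailure("every optimizer start failed to simulate")

    # identifiability: distinct parameter vectors reaching the same RSS
    warn = False
    for theta, f in candidates[1:]:
        if f <= best_rss * 1.01 and np.any(np.abs(theta - best_theta) > 1.0):
            warn = True
            break

    params = problem.params_from_theta(best_theta)
    n = problem.n_obs
    result_aic = aic(problem.K, n, best_rss) if best_rss > 0 else -math.inf
    return FitResult(
        params=params,
        rss=best_rss,
        K=problem.K,
        n_obs=n,
        aic=result_aic,
        converged=polished_ok or spec.method in ("random", "hooke_jeeves"),
        seed=spec.seed,
        constraints=problem.constraints,
        free=problem.free,
        trace=trace,
        identifiability_warning=warn,
    )


def compare_fits(result_a: FitResult, result_b: FitResult,
                 label_a: str = "a", label_b: str = "b") -> dict:
    """Akaike comparison of two fits of the SAME data (n must match)."""
    if result_a.n_obs != result_b.n_obs:
        raise ValueError("AIC comparison requires fits of the same data")
    delta = result_a.aic - result_b.aic
    return {
        label_a: {"aic": result_a.aic, "rss": result_a.rss, "K": result_a.K},
        label_b: {"aic": result_b.aic, "rss": result_b.rss, "K": result_b.K},
        "delta_aic": delta,
        "selected": label_a if delta <= 0 else label_b,
    }
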