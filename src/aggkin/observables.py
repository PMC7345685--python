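"""Observable maps and the 2-equation reduced model.

Optical density (light-transmission aggregometry).  A stirred suspension
absorbs light according to Beer-Lambert; the absorbance index is
proportional to the concentration of absorbing particles.  An aggregate of
``i`` particles absorbs less than ``i`` singles; the per-aggregate weight
``w(i)`` is configurable (default ``i/2``).  The normalized optical density
of a size distribution ``[1..N]`` is::

    OD(t) = exp( ([1](t)*(1 + c1*b(t)) + sum_{i>=2} w(i)*[i](t) - p0) / p0 )

with ``b(t) = t/(t + lag)`` a saturating shape-change factor: platelets
swell on activation, transiently raising OD by a factor up to
``exp(c1) ~ 1.1`` before aggregation drives it down.  ``b`` is defined as 0
at ``t = 0`` (also when ``lag = 0``).

The 2-equation model pools every aggregate of size >= 2 into a single
concentration ``n`` next to the free monomers ``p``::

    dp/dt = -k1*n*p - 2*k2*p**2 + k_m1*n
    dn/dt =  k2*p**2 - k_m2*n**2 + k3*n

Its mean aggregate size is ``s = (p0 - p)/n``; because ``n`` carries no
size information, mass is not exactly conserved and ``s < 2`` signals a
mass-balance violation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .network import SizeDistribution
from .params import KineticParams, ParameterError, Variant

#: relative threshold below which the pooled aggregate concentration is
#: treated as "no aggregates" when evaluating the 2-equation mean size
MEAN_SIZE_EPS = 1e-12

OBSERVABLE_NAMES = ("od", "mean_size", "monomers", "cluster_count", "size_distribution")

WEIGHT_RULES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "half": lambda i: i / 2.0,
    "floor_half": lambda i: np.floor(i / 2.0),
    "sqrt": lambda i: np.sqrt(i),
}


class UndefinedSizeError(ValueError):
    """Mean size requested for an empty distribution."""


@dataclass
class TwoEqState:
    """State of the reduced model: free monomers p and pooled aggregates n."""

    p: float
    n: float
    t: float = 0.0


@dataclass
class ObservableSeries:
    """A named time series derived from a model trajectory or measured."""

    name: str
    times: np.ndarray
    values: np.ndarray
    weight_rule: str = "half"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.name not in OBSERVABLE_NAMES:
            raise ValueError(f"unknown observable {self.name!r}")
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if self.values.shape[0] != self.times.size:
            raise ValueError("one value (row) per time point required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observable values must be finite")

    def __len__(self) -> int:
        return self.times.size


def shape_change_factor(t: float | np.ndarray, lag: float) -> float | np.ndarray:
    """b(t) = t/(t + lag), with b(0) = 0 by continuity (also when lag = 0)."""
    t = np.asarray(t, dtype=float)
    out = np.divide(t, t + lag, out=np.zeros_like(t), where=(t + lag) > 0)
    return out if out.ndim else float(out)


def rhs_two_equation(params: KineticParams, p: float, n: float) -> tuple[float, float]:
    """Time derivatives (dp/dt, dn/dt) of the reduced model."""
    params.require_variant(Variant.TWO_EQUATION)
    dp = -params.k1 * n * p - 2.0 * params.k2 * p * p + params.k_m1 * n
    dn = params.k2 * p * p - params.k_m2 * n * n + params.k3 * n
    return dp, dn


def optical_density(
    state: SizeDistribution | TwoEqState,
    params: KineticParams,
    t: float | None = None,
    weight_rule: str = "half",
) -> float:
    """Normalized optical density of a model state (1 at t = 0 by construction)."""
    if params.p0 <= 0:
        raise ParameterError("p0 must be positive for the OD observable")
    if t is None:
        t = state.t
    b = shape_change_factor(t, params.lag)
    w = WEIGHT_RULES[weight_rule]
    if isinstance(state, TwoEqState):
        # pooled aggregates absorb like (mean size)/2 singles each:
        # w_bar*n = s/2*n = (p0 - p)/2
        mono = state.p
        agg = (params.p0 - state.p) / 2.0
    else:
        mono = state.c[0]
        sizes = np.arange(2, state.N + 1)
        agg = float(np.dot(w(sizes), state.c[1:]))
    return math.exp((mono * (1.0 + params.c1 * b) + agg - params.p0) / params.p0)


def mean_size_full(dist: SizeDistribution) -> float:
    """Number-weighted mean aggregate size S = sum(i*[i]) / sum([i])."""
    total = float(dist.c.sum())
    if total <= 0:
        raise UndefinedSizeError("mean size undefined: no aggregates of any size")
    return dist.total_mass / total


def mean_size_two_eq(p: float, n: float, p0: float) -> tuple[float, bool]:
    """Reduced-model mean size s = (p0 - p)/n.

    Returns ``(s, ok)``.  When ``n`` is below the definedness threshold the
    sentinel ``(nan, False)`` is returned (no aggregates exist).  ``ok`` is
    also False when ``s < 2``, which flags a violation of the implicit mass
    balance (a pooled aggregate must contain at least two particles).
    """
    if n <= MEAN_SIZE_EPS * p0:
        return math.nan, False
    s = (p0 - p) / n
    return s, s >= 2.0
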