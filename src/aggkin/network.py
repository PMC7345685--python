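"""Finite coagulation-fragmentation reaction networks.

A model variant is defined by its piecewise-constant kernels: the matrix
``a[i, j]`` of coagulation rate constants (the pair of sizes ``i + j <= N``
merges) and ``f[i, j]`` of fragmentation rate constants (an aggregate of
size ``i + j`` splits into parts of sizes ``i`` and ``j``).  Because real
aggregates cannot grow without bound, the system is truncated at a maximal
size ``N``: any channel whose product would exceed ``N`` simply does not
exist.

The network form is the normative model.  Each channel is an elementary
mass-action reaction:

* coagulation ``(i, j) -> i+j`` fires at rate ``a[i,j]*[i]*[j]``; for a
  self-pair ``(i, i)`` the event rate is ``a[i,i]*[i]**2`` and one event
  consumes two particles of size ``i``,
* fragmentation ``s -> (i, s-i)`` fires at rate ``f[i,s-i]*[s]`` for each
  split ``i = 1..floor(s/2)`` independently.

Total mass ``sum(i*[i])`` is conserved exactly by every channel's
stoichiometry.

Aggregation-variant kernels (3D aggregation of particles in suspension)::

    a[1,1] = k2    a[1,j>1] = k1    a[i>1,j>1] = k_m2
    f[1,j] = k_m1  f[i>1,j>1] = k3

Clustering-variant kernels (2D clustering of membrane receptors, an
extended Becker-Doring scheme: only monomers and dimers are mobile enough
to attach or detach)::

    a[1,j] = k1    a[2,j] = k2    a[i>2,j>2] = 0
    f[1,j] = k_m1  f[2,j] = k_m2  f[i>2,j>2] = 0

The monomer and dimer rows overlap on the mixed pair ``(1, 2)``: that pair
carries two independent coagulation channels (one at ``k1``, one at
``k2``), and the size-3 fission into ``(1, 2)`` likewise carries both a
``k_m1`` and a ``k_m2`` channel.  The self-pair ``(1, 1)`` uses ``k1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

from .params import KineticParams, Variant


class InvalidSizeError(ValueError):
    """Maximal size N out of range, or a state of the wrong dimension."""


@dataclass
class SizeDistribution:
    """Concentrations of aggregates/clusters of each size 1..N at one time."""

    c: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.ndim != 1 or self.c.size < 1:
            raise InvalidSizeError("concentration vector must be 1-D and non-empty")

    @property
    def N(self) -> int:
        return self.c.size

    @property
    def total_mass(self) -> float:
        """M = sum of i*[i], the conserved particle count."""
        return float(np.dot(np.arange(1, self.N + 1), self.c))

    @classmethod
    def all_monomer(cls, N: int, p0: float, t: float = 0.0) -> "SizeDistribution":
        c = np.zeros(N)
        c[0] = p0
        return cls(c=c, t=t)


class ReactionKind(str, Enum):
    COAGULATION = "coagulation"
    FRAGMENTATION = "fragmentation"


@dataclass(frozen=True)
class Reaction:
    """One elementary channel: (i, j) <-> i+j with a named rate constant."""

    kind: ReactionKind
    i: int
    j: int
    rate_label: str

    def __post_init__(self) -> None:
        if not (1 <= self.i <= self.j):
            raise InvalidSizeError("reaction sizes must satisfy 1 <= i <= j")

    @property
    def product_or_source(self) -> int:
        return self.i + self.j

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "sizes": [self.i, self.j],
            "product_or_source": self.product_or_source,
            "rate_label": self.rate_label,
        }


def _aggregation_channels(N: int) -> Iterable[Reaction]:
    for i in range(1, N + 1):
        for j in range(i, N - i + 1):
            label = "k2" if (i, j) == (1, 1) else ("k1" if i == 1 else "k_m2")
            yield Reaction(ReactionKind.COAGULATION, i, j, label)
    for s in range(2, N + 1):
        for i in range(1, s // 2 + 1):
            label = "k_m1" if i == 1 else "k3"
            yield Reaction(ReactionKind.FRAGMENTATION, i, s - i, label)


def _clustering_channels(N: int) -> Iterable[Reaction]:
    # Only monomer (i=1) and dimer (i=2) rows of the kernel are non-zero.
    # The (1,2) pair carries BOTH channels; (1,1) uses k1.
    for i in range(1, N + 1):
        for j in range(i, N - i + 1):
            if i == 1:
                yield Reaction(ReactionKind.COAGULATION, i, j, "k1")
                if j == 2:
                    yield Reaction(ReactionKind.COAGULATION, i, j, "k2")
            elif i == 2:
                yield Reaction(ReactionKind.COAGULATION, i, j, "k2")
    for s in range(2, N + 1):
        for i in range(1, s // 2 + 1):
            if i == 1:
                yield Reaction(ReactionKind.FRAGMENTATION, i, s - i, "k_m1")
                if s - i == 2:
                    yield Reaction(ReactionKind.FRAGMENTATION, i, s - i, "k_m2")
            elif i == 2:
                yield Reaction(ReactionKind.FRAGMENTATION, i, s - i, "k_m2")


@dataclass
class ReactionNetwork:
    """Explicit channel list plus compiled index arrays for the mass-action RHS."""

    N: int
    variant: Variant
    reactions: list[Reaction]
    params: KineticParams
    # compiled arrays (filled in __post_init__)
    _ci: np.ndarray = field(init=False, repr=False)
    _cj: np.ndarray = field(init=False, repr=False)
    _cp: np.ndarray = field(init=False, repr=False)
    _crate: np.ndarray = field(init=False, repr=False)
    _fi: np.ndarray = field(init=False, repr=False)
    _fj: np.ndarray = field(init=False, repr=False)
    _fs: np.ndarray = field(init=False, repr=False)
    _frate: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rates = self.params.rates()
        coag = [r for r in self.reactions if r.kind is ReactionKind.COAGULATION]
        frag = [r for r in self.reactions if r.kind is ReactionKind.FRAGMENTATION]
        self._ci = np.array([r.i - 1 for r in coag], dtype=np.intp)
        self._cj = np.array([r.j - 1 for r in coag], dtype=np.intp)
        self._cp = np.array([r.i + r.j - 1 for r in coag], dtype=np.intp)
        self._crate = np.array([rates[r.rate_label] for r in coag], dtype=float)
        self._fi = np.array([r.i - 1 for r in frag], dtype=np.intp)
        self._fj = np.array([r.j - 1 for r in frag], dtype=np.intp)
        self._fs = np.array([r.i + r.j - 1 for r in frag], dtype=np.intp)
        self._frate = np.array([rates[r.rate_label] for r in frag], dtype=float)

    def rhs(self, c: np.ndarray) -> np.ndarray:
        """Mass-action time derivatives d[i]/dt for a concentration vector c."""
        c = np.asarray(c, dtype=float)
        if c.shape != (self.N,):
            raise InvalidSizeError(
                f"state has dimension {c.shape}, network expects ({self.N},)"
            )
        dc = np.zeros(self.N)
        if self._crate.size:
            R = self._crate * c[self._ci] * c[self._cj]
            np.subtract.at(dc, self._ci, R)
            np.subtract.at(dc, self._cj, R)
            np.add.at(dc, self._cp, R)
        if self._frate.size:
            R = self._frate * c[self._fs]
            np.subtract.at(dc, self._fs, R)
            np.add.at(dc, self._fi, R)
            np.add.at(dc, self._fj, R)
        return dc

    def rhs_distribution(self, state: SizeDistribution) -> np.ndarray:
        return self.rhs(state.c)

    def jacobian(self, c: np.ndarray) -> np.ndarray:
        """Analytic Jacobian d(rhs)/dc; essential for stiff integration."""
        c = np.asarray(c, dtype=float)
        J = np.zeros((self.N, self.N))
        if self._crate.size:
            # channel rate R = a*c_i*c_j: dR/dc_i = a*c_j, dR/dc_j = a*c_i
            di = self._crate * c[self._cj]
            dj = self._crate * c[self._ci]
            for rows, sign in (((self._ci,), -1.0), ((self._cj,), -1.0),
                               ((self._cp,), +1.0)):
                np.add.at(J, (rows[0], self._ci), sign * di)
                np.add.at(J, (rows[0], self._cj), sign * dj)
        if self._frate.size:
            np.add.at(J, (self._fs, self._fs), -self._frate)
            np.add.at(J, (self._fi, self._fs), self._frate)
            np.add.at(J, (self._fj, self._fs), self._frate)
        return J

    def dump(self) -> list[dict]:
        """JSON-ready listing of channels, for inspection and golden files."""
        return [r.to_dict() for r in self.reactions]


def build_aggregation_network(N: int, params: KineticParams) -> ReactionNetwork:
    """Truncated Smoluchowski coagulation-fragmentation network (3D aggregation)."""
    if N < 1:
        raise InvalidSizeError("maximal aggregate size N must be >= 1")
    params.require_variant(Variant.AGGREGATION)
    return ReactionNetwork(
        N=N,
        variant=Variant.AGGREGATION,
        reactions=list(_aggregation_channels(N)),
        params=params,
    )


def build_clustering_network(N: int, params: KineticParams) -> ReactionNetwork:
    """Extended Becker-Doring network: monomer and dimer exchange only (2D clustering)."""
    if N < 1:
        raise InvalidSizeError("maximal cluster size N must be >= 1")
    params.require_variant(Variant.CLUSTERING)
    return ReactionNetwork(
        N=N,
        variant=Variant.CLUSTERING,
        reactions=list(_clustering_channels(N)),
        params=params,
    )


def build_network(N: int, params: KineticParams) -> ReactionNetwork:
    """Dispatch on the parameter set's variant."""
    if params.variant is Variant.AGGREGATION:
        return build_aggregation_network(N, params)
    if params.variant is Variant.CLUSTERING:
        return build_clustering_network(N, params)
    raise ValueError("the two_equation variant has no size-resolved network")
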