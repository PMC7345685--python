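"""Rate-constant sets shared by the three model variants.

The same five rate constants appear in all variants but their meaning
changes with the variant:

============  =============================  ==============================
constant      aggregation / two_equation     clustering
============  =============================  ==============================
k1            particle attachment to an      monomer attachment to a
              existing aggregate             cluster
k2            new aggregate formation from   dimer attachment to a cluster
              two single particles
k_m1 (k−1)    single-particle detachment     monomer detachment
k_m2 (k−2)    aggregate–aggregate            dimer detachment
              coagulation
k3            aggregate fission into two     (absent)
              multi-particle parts
============  =============================  ==============================

``p0`` is the initial concentration of free monomers; ``c1`` and ``lag``
parameterize the shape-change term of the optical-density observable and
play no role in the kinetics themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum


class Variant(str, Enum):
    """Model variant; fixes the semantics of the rate constants."""

    AGGREGATION = "aggregation"
    CLUSTERING = "clustering"
    TWO_EQUATION = "two_equation"


RATE_NAMES = ("k1", "k2", "k_m1", "k_m2", "k3")


class ParameterError(ValueError):
    """Invalid kinetic parameter set."""


class VariantMismatchError(ValueError):
    """Operation called with a parameter set of the wrong model variant."""


@dataclass(frozen=True)
class KineticParams:
    variant: Variant
    k1: float = 0.0
    k2: float = 0.0
    k_m1: float = 0.0
    k_m2: float = 0.0
    k3: float = 0.0
    p0: float = 1.0
    c1: float = 0.1
    lag: float = 0.0
    time_unit: str = field(default="s", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Variant(self.variant))
        for name in RATE_NAMES:
            if getattr(self, name) < 0:
                raise ParameterError(f"rate constant {name} must be >= 0")
        if self.p0 <= 0:
            raise ParameterError("initial monomer concentration p0 must be > 0")
        if self.variant is Variant.CLUSTERING and self.k3 != 0.0:
            raise ParameterError(
                "the clustering variant has no aggregate-fission channel: k3 must be 0"
            )

    def require_variant(self, variant: Variant) -> None:
        if self.variant is not Variant(variant):
            raise VariantMismatchError(
                f"expected {Variant(variant).value} parameters, got {self.variant.value}"
            )

    def rates(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATE_NAMES}

    def with_updates(self, **kwargs: float) -> "KineticParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in RATE_NAMES}
        d.update(
            variant=self.variant.value,
            p0=self.p0,
            c1=self.c1,
            lag=self.lag,
            time_unit=self.time_unit,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)
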