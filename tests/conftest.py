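"""Shared fixtures: published-style fitted parameter sets used across tests.

These four sets are realistic fitted values for the two experimental systems
the models target (platelet aggregation in light-transmission aggregometry,
and membrane-receptor clustering), spanning the rate-constant magnitudes the
code must handle.
"""

from __future__ import annotations

import numpy as np
import pytest

from aggkin import KineticParams, Variant

# Platelet aggregation at 2 uM ADP, full aggregation model (rates in 1/s).
ADP2_AGG = dict(
    variant=Variant.AGGREGATION,
    k_m1=0.0001, k1=0.009, k_m2=8e-7, k2=0.0016, k3=0.0068, p0=4.8,
)

# Same system, two-equation reduction.
ADP2_2EQ = dict(
    variant=Variant.TWO_EQUATION,
    k_m1=0.0061, k1=0.009, k_m2=8e-7, k2=0.0016, k3=0.0014, p0=4.24,
)

# GPVI receptor clustering on a collagen surface (clustering model).
GPVI_CLU = dict(
    variant=Variant.CLUSTERING,
    k1=6.1e-6, k_m1=0.053, k2=0.56, k_m2=10.2, p0=1e4,
)

# Complement-receptor clustering, per-minute rates, p0 in receptors/um^2.
CR3_CLU = dict(
    variant=Variant.CLUSTERING,
    k1=5.4e-5, k_m1=6.7e-4, k2=3.4e-5, k_m2=6.7e-4, p0=16.4,
    time_unit="min",
)


@pytest.fixture
def adp2_aggregation() -> KineticParams:
    return KineticParams(**ADP2_AGG)


@pytest.fixture
def adp2_two_eq() -> KineticParams:
    return KineticParams(**ADP2_2EQ)


@pytest.fixture
def gpvi_clustering() -> KineticParams:
    return KineticParams(**GPVI_CLU)


@pytest.fixture
def cr3_clustering() -> KineticParams:
    return KineticParams(**CR3_CLU)


def random_state(N: int, seed: int) -> np.ndarray:
    """A strictly positive random concentration vector for oracle tests."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.1, 2.0, size=N)
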