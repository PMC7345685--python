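"""Synthetic observable generator with known ground truth.

Emulates the four kinds of measurement these models are fitted against:

* optical density traces from light-transmission aggregometry (platelet
  aggregation; sampled once per second),
* non-aggregated monomer fraction over time (protein aggregation assays),
* mean cluster size over time (receptor clustering quantified from TIRF
  microscopy),
* cluster-size distribution snapshots at a few time points, reported as
  percentages of total receptor mass per size bin (immunolocalization
  counts).

Noise is additive i.i.d. Gaussian with standard deviation expressed as a
fraction of the noiseless signal's range, applied to the measured signal
(for OD: after the exponential map, where instrument noise acts).  Every
series carries a sidecar with the true parameters and the seed so that
parameter-recovery tests can close the loop.

The generator emulates measurement noise only: real assays additionally
carry baseline drift, donor-to-donor variability and optical nonlinearity
that are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observables import ObservableSeries
from .params import KineticParams, Variant
from .simulate import simulate


@dataclass
class SyntheticSpec:
    true_params: KineticParams
    observable: str = "od"
    N: int = 10
    t_grid: np.ndarray | None = None
    sigma: float = 0.0  # noise s.d. as a fraction of the signal range
    seed: int = 0
    weight_rule: str = "half"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise level sigma must be >= 0")
        if self.t_grid is None:
            self.t_grid = np.arange(0.0, 601.0, 1.0)
        self.t_grid = np.asarray(self.t_grid, dtype=float)


def generate(spec: SyntheticSpec) -> tuple[ObservableSeries, dict]:
    """Simulate the ground truth, add noise, and return (series, sidecar)."""
    traj = simulate(spec.true_params, N=spec.N, t_grid=spec.t_grid)
    clean = traj.observable_values(spec.observable, spec.weight_rule)
    rng = np.random.default_rng(spec.seed)
    if spec.observable == "size_distribution":
        # snapshots as percentage of total receptor mass per size bin
        sizes = np.arange(1, spec.N + 1)
        mass = clean * sizes  # (n_times, N)
        clean = 100.0 * mass / mass.sum(axis=1, keepdims=True)
    scale = spec.sigma * float(np.ptp(clean)) if spec.sigma > 0 else 0.0
    values = clean + rng.normal(0.0, scale, size=clean.shape) if scale > 0 else clean.copy()
    series = ObservableSeries(
        name=spec.observable,
        times=spec.t_grid.copy(),
        values=values,
        weight_rule=spec.weight_rule,
        meta={
            "synthetic": True,
            "seed": spec.seed,
            "sigma": spec.sigma,
            "variant": spec.true_params.variant.value,
            "N": spec.N,
        },
    )
    sidecar = {
        "true_params": spec.true_params.to_dict(),
        "N": spec.N,
        "observable": spec.observable,
        "sigma": spec.sigma,
        "seed": spec.seed,
        "noiseless": clean.tolist(),
    }
    return series, sidecar
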