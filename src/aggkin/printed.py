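"""Independent transcriptions of the written-out ODE systems.

The model is defined normatively by the kernel-derived reaction network
(:mod:`aggkin.network`).  The written-out, size-indexed expansions of the
aggregation and clustering systems serve as a cross-check: this module
transcribes them as straightforward index sums, deliberately sharing no
code with the channel-based implementation.

Two transcriptions are provided per variant:

* ``literal=True`` — the expansion exactly as written, including its
  typographic defects (terms listed in :data:`DISCREPANCIES`), with any
  out-of-range concentration read as zero;
* ``literal=False`` (corrected, the default) — the same sum structure with
  the defects repaired: self-pair double-count corrections restored,
  spurious terms dropped, and truncation guards added at the j = N
  boundary.  The corrected transcription must agree with the network RHS
  to round-off for every state; the test suite asserts this.
"""

from __future__ import annotations

import numpy as np

from .network import ReactionNetwork
from .params import KineticParams, Variant

#: Printed terms that cannot be reproduced from the kernel tables.  Each
#: entry names the equation line, the term as written, and the kernel-based
#: resolution used in the corrected transcription.
DISCREPANCIES: list[dict] = [
    {
        "variant": "aggregation",
        "line": "d[2]/dt",
        "printed_term": "-k3*[2] (inside the k3 parenthesis)",
        "resolution": (
            "dropped: a size-2 aggregate has only the (1,1) split, which is a "
            "monomer-detachment (k_m1) channel, never a multi-particle (k3) fission"
        ),
    },
    {
        "variant": "aggregation",
        "line": "d[j]/dt, j>2",
        "printed_term": "-h_j*[j] (inside the k_m2 parenthesis)",
        "resolution": (
            "read as -h_j*[j]**2: the self-coagulation channel (j,j) consumes two "
            "aggregates per event, so the loss carries [j] squared twice in total"
        ),
    },
    {
        "variant": "aggregation",
        "line": "d[j]/dt, j>2",
        "printed_term": "-k1*[1]*[j] at j = N (and k_m1*[j+1] at j = N)",
        "resolution": (
            "guarded by the truncation: the channel (1,N) -> N+1 does not exist, "
            "and [N+1] is identically zero"
        ),
    },
    {
        "variant": "clustering",
        "line": "d[1]/dt",
        "printed_term": "-k1*[1]*sum_{i=1}^{N-1}[i] (self pair counted once)",
        "resolution": (
            "one additional -k1*[1]**2 restored: the (1,1) event consumes two "
            "monomers at rate k1*[1]**2, as the written d[2]/dt gain +k1*[1]*[1] "
            "and mass conservation both require"
        ),
    },
    {
        "variant": "clustering",
        "line": "d[2]/dt",
        "printed_term": "-k2*[2]*sum_{i=1}^{N-2}[i] (self pair counted once)",
        "resolution": (
            "one additional -k2*[2]**2 restored for the dimer-dimer (2,2) channel "
            "when 4 <= N"
        ),
    },
    {
        "variant": "clustering",
        "line": "d[j]/dt, j>2",
        "printed_term": "-k1*[1]*[j] at j = N; -k2*[2]*[j] at j >= N-1",
        "resolution": "guarded by the truncation (products above N do not exist)",
    },
]


def _padded(c: np.ndarray) -> np.ndarray:
    """1-indexed copy of c, zero-padded up to index 2N (index 0 unused)."""
    N = c.size
    out = np.zeros(2 * N + 2)
    out[1 : N + 1] = c
    return out


def aggregation_rhs_printed(
    c: np.ndarray, params: KineticParams, literal: bool = False
) -> np.ndarray:
    """Transcription of the written-out truncated Smoluchowski system."""
    params.require_variant(Variant.AGGREGATION)
    c = np.asarray(c, dtype=float)
    N = c.size
    k1, k2, km1, km2, k3 = params.k1, params.k2, params.k_m1, params.k_m2, params.k3
    u = _padded(c)
    d = np.zeros(N + 1)

    # d[1]/dt; the dimerization loss requires the size-2 product to exist
    k2_loss = u[1] ** 2 if (literal or N >= 2) else 0.0
    d[1] = (
        -k1 * u[1] * u[2:N].sum()
        - 2.0 * k2 * k2_loss
        + km1 * (u[2 : N + 1].sum() + u[2])
    )

    if N >= 2:
        # d[2]/dt
        km2_loss = u[2 : N - 1].sum() + (u[2] if (literal or N >= 4) else 0.0)
        k3_gain = u[4 : N + 1].sum() + u[4] - (u[2] if literal else 0.0)
        k1_loss = u[2] if (literal or N >= 3) else 0.0
        d[2] = (
            k2 * u[1] * u[1]
            - km2 * u[2] * km2_loss
            + k3 * k3_gain
            - k1 * u[1] * k1_loss
            + km1 * (u[3] - u[2])
        )

    for j in range(3, N + 1):
        h_j = 1.0 if 2 * j <= N else 0.0
        gain_pairs = sum(u[i] * u[j - i] for i in range(2, j // 2 + 1))
        self_loss = u[j] if literal else u[j] ** 2
        km2_term = km2 * (
            gain_pairs - u[j] * u[2 : N - j + 1].sum() - h_j * self_loss
        )
        k3_term = k3 * (
            u[j + 2 : N + 1].sum() + h_j * u[2 * j] - (j // 2 - 1) * u[j]
        )
        k1_out = u[j] if (literal or j + 1 <= N) else 0.0
        k1_term = -k1 * u[1] * (k1_out - u[j - 1])
        km1_term = km1 * (u[j + 1] - u[j])
        d[j] = km2_term + k3_term + k1_term + km1_term

    return d[1 : N + 1]


def clustering_rhs_printed(
    c: np.ndarray, params: KineticParams, literal: bool = False
) -> np.ndarray:
    """Transcription of the written-out extended Becker-Doring system."""
    params.require_variant(Variant.CLUSTERING)
    c = np.asarray(c, dtype=float)
    N = c.size
    k1, k2, km1, km2 = params.k1, params.k2, params.k_m1, params.k_m2
    u = _padded(c)
    d = np.zeros(N + 1)

    self_mono = 0.0 if literal else (u[1] if N >= 2 else 0.0)
    d[1] = (
        -k1 * u[1] * (u[1:N].sum() + self_mono)
        + km1 * (u[2 : N + 1].sum() + u[2])
        - k2 * u[1] * (u[2] if (literal or N >= 3) else 0.0)
        + km2 * u[3]
    )

    if N >= 2:
        self_dim = 0.0 if literal else (u[2] if N >= 4 else 0.0)
        d[2] = (
            -k2 * u[2] * (u[1 : N - 1].sum() + self_dim)
            + km2 * (u[3 : N + 1].sum() + u[4])
            + k1 * u[1] * (u[1] - (u[2] if (literal or N >= 3) else 0.0))
            - km1 * (u[2] - u[3])
        )

    for j in range(3, N + 1):
        k1_out = u[j] if (literal or j + 1 <= N) else 0.0
        k2_out = u[j] if (literal or j + 2 <= N) else 0.0
        d[j] = (
            k1 * (u[j - 1] * u[1] - k1_out * u[1])
            + km1 * (u[j + 1] - u[j])
            + k2 * (u[j - 2] * u[2] - k2_out * u[2])
            + km2 * (u[j + 2] - u[j])
        )

    return d[1 : N + 1]


def rhs_printed(
    c: np.ndarray, params: KineticParams, literal: bool = False
) -> np.ndarray:
    if params.variant is Variant.AGGREGATION:
        return aggregation_rhs_printed(c, params, literal=literal)
    if params.variant is Variant.CLUSTERING:
        return clustering_rhs_printed(c, params, literal=literal)
    raise ValueError("no written-out expansion exists for the two_equation variant")


def discrepancy_report(network: ReactionNetwork, c: np.ndarray) -> dict:
    """Compare the network RHS against both transcriptions at a given state.

    Returns the maximum absolute deviation of the corrected transcription
    (expected: round-off) and of the literal one (expected: the documented
    defects), together with the catalogue of known printed discrepancies
    for the network's variant.
    """
    c = np.asarray(c, dtype=float)
    ref = network.rhs(c)
    corrected = rhs_printed(c, network.params, literal=False)
    literal = rhs_printed(c, network.params, literal=True)
    return {
        "variant": network.variant.value,
        "N": network.N,
        "max_abs_dev_corrected": float(np.max(np.abs(ref - corrected))),
        "max_abs_dev_literal": float(np.max(np.abs(ref - literal))),
        "known_discrepancies": [
            d for d in DISCREPANCIES if d["variant"] == network.variant.value
        ],
    }
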