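"""Rank-1 principal-component suppression of fine wavelet detail bands.

Global, redundant structure (and most of the white noise) in an expression
profile lives in the first — finest — detail bands of the per-sample DWT.
Suppression replaces each detail coefficient matrix D_j with j <= tau by its
rank-1 PCA reconstruction: samples are observations, coefficients are
variables, the matrix is column-centered, projected on its first principal
direction, and the column means are added back.  Everything above the
threshold (j > tau) and the approximation matrix are kept verbatim — a full
reconstruction at 100% explained variance is the identity, so the "lazy"
keep-it-all rule is exact, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateVarianceError
from .wavelet import WaveletDecomposition

DEFAULT_TAU = 3


@dataclass(frozen=True)
class SuppressionPolicy:
    """Level threshold tau: bands 1..tau are rank-1 suppressed, the rest kept.

    tau = 0 disables suppression entirely.
    """

    tau: int = DEFAULT_TAU

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


def explained_variance_percentage(eigenvalues, r: int) -> float:
    """Cumulative fraction of variance captured by the first r eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    if not (0 <= r <= lam.size):
        raise ValueError(f"r={r} outside [0, {lam.size}]")
    # tolerate the tiny negative eigenvalues numerical symmetric solvers emit
    if np.any(lam < -1e-10 * max(lam.max(initial=0.0), 1.0)):
        raise ValueError("eigenvalues must be nonnegative")
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total == 0:
        raise DegenerateVarianceError("all eigenvalues are zero")
    return float(lam[:r].sum() / total)


def pca_rank1_reconstruct(D: np.ndarray) -> np.ndarray:
    """Project D onto its first principal direction (plus column means).

    Columns are centered by their means mu; the centered matrix is replaced by
    (score along u_1) u_1^T and the means are re-added through the all-ones
    vector.  Degenerate inputs — a single row, or a band with zero variance —
    pass through unchanged: suppressing a deterministic band is a no-op.
    """
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("rank-1 reconstruction requires finite input")
    mu = D.mean(axis=0)
    centered = D - mu
    if D.shape[0] == 1 or not np.any(centered):
        return D.copy()
    # right singular vectors = principal directions over coefficient columns
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u1 = vt[0]
    # canonical sign: largest-magnitude entry positive (byte-stable output)
    if u1[np.argmax(np.abs(u1))] < 0:
        u1 = -u1
    score = centered @ u1
    return np.outer(score, u1) + mu


def apply_suppression(decomp: WaveletDecomposition,
                      policy: SuppressionPolicy) -> WaveletDecomposition:
    """Return a new decomposition with bands 1..tau rank-1 suppressed.

    The input decomposition is not mutated.  Idempotent for a fixed tau: the
    rank-1 reconstruction is a projection.
    """
    if policy.tau > decomp.level:
        raise ValueError(f"tau={policy.tau} exceeds decomposition level {decomp.level}")
    out = decomp.copy()
    for j in range(policy.tau):
        out.details[j] = pca_rank1_reconstruct(out.details[j])
    return out
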