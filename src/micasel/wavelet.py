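"""Per-sample multilevel discrete wavelet transform and its exact inverse.

Each sample (row) of the expression matrix is treated as a 1-D signal along
the gene axis and decomposed with a multilevel DWT.  Level indexing follows
the filter-bank order: level 1 is the FIRST decomposition step, i.e. the
highest-frequency detail band; level L is the last, coarsest detail band.  The
final approximation band sits below level L.

Only orthogonal wavelets are supported by default; the biorthogonal family can
be enabled explicitly (``allow_nonorthogonal=True``) since perfect
reconstruction still holds, but the energy partition does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .exceptions import ConsistencyError
from .profile import ExpressionProfile

logger = logging.getLogger(__name__)

DEFAULT_WAVELET = "db8"
DEFAULT_LEVEL = 12
DEFAULT_MODE = "symmetric"


@dataclass
class WaveletDecomposition:
    """Multilevel DWT of a ``p x n`` profile.

    ``details[j-1]`` is D_j, the level-j detail coefficient matrix (level 1 =
    finest / highest frequency); ``approx`` is the final approximation matrix.
    All matrices have p rows; per-level column counts follow the filter-bank
    cascade for the chosen wavelet and extension mode.
    """

    wavelet_name: str
    level: int
    details: list[np.ndarray]
    approx: np.ndarray
    extension_mode: str
    original_n: int

    @property
    def n_samples(self) -> int:
        return self.approx.shape[0]

    def coeff_lengths(self) -> tuple[list[int], int]:
        """Expected (detail lengths for levels 1..L, approximation length)."""
        wav = pywt.Wavelet(self.wavelet_name)
        lengths = []
        n = self.original_n
        for _ in range(self.level):
            n = pywt.dwt_coeff_len(n, wav.dec_len, self.extension_mode)
            lengths.append(n)
        return lengths, n

    def validate(self) -> None:
        lengths, approx_len = self.coeff_lengths()
        p = self.n_samples
        if self.approx.shape != (p, approx_len):
            raise ConsistencyError(
                f"approximation matrix has shape {self.approx.shape}, "
                f"expected ({p}, {approx_len})")
        if len(self.details) != self.level:
            raise ConsistencyError(
                f"{len(self.details)} detail matrices for level {self.level}")
        for j, (D, m) in enumerate(zip(self.details, lengths), start=1):
            if D.shape != (p, m):
                raise ConsistencyError(
                    f"detail matrix D_{j} has shape {D.shape}, expected ({p}, {m})")

    def copy(self) -> "WaveletDecomposition":
        return WaveletDecomposition(
            wavelet_name=self.wavelet_name,
            level=self.level,
            details=[D.copy() for D in self.details],
            approx=self.approx.copy(),
            extension_mode=self.extension_mode,
            original_n=self.original_n,
        )


def _check_wavelet(wavelet_name: str, allow_nonorthogonal: bool) -> pywt.Wavelet:
    try:
        wav = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet_name!r}") from exc
    if not wav.orthogonal and not allow_nonorthogonal:
        raise ValueError(
            f"wavelet {wavelet_name!r} is not orthogonal; pass "
            f"allow_nonorthogonal=True to use it anyway")
    return wav


def max_level(n: int, wavelet_name: str) -> int:
    """Deepest decomposition level supported for signals of length n."""
    wav = pywt.Wavelet(wavelet_name)
    return max(pywt.dwt_max_level(n, wav.dec_len), 1)


def decompose(profile, wavelet_name: str = DEFAULT_WAVELET,
              level: int = DEFAULT_LEVEL,
              extension_mode: str = DEFAULT_MODE,
              allow_nonorthogonal: bool = False) -> WaveletDecomposition:
    """L-level DWT of every sample of the profile along the gene axis.

    A requested depth beyond what the signal length and filter support is
    capped to the maximum valid depth (with a logged warning), so the default
    12-level transform is usable on profiles of any width.
    """
    values = profile.values if isinstance(profile, ExpressionProfile) else \
        np.atleast_2d(np.asarray(profile, dtype=float))
    wav = _check_wavelet(wavelet_name, allow_nonorthogonal)
    n = values.shape[1]
    if n < wav.dec_len:
        raise ValueError(
            f"signal length {n} shorter than the {wavelet_name!r} filter "
            f"({wav.dec_len} taps)")
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    cap = max_level(n, wavelet_name)
    if level > cap:
        logger.warning("requested level %d exceeds maximum %d for n=%d with %s; "
                       "capping", level, cap, n, wavelet_name)
        level = cap
    coeffs = pywt.wavedec(values, wav, mode=extension_mode, level=level, axis=1)
    # pywt returns [cA_L, cD_L, ..., cD_1]; store details as [D_1, ..., D_L]
    details = list(reversed(coeffs[1:]))
    return WaveletDecomposition(
        wavelet_name=wavelet_name,
        level=level,
        details=details,
        approx=coeffs[0],
        extension_mode=extension_mode,
        original_n=n,
    )


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse DWT back to a ``p x original_n`` matrix (exact for untouched
    coefficients; boundary padding is trimmed)."""
    decomp.validate()
    coeffs = [decomp.approx] + list(reversed(decomp.details))
    out = pywt.waverec(coeffs, pywt.Wavelet(decomp.wavelet_name),
                       mode=decomp.extension_mode, axis=1)
    return out[:, :decomp.original_n]
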