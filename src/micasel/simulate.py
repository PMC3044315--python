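"""Synthetic two-class expression profiles with controlled structure.

Real tumor profiles motivating this package share smooth genome-wide expression
structure between classes while differing in *localized* groups of genes; on
top of that sits sample-level technical variation common to all genes (array
effects) and per-measurement noise.  The generator makes that premise literal:

    sample = shared smooth baseline            (low-order cosines over genes)
           + per-sample global shift           (class-independent confound)
           + class-specific block signal       (class +1 only, chosen windows)
           + i.i.d. Gaussian noise

Every draw is a pure function of the spec, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile import ExpressionProfile

#: Default gene windows carrying class signal: three blocks, each ~n/32 genes
#: wide, starting at 10%, 40% and 70% of the gene axis (32 genes each at the
#: default n=1024).
DEFAULT_BLOCK_FRACTIONS = (0.1, 0.4, 0.7)
DEFAULT_BLOCK_WIDTH_FRACTION = 1.0 / 32.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class generator.

    effect_size is the mean shift inside signal blocks in units of noise_sd;
    global_shift is the standard deviation of the per-sample (class-shared)
    additive confound, also in raw units.
    """

    p_per_class: int = 30
    n: int = 1024
    baseline_smoothness: int = 5
    block_starts: tuple[int, ...] | None = None
    block_lengths: tuple[int, ...] | None = None
    effect_size: float = 3.0
    global_shift: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_per_class <= 0 or self.n <= 0:
            raise ValueError("p_per_class and n must be positive")
        if self.block_starts is None:
            width = max(1, round(self.n * DEFAULT_BLOCK_WIDTH_FRACTION))
            object.__setattr__(self, "block_starts", tuple(
                int(f * self.n) for f in DEFAULT_BLOCK_FRACTIONS))
            object.__setattr__(self, "block_lengths",
                               (width,) * len(DEFAULT_BLOCK_FRACTIONS))
        if self.block_lengths is None:
            raise ValueError("block_lengths required when block_starts is given")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.block_starts) != len(self.block_lengths):
            raise ValueError("block_starts and block_lengths must have equal length")
        for s, w in zip(self.block_starts, self.block_lengths):
            if s < 0 or w <= 0 or s + w > self.n:
                raise ValueError(f"block [{s}, {s + w}) outside gene range [0, {self.n})")


def block_mask(spec: SyntheticSpec) -> np.ndarray:
    """Boolean mask over genes marking the class-signal windows."""
    mask = np.zeros(spec.n, dtype=bool)
    for s, w in zip(spec.block_starts, spec.block_lengths):
        mask[s:s + w] = True
    return mask


def generate_two_class_profile(spec: SyntheticSpec) -> ExpressionProfile:
    """Draw a labelled 2*p_per_class x n profile from the generative model.

    Controls (label -1) come first, cancers (label +1) second.  Only class +1
    receives the block signal, so class-conditional means differ exactly on the
    block windows.
    """
    rng = np.random.default_rng(spec.seed)
    p = 2 * spec.p_per_class
    t = np.arange(spec.n) / spec.n

    baseline = np.zeros(spec.n)
    for m in range(1, spec.baseline_smoothness + 1):
        amp = rng.normal(0.0, 2.0 / m)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        baseline += amp * np.cos(2.0 * np.pi * m * t + phase)

    shifts = rng.normal(0.0, spec.global_shift, size=p) if spec.global_shift > 0 \
        else np.zeros(p)
    noise = rng.normal(0.0, spec.noise_sd, size=(p, spec.n))

    values = baseline[None, :] + shifts[:, None] + noise
    labels = np.repeat([-1, 1], spec.p_per_class)
    values[labels == 1] += (spec.effect_size * spec.noise_sd) * block_mask(spec)

    width = len(str(p))
    sample_ids = [f"ctrl_{i + 1:0{width}d}" for i in range(spec.p_per_class)] + \
                 [f"case_{i + 1:0{width}d}" for i in range(spec.p_per_class)]
    gene_ids = [f"g{j + 1:05d}" for j in range(spec.n)]
    return ExpressionProfile(values, sample_ids, gene_ids, labels)


def planted_marker_spec(seed: int, n_nulls: int = 500,
                        effect_size: float = 4.0) -> SyntheticSpec:
    """Fixture for biomarker-recovery studies: three single-gene markers
    hidden among ``n_nulls`` null genes.

    The global confound is kept weak (0.3 x noise) so that pairs of true
    markers saturate a wrapper classifier and recovery is limited by the
    filter ranking rather than by overlap between the classes.
    """
    n = n_nulls + 3
    starts = (n // 10, n // 2, (9 * n) // 10)
    return SyntheticSpec(p_per_class=30, n=n, block_starts=starts,
                         block_lengths=(1, 1, 1), effect_size=effect_size,
                         global_shift=0.3, noise_sd=1.0, seed=seed)


# fixed low-order cosine signal used by the denoising fixture; deterministic so
# the "clean" target is identical across seeds
_CLEAN_AMPLITUDES = (5.0, 4.0, 3.0, 2.0, 1.0)
_CLEAN_PHASES = (0.0, 0.9, 1.7, 2.6, 3.4)


def generate_denoising_fixture(n: int, noise_sd: float, seed: int
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Return (clean, noisy): a smooth signal and a noise-corrupted copy.

    The clean signal is a fixed sum of five low-order cosines, so its energy
    lives in the coarse wavelet bands; white noise spreads uniformly across
    bands, which is what makes fine-band suppression act as a denoiser.
    """
    if n < 64:
        raise ValueError("n must be at least 64")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    t = np.arange(n) / n
    clean = np.zeros(n)
    for m, (amp, phase) in enumerate(zip(_CLEAN_AMPLITUDES, _CLEAN_PHASES), start=1):
        clean += amp * np.cos(2.0 * np.pi * m * t + phase)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else clean.copy()
    return clean, noisy


def generate_denoising_profile(n: int, noise_sd: float, seed: int,
                               n_replicates: int = 6) -> tuple[np.ndarray, ExpressionProfile]:
    """Stack independent noisy replicates of the same clean signal as a profile.

    The fine-band suppression is a cross-sample principal-component operation,
    so exercising its denoising behaviour needs several replicate samples; a
    single sample passes through rank-1 suppression unchanged.
    """
    clean, _ = generate_denoising_fixture(n, noise_sd, seed)
    rng = np.random.default_rng(seed)
    values = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, n))
    prof = ExpressionProfile(values,
                             [f"rep_{i + 1}" for i in range(n_replicates)],
                             [f"g{j + 1:05d}" for j in range(n)])
    return clean, prof
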