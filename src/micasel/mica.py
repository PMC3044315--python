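"""Multi-resolution ICA: wavelet suppression + independent component basis.

The transform chains four stages: (1) per-sample multilevel DWT along the
gene axis, (2) rank-1 PCA suppression of the tau finest detail bands, (3)
inverse DWT giving the denoised meta-profile X*, and (4) FastICA on X* so that

    X*  =  offset  +  A Z

where the rows of Z (k x n) are statistically independent basis signals over
genes ("eigen-genes") and row i of the mixing matrix A (p x k) is the
*meta-sample* of biological sample i — its coordinates in the independent
basis, and the low-dimensional representation all classifiers here consume.

Scale convention: FastICA's unit-variance source normalization would make Z
exactly white, collapsing the condition number delta = S_max(Z)/S_min(Z) to 1
for every threshold and leaving nothing to select tau with.  We therefore
normalize the columns of A to unit Euclidean norm and carry each component's
scale on its row of Z, so delta measures how unevenly energy is spread across
components — a small delta is a well-balanced, stable basis.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from . import suppression, wavelet
from .exceptions import AlignmentError, ConvergenceError, RankError
from .profile import ExpressionProfile

logger = logging.getLogger(__name__)

DEFAULT_ICA_TOL = 1e-4
DEFAULT_ICA_MAX_ITER = 400
DEFAULT_ICA_RESTARTS = 5
_RANK_RTOL = 1e-10
_RESTART_STRIDE = 0x9E3779B1  # odd constant decorrelating restart seeds


@dataclass
class MetaProfile:
    """The denoised approximation X* of an input profile (same shape)."""

    values: np.ndarray
    wavelet_name: str
    level: int
    tau: int


@dataclass
class MICAModel:
    """Fitted multi-resolution ICA transform.

    Z : (k, n) independent component matrix, rows sign-canonicalized
        (largest-magnitude entry positive) and ordered by decreasing energy.
    A : (p, k) mixing matrix; row i is sample i's meta-sample.
    offset : (n,) mean meta-profile removed before ICA and re-added in
        reconstructions: X* = offset + A Z.
    delta : condition number S_max/S_min of Z (+inf if Z is rank deficient).
    """

    Z: np.ndarray
    A: np.ndarray
    offset: np.ndarray
    k: int
    delta: float
    wavelet_name: str
    level: int
    tau: int
    extension_mode: str
    seed: int
    ica_tolerance: float
    ica_max_iter: int
    n_iter: int
    gene_ids: list[str]
    sample_ids: list[str]


def condition_number(Z: np.ndarray) -> float:
    """S_max / S_min over the singular values of Z; +inf when S_min == 0."""
    Z = np.asarray(Z, dtype=float)
    if not np.any(Z):
        raise ValueError("condition number of an all-zero matrix is undefined")
    s = np.linalg.svd(Z, compute_uv=False)
    # numerically zero smallest singular value -> documented infinity sentinel
    if s[-1] <= s[0] * max(Z.shape) * np.finfo(float).eps:
        return float("inf")
    return float(s[0] / s[-1])


def _run_fastica_once(whitened: np.ndarray, seed: int, tol: float,
                      max_iter: int) -> tuple[np.ndarray, int, bool]:
    ica = FastICA(whiten=False, fun="logcosh", tol=tol, max_iter=max_iter,
                  random_state=np.random.RandomState(seed))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(whitened.T)
    converged = not any(issubclass(w.category, ConvergenceWarning)
                        for w in caught)
    return np.asarray(ica.components_), int(ica.n_iter_), converged


def _run_fastica(whitened: np.ndarray, seed: int, tol: float, max_iter: int,
                 restarts: int = DEFAULT_ICA_RESTARTS,
                 on_nonconvergence: str = "warn") -> tuple[np.ndarray, int]:
    """Fixed-point ICA rotation of pre-whitened (k, n) data.

    The symmetric fixed point can oscillate indefinitely when some whitened
    directions are essentially Gaussian (no independent structure to lock
    onto), so up to ``restarts`` deterministic re-initializations (seeds
    derived from ``seed``) are attempted.  If none meets the tolerance the
    default policy keeps the first attempt's final rotation with a logged
    warning — the rotation is still orthogonal, so downstream algebra is
    unaffected and only approximate independence is lost;
    ``on_nonconvergence="raise"`` turns this into a ConvergenceError with
    iteration diagnostics instead.  Returns (W, iteration count).
    """
    if on_nonconvergence not in ("warn", "raise"):
        raise ValueError(f"unknown policy {on_nonconvergence!r}")
    fallback: tuple[np.ndarray, int] | None = None
    for r in range(restarts):
        attempt_seed = int((seed + r * _RESTART_STRIDE) % (2**31 - 1))
        W, n_iter, converged = _run_fastica_once(whitened, attempt_seed, tol,
                                                 max_iter)
        if converged:
            if r:
                logger.info("FastICA converged on restart %d", r)
            return W, n_iter
        if fallback is None:
            fallback = (W, n_iter)
        logger.info("FastICA attempt %d/%d did not converge (%d iters)",
                    r + 1, restarts, n_iter)
    if on_nonconvergence == "raise":
        raise ConvergenceError(
            f"FastICA failed to converge in {restarts} restarts of {max_iter} "
            f"iterations (tol={tol:g}); consider loosening ica_tolerance",
            n_iter=fallback[1] if fallback else None)
    logger.warning("FastICA did not meet tol=%g in %d restarts x %d "
                   "iterations; keeping the final rotation", tol, restarts,
                   max_iter)
    return fallback


def ica_decompose(values: np.ndarray, k, seed: int,
                  tol: float = DEFAULT_ICA_TOL,
                  max_iter: int = DEFAULT_ICA_MAX_ITER,
                  restarts: int = DEFAULT_ICA_RESTARTS,
                  on_nonconvergence: str = "warn"
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Classic ICA of a (p, n) matrix into offset + A Z.

    The mean row (offset) is removed, the residual is whitened by SVD to at
    most k = min(k, rank) dimensions, and the FastICA fixed point supplies the
    rotation.  Columns of A are normalized to unit norm with component scale
    carried on the rows of Z (see module docstring).
    """
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    offset = values.mean(axis=0)
    centered = values - offset

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * _RANK_RTOL)) if s[0] > 0 else 0
    if rank == 0:
        raise RankError("profile has no variation across samples")
    k_req = (p - 1) if (k is None or k == "auto") else int(k)
    if not (1 <= k_req <= p):
        raise ValueError(f"k={k_req} outside [1, p={p}]")
    k_eff = min(k_req, rank)
    if k_eff < k_req:
        logger.warning("requested k=%d capped at whitening rank %d", k_req, k_eff)

    whitened = vt[:k_eff] * np.sqrt(n)  # rows with unit mean-square
    W, n_iter = _run_fastica(whitened, seed, tol, max_iter, restarts,
                             on_nonconvergence)
    Z = W @ whitened  # (k, n), unit-variance rows (W orthogonal)

    # least-squares mixing matrix, then move component scale onto Z
    G = Z @ Z.T
    A = np.linalg.solve(G, Z @ centered.T).T
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise RankError("degenerate mixing matrix: zero-norm column")
    A = A / norms
    Z = Z * norms[:, None]

    # canonical sign per component, then order by decreasing energy
    for i in range(k_eff):
        if Z[i, np.argmax(np.abs(Z[i]))] < 0:
            Z[i] = -Z[i]
            A[:, i] = -A[:, i]
    energy = np.linalg.norm(A, axis=0) * np.linalg.norm(Z, axis=1)
    order = np.argsort(-energy, kind="stable")
    return offset, A[:, order], Z[order], n_iter


def fit_mica(profile: ExpressionProfile,
             wavelet_name: str = wavelet.DEFAULT_WAVELET,
             level: int = wavelet.DEFAULT_LEVEL,
             tau: int = suppression.DEFAULT_TAU,
             k="auto",
             seed: int = 0,
             extension_mode: str = wavelet.DEFAULT_MODE,
             ica_tolerance: float = DEFAULT_ICA_TOL,
             ica_max_iter: int = DEFAULT_ICA_MAX_ITER,
             ica_restarts: int = DEFAULT_ICA_RESTARTS,
             on_nonconvergence: str = "warn",
             allow_nonorthogonal: bool = False
             ) -> tuple[MICAModel, MetaProfile]:
    """Fit the multi-resolution ICA transform to a labelled or unlabelled profile.

    The requested decomposition depth is capped at the maximum the gene count
    supports; ``tau`` must not exceed the capped depth.  The whole fit is a
    pure function of (profile, parameters, seed).
    """
    if profile.n_samples < 3:
        raise ValueError("MICA needs at least 3 samples")
    decomp = wavelet.decompose(profile, wavelet_name, level, extension_mode,
                               allow_nonorthogonal)
    if tau > decomp.level:
        raise ValueError(
            f"tau={tau} exceeds the usable decomposition depth {decomp.level} "
            f"for n={profile.n_genes} genes")
    suppressed = suppression.apply_suppression(decomp,
                                               suppression.SuppressionPolicy(tau))
    meta_values = wavelet.reconstruct(suppressed)
    meta = MetaProfile(meta_values, wavelet_name, decomp.level, tau)

    offset, A, Z, n_iter = ica_decompose(meta_values, k, seed,
                                         ica_tolerance, ica_max_iter,
                                         ica_restarts, on_nonconvergence)
    model = MICAModel(
        Z=Z, A=A, offset=offset, k=Z.shape[0], delta=condition_number(Z),
        wavelet_name=wavelet_name, level=decomp.level, tau=tau,
        extension_mode=extension_mode, seed=seed,
        ica_tolerance=ica_tolerance, ica_max_iter=ica_max_iter, n_iter=n_iter,
        gene_ids=list(profile.gene_ids), sample_ids=list(profile.sample_ids),
    )
    return model, meta


def meta_samples(model: MICAModel) -> np.ndarray:
    """The p x k matrix of meta-samples (rows of the mixing matrix)."""
    return model.A.copy()


def meta_features(model: MICAModel) -> np.ndarray:
    """Meta-samples in the classic ICA scale, for classification.

    Rescaling each mixing-matrix column by its component's energy recovers
    the mixing matrix of unit-variance sources: components that carry more
    of the meta-profile's structure get proportionally larger coordinates.
    Classifiers train on this scale — under the unit-column convention a
    weak noise component would span the same numeric range as the dominant
    structure and distort the soft margin.
    """
    return model.A * np.linalg.norm(model.Z, axis=1)


def project_features(model: MICAModel, new_profile: ExpressionProfile) -> np.ndarray:
    """Classic-scale coordinates of new samples (see :func:`meta_features`)."""
    return project_samples(model, new_profile) * np.linalg.norm(model.Z, axis=1)


def transform_meta_values(model: MICAModel, values: np.ndarray) -> np.ndarray:
    """Wavelet-suppress new raw samples with the model's parameters."""
    decomp = wavelet.decompose(values, model.wavelet_name, model.level,
                               model.extension_mode, allow_nonorthogonal=True)
    suppressed = suppression.apply_suppression(
        decomp, suppression.SuppressionPolicy(model.tau))
    return wavelet.reconstruct(suppressed)


def project_samples(model: MICAModel, new_profile: ExpressionProfile) -> np.ndarray:
    """Meta-samples for new profiles: least-squares coordinates in the Z basis.

    New samples go through the model's wavelet suppression, the stored offset
    is removed, and each sample's coordinates solve
    ``argmin_a || x* - offset - a Z ||^2``.  For the training profile this
    reproduces the stored mixing matrix (training rows lie in the span of Z).
    """
    if list(new_profile.gene_ids) != list(model.gene_ids):
        raise AlignmentError("gene ids of the new profile do not match the model")
    meta_values = transform_meta_values(model, new_profile.values)
    centered = meta_values - model.offset
    G = model.Z @ model.Z.T
    try:
        coords = np.linalg.solve(G, model.Z @ centered.T)
    except np.linalg.LinAlgError as exc:
        raise RankError("Z Z^T is singular; cannot project") from exc
    return coords.T


def resolve_optimal_tau(deltas: dict[int, float], tie_rtol: float = 1e-6) -> int:
    """Smallest-delta threshold with the documented tie rule.

    Thresholds whose delta is within ``tie_rtol`` (relative) of the minimum
    are tied; among ties the LOWEST threshold strictly greater than 1 wins
    (falling back to the lowest tie if none exceeds 1).
    """
    if not deltas:
        raise ValueError("empty delta map")
    finite = {t: d for t, d in deltas.items() if np.isfinite(d)}
    if not finite:
        raise ValueError("all condition numbers are infinite")
    dmin = min(finite.values())
    tied = sorted(t for t, d in finite.items() if d - dmin <= tie_rtol * dmin)
    above_one = [t for t in tied if t > 1]
    return above_one[0] if above_one else tied[0]


def select_level_threshold(profile: ExpressionProfile,
                           candidate_taus,
                           wavelet_name: str = wavelet.DEFAULT_WAVELET,
                           level: int = wavelet.DEFAULT_LEVEL,
                           k="auto",
                           seed: int = 0,
                           tie_rtol: float = 1e-6,
                           **fit_kwargs) -> tuple[int, dict[int, float]]:
    """Pick the level threshold with the smallest condition number of Z.

    Fits one model per candidate tau (all with the same seed) and applies the
    tie rule of :func:`resolve_optimal_tau`.  Returns the winner and the full
    tau -> delta map for reporting.
    """
    candidates = list(candidate_taus)
    if not candidates:
        raise ValueError("candidate_taus must be nonempty")
    deltas: dict[int, float] = {}
    failures: list[str] = []
    for tau in candidates:
        try:
            model, _ = fit_mica(profile, wavelet_name=wavelet_name, level=level,
                                tau=tau, k=k, seed=seed, **fit_kwargs)
            deltas[tau] = model.delta
        except (ConvergenceError, ValueError) as exc:
            failures.append(f"tau={tau}: {exc}")
            logger.warning("threshold candidate failed: %s", failures[-1])
    if not deltas:
        raise ConvergenceError(
            "every candidate threshold failed to fit: " + "; ".join(failures))
    return resolve_optimal_tau(deltas, tie_rtol), deltas


# --------------------------------------------------------------------------
# serialization (single JSON document; arrays as nested lists)

def model_to_dict(model: MICAModel) -> dict:
    return {
        "format": "micasel-model-v1",
        "wavelet_name": model.wavelet_name,
        "level": model.level,
        "tau": model.tau,
        "extension_mode": model.extension_mode,
        "seed": model.seed,
        "ica_tolerance": model.ica_tolerance,
        "ica_max_iter": model.ica_max_iter,
        "n_iter": model.n_iter,
        "k": model.k,
        "delta": model.delta,
        "gene_ids": list(model.gene_ids),
        "sample_ids": list(model.sample_ids),
        "offset": model.offset.tolist(),
        "A": model.A.tolist(),
        "Z": model.Z.tolist(),
    }


def model_from_dict(d: dict) -> MICAModel:
    if d.get("format") != "micasel-model-v1":
        raise ValueError(f"unrecognized model format {d.get('format')!r}")
    return MICAModel(
        Z=np.asarray(d["Z"], dtype=float),
        A=np.asarray(d["A"], dtype=float),
        offset=np.asarray(d["offset"], dtype=float),
        k=int(d["k"]), delta=float(d["delta"]),
        wavelet_name=d["wavelet_name"], level=int(d["level"]), tau=int(d["tau"]),
        extension_mode=d["extension_mode"], seed=int(d["seed"]),
        ica_tolerance=float(d["ica_tolerance"]),
        ica_max_iter=int(d["ica_max_iter"]), n_iter=int(d["n_iter"]),
        gene_ids=list(d["gene_ids"]), sample_ids=list(d["sample_ids"]),
    )


def save_model(model: MICAModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, sort_keys=True)


def load_model(path) -> MICAModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
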