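"""Classifiers over meta-samples and baseline feature spaces.

Methods
-------
``mica-svm`` / ``mica-lda``
    Fit the multi-resolution ICA transform on the training profile, then a
    linear-kernel soft-margin SVM (or LDA) on the meta-samples.
``svm`` / ``lda``
    The same classifiers on the raw gene space (no feature extraction).
``pca-svm`` / ``ica-svm`` / ``pca-lda``
    Single-resolution PCA or classic ICA feature extraction at the same
    component count as MICA would use, for like-for-like comparison.

Only the linear kernel is enabled for the SVM variants by default; the
Gaussian kernel reliably overfits profiles with far more genes than samples
(every sample becomes a support vector) and must be opted into explicitly.

Modes: *inductive* (default) fits the feature transform on training data only
and projects test samples through it; *transductive* refits the transform on
pooled train+test data at prediction time and splits the mixing-matrix rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from . import mica
from .exceptions import AlignmentError, MicaselError
from .profile import ExpressionProfile

logger = logging.getLogger(__name__)

METHODS = ("mica-svm", "mica-lda", "svm", "lda", "pca-svm", "ica-svm", "pca-lda")
_MICA_METHODS = ("mica-svm", "mica-lda")
_SVM_METHODS = ("mica-svm", "svm", "pca-svm", "ica-svm")


@dataclass
class PCAFeatureModel:
    """PCA feature extractor (samples x genes in, samples x k out)."""

    pca: PCA
    gene_ids: list[str]

    def project(self, profile: ExpressionProfile) -> np.ndarray:
        _check_genes(self.gene_ids, profile)
        return self.pca.transform(profile.values)


@dataclass
class ICAFeatureModel:
    """Classic (single-resolution) ICA extractor sharing MICA's conventions."""

    Z: np.ndarray
    offset: np.ndarray
    gene_ids: list[str]

    def project(self, profile: ExpressionProfile) -> np.ndarray:
        _check_genes(self.gene_ids, profile)
        centered = profile.values - self.offset
        coords = np.linalg.solve(self.Z @ self.Z.T, self.Z @ centered.T).T
        return coords * np.linalg.norm(self.Z, axis=1)


@dataclass
class MICAFeatureModel:
    model: mica.MICAModel

    def project(self, profile: ExpressionProfile) -> np.ndarray:
        return mica.project_features(self.model, profile)


def _check_genes(gene_ids, profile: ExpressionProfile) -> None:
    if list(gene_ids) != list(profile.gene_ids):
        raise AlignmentError("gene ids do not match the fitted feature model")


@dataclass
class TrainedClassifier:
    method: str
    estimator: object  # fitted SVC or LinearDiscriminantAnalysis
    feature_model: object | None
    mode: str
    C: float
    params: dict = field(default_factory=dict)
    train_profile: ExpressionProfile | None = None  # kept for transductive mode


def _fit_estimator(method: str, features: np.ndarray, labels: np.ndarray,
                   C: float, kernel: str):
    if method in _SVM_METHODS:
        est = SVC(kernel=kernel, C=C)
        est.fit(features, labels)
        return est
    est = LinearDiscriminantAnalysis()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collinearity chatter on wide data
            est.fit(features, labels)
        if not np.all(np.isfinite(est.coef_)):
            raise np.linalg.LinAlgError("non-finite LDA coefficients")
    except np.linalg.LinAlgError:
        logger.warning("LDA scatter degenerate; falling back to shrinkage LDA")
        est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        est.fit(features, labels)
    return est


def _fit_features(profile: ExpressionProfile, method: str, *,
                  wavelet_name, level, tau, k, seed, extension_mode,
                  ica_tolerance, ica_max_iter):
    """Feature extractor + training feature matrix for the given method."""
    if method in ("svm", "lda"):
        return None, profile.values
    if method in _MICA_METHODS:
        model, _ = mica.fit_mica(profile, wavelet_name=wavelet_name, level=level,
                                 tau=tau, k=k, seed=seed,
                                 extension_mode=extension_mode,
                                 ica_tolerance=ica_tolerance,
                                 ica_max_iter=ica_max_iter)
        return MICAFeatureModel(model), mica.meta_features(model)
    p = profile.n_samples
    k_eff = (p - 1) if (k is None or k == "auto") else int(k)
    k_eff = min(k_eff, p - 1, profile.n_genes)
    if method.startswith("pca"):
        pca = PCA(n_components=k_eff, random_state=seed)
        feats = pca.fit_transform(profile.values)
        return PCAFeatureModel(pca, list(profile.gene_ids)), feats
    if method == "ica-svm":
        offset, A, Z, _ = mica.ica_decompose(profile.values, k_eff, seed,
                                             ica_tolerance, ica_max_iter)
        feats = A * np.linalg.norm(Z, axis=1)  # classic-scale coordinates
        return ICAFeatureModel(Z, offset, list(profile.gene_ids)), feats
    raise ValueError(f"unknown method {method!r}")


def train_classifier(profile: ExpressionProfile, method: str = "mica-svm", *,
                     wavelet_name: str = "db8", level: int = 12, tau: int = 3,
                     k="auto", C: float = 1.0, seed: int = 0,
                     mode: str = "inductive",
                     extension_mode: str = "symmetric",
                     ica_tolerance: float = mica.DEFAULT_ICA_TOL,
                     ica_max_iter: int = mica.DEFAULT_ICA_MAX_ITER,
                     kernel: str = "linear",
                     allow_rbf: bool = False) -> TrainedClassifier:
    """Train any of the supported classifiers on a labelled profile."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if mode not in ("inductive", "transductive"):
        raise ValueError(f"unknown mode {mode!r}")
    if kernel != "linear" and not allow_rbf:
        raise ValueError(
            "non-linear SVM kernels overfit wide expression profiles and are "
            "disabled; pass allow_rbf=True to override")
    labels = profile.require_labels()
    if C <= 0:
        raise ValueError("C must be positive")

    params = dict(wavelet_name=wavelet_name, level=level, tau=tau, k=k,
                  seed=seed, extension_mode=extension_mode,
                  ica_tolerance=ica_tolerance, ica_max_iter=ica_max_iter)
    feature_model, features = _fit_features(profile, method, **params)
    estimator = _fit_estimator(method, features, labels, C, kernel)
    return TrainedClassifier(
        method=method, estimator=estimator, feature_model=feature_model,
        mode=mode, C=C, params=params,
        train_profile=profile if (mode == "transductive" and method in _MICA_METHODS)
        else None,
    )


def decision_values(clf: TrainedClassifier, profile: ExpressionProfile) -> np.ndarray:
    """Signed decision-function values; positive means class +1."""
    if clf.mode == "transductive" and clf.method in _MICA_METHODS:
        return _transductive_decision(clf, profile)
    if clf.feature_model is None:
        feats = profile.values
        if profile.n_genes != clf.estimator.n_features_in_:
            raise AlignmentError("gene count does not match the trained classifier")
    else:
        feats = clf.feature_model.project(profile)
    return np.asarray(clf.estimator.decision_function(feats), dtype=float)


def _transductive_decision(clf: TrainedClassifier,
                           profile: ExpressionProfile) -> np.ndarray:
    """Refit MICA on pooled train+test rows, retrain the rule on train rows."""
    train = clf.train_profile
    if train is None:
        raise MicaselError("transductive classifier lost its training profile")
    if list(train.gene_ids) != list(profile.gene_ids):
        raise AlignmentError("gene ids do not match the training profile")
    pooled = ExpressionProfile(
        np.vstack([train.values, profile.values]),
        list(train.sample_ids) + [f"test::{s}" for s in profile.sample_ids],
        list(train.gene_ids))
    model, _ = mica.fit_mica(pooled, **clf.params)
    A = mica.meta_features(model)
    n_train = train.n_samples
    est = _fit_estimator(clf.method, A[:n_train], train.labels, clf.C, "linear")
    return np.asarray(est.decision_function(A[n_train:]), dtype=float)


def predict_labels(clf: TrainedClassifier, profile: ExpressionProfile) -> np.ndarray:
    """Predict {+1, -1} labels; a decision value of exactly 0 maps to +1."""
    d = decision_values(clf, profile)
    return np.where(d >= 0, 1, -1)
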