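"""Confusion-matrix metrics and cross-validation protocols.

Two protocols are provided, matching common practice for small expression
cohorts: repeated 50% holdout (many random half splits, classifier refit from
scratch each time) and k-fold CV (seeded random partition into near-equal
folds).  In inductive mode the feature transform is refit inside every split,
so held-out samples never influence the wavelet/ICA fit or the decision rule.

The positive class is +1 ("cancer"); sensitivity is the +1 recall,
specificity the -1 recall.  A metric with a zero denominator (no positives in
a test half, say) is recorded as NaN and excluded from averages, with a
logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .classify import TrainedClassifier, predict_labels, train_classifier
from .exceptions import ProtocolError
from .profile import ExpressionProfile

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class Metrics(NamedTuple):
    classification_rate: float
    sensitivity: float
    specificity: float


def counts_from_labels(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """(classification rate, sensitivity, specificity) from a confusion table."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    rate = (counts.tp + counts.tn) / counts.total
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0:
        logger.warning("no positive samples evaluated; sensitivity undefined")
        sens = math.nan
    else:
        sens = counts.tp / pos
    if neg == 0:
        logger.warning("no negative samples evaluated; specificity undefined")
        spec = math.nan
    else:
        spec = counts.tn / neg
    return Metrics(rate, sens, spec)


@dataclass
class EvaluationReport:
    """Per-trial metrics plus a nan-aware mean/std summary (ddof=1)."""

    per_trial: list[Metrics]
    protocol: dict = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, float]]:
        arr = np.asarray(self.per_trial, dtype=float)  # trials x 3
        out = {}
        for i, name in enumerate(Metrics._fields):
            col = arr[:, i]
            valid = col[~np.isnan(col)]
            out[name] = {
                "mean": float(np.mean(valid)) if valid.size else math.nan,
                "std": float(np.std(valid, ddof=1)) if valid.size > 1 else 0.0,
                "n": int(valid.size),
            }
        return out

    def mean(self, name: str = "classification_rate") -> float:
        return self.summary()[name]["mean"]


def _evaluate_split(profile: ExpressionProfile, train_idx, test_idx,
                    classifier_spec: dict, seed: int) -> Metrics:
    train = profile.subset(train_idx)
    test = profile.subset(test_idx)
    spec = {k: v for k, v in classifier_spec.items() if k != "seed"}
    clf: TrainedClassifier = train_classifier(train, seed=seed, **spec)
    pred = predict_labels(clf, test)
    return compute_metrics(counts_from_labels(test.labels, pred))


def holdout_cv(profile: ExpressionProfile, classifier_spec: dict,
               trials: int = 100, fraction: float = 0.5,
               seed: int = 0, stratified: bool = False) -> EvaluationReport:
    """Repeated random holdout: ``trials`` fresh splits, classifier refit each.

    The training half has ceil(p * fraction) samples.  Splits are plain
    random by default; a draw whose training half misses a class is redrawn
    (logged).  ``stratified=True`` splits each class proportionally instead.
    """
    labels = profile.require_labels()
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    p = profile.n_samples
    n_train = math.ceil(p * fraction)
    if n_train < 2 or p - n_train < 1:
        raise ProtocolError(f"cannot split {p} samples at fraction {fraction}")
    rng = np.random.default_rng(seed)
    per_trial: list[Metrics] = []
    for trial in range(trials):
        for attempt in range(_MAX_REDRAWS):
            if stratified:
                train_idx = []
                for cls in (-1, 1):
                    idx = np.flatnonzero(labels == cls)
                    take = int(round(len(idx) * fraction))
                    take = min(max(take, 1), len(idx) - 1)
                    train_idx.append(rng.permutation(idx)[:take])
                train_idx = np.sort(np.concatenate(train_idx))
            else:
                train_idx = np.sort(rng.permutation(p)[:n_train])
            if len(np.unique(labels[train_idx])) == 2:
                break
            logger.info("trial %d: single-class training half, redrawing", trial)
        else:
            raise ProtocolError("could not draw a two-class training half")
        test_idx = np.setdiff1d(np.arange(p), train_idx)
        trial_seed = int(rng.integers(2**31 - 1))
        per_trial.append(_evaluate_split(profile, train_idx, test_idx,
                                         classifier_spec, trial_seed))
    return EvaluationReport(per_trial, protocol={
        "protocol": "holdout", "trials": trials, "fraction": fraction,
        "seed": seed, "stratified": stratified,
        "classifier": dict(classifier_spec)})


def kfold_cv(profile: ExpressionProfile, classifier_spec: dict,
             k: int = 10, seed: int = 0) -> EvaluationReport:
    """Seeded random partition into k folds (sizes differ by at most one);
    each fold is tested once against a model trained on the rest."""
    labels = profile.require_labels()
    p = profile.n_samples
    if not (2 <= k <= p):
        raise ValueError(f"k must be in [2, {p}], got {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(p)
    folds = np.array_split(order, k)
    per_trial: list[Metrics] = []
    for fold in folds:
        train_idx = np.sort(np.setdiff1d(np.arange(p), fold))
        if len(np.unique(labels[train_idx])) < 2:
            raise ProtocolError("a training fold contains a single class; "
                                "use fewer folds or stratify the cohort")
        trial_seed = int(rng.integers(2**31 - 1))
        per_trial.append(_evaluate_split(profile, train_idx, np.sort(fold),
                                         classifier_spec, trial_seed))
    return EvaluationReport(per_trial, protocol={
        "protocol": "kfold", "k": k, "seed": seed,
        "classifier": dict(classifier_spec)})


def within_between_distance_ratio(features: np.ndarray, labels) -> float:
    """Mean within-class pairwise distance over mean between-class distance.

    The "self-clustering" diagnostic: values well below 1 mean samples of the
    same class sit closer to each other than to the other class.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    diff = features[:, None, :] - features[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = dist[iu][same[iu]]
    between = dist[iu][~same[iu]]
    if within.size == 0 or between.size == 0:
        raise ValueError("need at least two samples in each class")
    return float(within.mean() / between.mean())
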