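"""Penalized model selection over merge-history snapshots.

After every merge the pipeline records the model's dimension and its
cross-validated macro training error.  Selection shortlists the sqrt(#records)
snapshots of smallest training error and picks the one minimizing

    training_error + log(dimension) * log(N*k) / (N*k)

where N = min(number of training samples, b), b counts shortlist models of
lower dimension than the minimum-error model, and k is the shortlist's
min/max dimension ratio.  The logarithm penalty trades dimension against fit
the way an information criterion does: it vanishes as N*k grows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .baselines import nna_classify, per_class_error, svm_classify_hierarchical

__all__ = [
    "ModelRecord",
    "proportional_kfold",
    "cv_training_error",
    "penalty_score",
    "select_model",
    "CLASSIFIERS",
]


@dataclass
class ModelRecord:
    """Snapshot of the feature set after one merge step."""

    step: int
    dimension: int
    training_error: float
    feature_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("model dimension must be >= 1")


def proportional_kfold(labels: Sequence[int], folds: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment preserving class proportions; deterministic per seed.

    Returns an integer fold id per sample.  Classes with fewer members than
    folds leave some folds without that class; this is allowed but warned.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < folds).any():
        warnings.warn(
            "some class has fewer members than folds; folds will miss that class",
            stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        assignment = np.empty(len(y), dtype=int)
        offset = 0
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            assignment[idx] = (np.arange(len(idx)) + offset) % folds
            offset += len(idx)
        return assignment
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = i
    return assignment


def _predict(classifier: str | Callable, train_x, train_y, test_x) -> np.ndarray:
    if callable(classifier):
        return classifier(train_x, train_y, test_x)
    if classifier == "nna":
        return nna_classify(train_x, train_y, test_x)
    if classifier == "svm":
        return svm_classify_hierarchical(train_x, train_y, test_x)
    raise ValueError(f"unknown classifier {classifier!r}; use 'nna', 'svm' or a callable")


def cv_training_error(
    x: np.ndarray,
    labels: Sequence[int],
    classifier: str | Callable = "nna",
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Macro-averaged error of out-of-fold predictions under stratified CV.

    ``x`` is samples x features.  Per-class error rates are computed over the
    pooled out-of-fold predictions and averaged with equal class weight,
    which keeps the measure meaningful under class imbalance.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(labels)
    assignment = proportional_kfold(y, folds, seed)
    preds = np.empty_like(y)
    for f in np.unique(assignment):
        test = assignment == f
        preds[test] = _predict(classifier, x[~test], y[~test], x[test])
    _, macro = per_class_error(y, preds)
    return macro


CLASSIFIERS = ("nna", "svm")


def penalty_score(training_error: float, dimension: int, n: float, k: float) -> float:
    """training_error + log(dimension) * log(N*k) / (N*k); no penalty if N*k = 0."""
    nk = n * k
    if nk <= 0:
        return float(training_error)
    return float(training_error + math.log(dimension) * math.log(nk) / nk)


def select_model(
    records: Sequence[ModelRecord], number_training_data: int
) -> tuple[ModelRecord, dict]:
    """Pick the dimension/error compromise among recorded snapshots.

    Shortlists the floor(sqrt(#records)) smallest-training-error records
    (ordered by dimension descending), derives b, N and k as described in the
    module docstring, and returns the record minimizing the penalty score,
    together with the selection context (shortlist, N, k, b, scores).
    """
    if not records:
        raise ValueError("no recorded models to select from")
    p = max(int(math.isqrt(len(records))), 1)
    # among equal training errors the smaller model is the better candidate
    by_error = sorted(records, key=lambda r: (r.training_error, r.dimension))
    shortlist = sorted(by_error[:p], key=lambda r: -r.dimension)
    best_err = by_error[0]
    b = sum(1 for r in shortlist if r.dimension < best_err.dimension)
    n = min(number_training_data, b)
    dims = [r.dimension for r in shortlist]
    k = min(dims) / max(dims)
    scores = {r.step: penalty_score(r.training_error, r.dimension, n, k) for r in shortlist}
    chosen = min(shortlist, key=lambda r: (scores[r.step], r.dimension, r.step))
    context = {"shortlist": shortlist, "N": n, "k": k, "b": b, "scores": scores}
    return chosen, context
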