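"""High-level orchestration: fit PMF, select a model, rank motifs, evaluate.

This is the programmatic face of the tool; the CLI subcommands are thin
wrappers over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import per_class_error, roc_curve
from .core import PMFResult, covered_at_step, features_at_step, pmf_iterate, transform
from .profiles import KmerProfileMatrix, filter_zero_variance
from .ranking import RankedMotif, rank_model_motifs
from .selection import ModelRecord, _predict, select_model

__all__ = ["PMFModel", "fit_pmf", "evaluate_classifier"]


@dataclass
class PMFModel:
    """A fitted PMF pipeline: merge history, selected snapshot, ranked motifs."""

    result: PMFResult
    selected: ModelRecord
    context: dict
    profiles: pd.DataFrame  # selected model's features x training samples
    ranked: list[RankedMotif]

    @property
    def dimension(self) -> int:
        return self.selected.dimension

    @property
    def training_error(self) -> float:
        return self.selected.training_error

    def covered(self) -> dict[str, frozenset[str]]:
        return covered_at_step(self.result, self.selected.step)

    def transform(self, matrix: KmerProfileMatrix) -> pd.DataFrame:
        """Project new samples onto the selected model's motif features."""
        return transform(self.result, self.selected.step, matrix)


def fit_pmf(
    matrix: KmerProfileMatrix,
    classifier: str = "nna",
    folds: int = 5,
    seed: int = 0,
    snapshot_every: int = 1,
    ridge: float = 1e-6,
    progress=None,
) -> PMFModel:
    """Run the whole PMF pipeline on a labelled training profile matrix.

    Filters zero-variance features, agglomerates every motif length to
    completion while recording model snapshots, applies penalized model
    selection over the snapshots, and ranks the selected model's motifs by
    (1 - p) + specificity.
    """
    filtered = filter_zero_variance(matrix)
    result = pmf_iterate(
        filtered, classifier, folds, seed, snapshot_every, ridge, progress
    )
    selected, context = select_model(result.records, filtered.n_samples)
    profiles = features_at_step(result, selected.step)
    ranked = rank_model_motifs(profiles, filtered.labels.to_numpy())
    return PMFModel(result, selected, context, profiles, ranked)


def evaluate_classifier(
    train_profiles: pd.DataFrame,
    train_labels: np.ndarray,
    test_profiles: pd.DataFrame,
    test_labels: np.ndarray,
    classifier: str = "nna",
) -> dict:
    """Train on one feature-by-sample table, test on another; macro error report.

    Returns per-class error rates, the macro mean, the dimension used, and a
    one-vs-rest ROC (FPR/TPR points) per class based on a nearest-neighbour
    distance score.
    """
    xtr = train_profiles.to_numpy(dtype=float).T
    xte = test_profiles.to_numpy(dtype=float).T
    ytr = np.asarray(train_labels)
    yte = np.asarray(test_labels)
    preds = _predict(classifier, xtr, ytr, xte)
    errs, macro = per_class_error(yte, preds)
    rocs = {}
    for c in np.unique(yte):
        # score: margin between nearest other-class and nearest same-class point
        d = np.sqrt(
            np.maximum(
                (xte**2).sum(1)[:, None] - 2 * xte @ xtr.T + (xtr**2).sum(1)[None, :],
                0.0,
            )
        )
        d_in = d[:, ytr == c].min(axis=1)
        d_out = d[:, ytr != c].min(axis=1)
        if len(np.unique(yte == c)) == 2:
            rocs[int(c)] = roc_curve(d_out - d_in, (yte == c).astype(int))
    return {
        "per_class_error": {int(c): float(e) for c, e in zip(np.unique(yte), errs)},
        "macro_error": float(macro),
        "dimension": int(train_profiles.shape[0]),
        "roc": rocs,
    }
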