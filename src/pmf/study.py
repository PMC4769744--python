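"""Planted-motif recovery study: the package's end-to-end benchmark.

Simulates per-class 16S-like read sets with a planted degenerate 6-mer motif
occurring at a class-dependent rate, runs the full pipeline (profiling,
agglomeration, penalized selection, ranking), and measures how well the
selected model captures the planted signal, together with held-out test
errors for PMF against the univariate baseline selectors.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence


from .baselines import rank_features_baseline
from .pipeline import PMFModel, evaluate_classifier, fit_pmf
from .profiles import build_profile_matrix
from .selection import cv_training_error
from .simulate import (
    PlantSpec,
    generate_reads,
    planted_canonical_kmers,
    planted_signal_kmers,
)

__all__ = ["planted_motif_study"]

# study conditions: a 6-mer with two 2-member degenerate sites, planted at
# 3 instances per read in the case class and absent from controls
DEFAULT_SPEC = PlantSpec(
    motif="TCWCGY",
    rates=(3.0, 0.0),
    read_length=150,
    reads_per_sample=200,
    samples_per_class=(20, 20),
)


def planted_motif_study(
    seed: int,
    spec: PlantSpec = DEFAULT_SPEC,
    k_range: Sequence[int] = range(2, 7),
    classifier: str = "nna",
    folds: int = 5,
    snapshot_every: int = 10,
    test_samples_per_class: Sequence[int] = (8, 8),
    baseline_top: int = 20,
    progress=None,
) -> dict:
    """Run one full planted-recovery experiment and return its measurements.

    Returns a dict with the fitted model and scalar metrics:

    - ``planted_coverage``: largest fraction of the planted motif's concrete
      canonical instances found inside a single selected feature's covered set
    - ``top_motif_overlap``: number of planted-signal k-mers in the top-ranked
      motif's covered set
    - ``selected_cv_error`` / ``full_feature_cv_error``: macro CV training
      errors of the selected model and of the unmerged profile matrix
    - ``test_errors``: held-out macro error for PMF and each baseline selector
    """
    spec = replace(spec, seed=seed)
    samples, labels = generate_reads(spec)
    train = build_profile_matrix(samples, labels, k_range)

    test_spec = replace(
        spec, samples_per_class=tuple(test_samples_per_class), seed=seed + 10_000
    )
    test_samples, test_labels = generate_reads(test_spec)
    test = build_profile_matrix(test_samples, test_labels, k_range)

    model: PMFModel = fit_pmf(
        train, classifier, folds, seed=0, snapshot_every=snapshot_every,
        progress=progress,
    )

    planted = planted_canonical_kmers(spec.motif)
    signal = planted_signal_kmers(spec.motif, k_range)
    covered = model.covered()
    coverage = max(
        (len(cov & planted) / len(planted) for cov in covered.values()), default=0.0
    )
    top = model.ranked[0]
    top_overlap = len(covered.get(top.motif.sites, frozenset()) & signal)

    y = model.result.matrix.labels.to_numpy()
    full_err = cv_training_error(
        model.result.matrix.values.to_numpy().T, y, classifier, folds, seed=0
    )
    selected_err = cv_training_error(
        model.profiles.to_numpy().T, y, classifier, folds, seed=0
    )

    test_y = test.labels.to_numpy()
    test_errors = {
        "pmf": evaluate_classifier(
            model.profiles, y, model.transform(test), test_y, classifier
        )["macro_error"]
    }
    for method in ("kw", "ig", "chi2"):
        names = rank_features_baseline(model.result.matrix, method=method)[:baseline_top]
        tr = model.result.matrix.values.loc[names]
        te = test.values.reindex(names).fillna(0.0)
        test_errors[method] = evaluate_classifier(tr, y, te, test_y, classifier)[
            "macro_error"
        ]
    te_all = test.values.reindex(model.result.matrix.values.index).fillna(0.0)
    test_errors["none"] = evaluate_classifier(
        model.result.matrix.values, y, te_all, test_y, classifier
    )["macro_error"]

    return {
        "model": model,
        "train": train,
        "test": test,
        "planted_coverage": coverage,
        "top_motif": top,
        "top_motif_overlap": top_overlap,
        "selected_cv_error": selected_err,
        "full_feature_cv_error": full_err,
        "selected_dimension": model.dimension,
        "runs": len(model.result.history),
        "test_errors": test_errors,
    }
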