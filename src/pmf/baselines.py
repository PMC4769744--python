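"""Classifiers, feature-ranking baselines and evaluation utilities.

Contains the regularized Fisher LDA direction used to merge covered k-mer
profiles, the Kruskal-Wallis / Information-Gain / Chi-square feature
selectors, a 1-nearest-neighbour classifier with a deterministic tie rule,
the hierarchical SVM used for the 3-class pneumonia problem, and the
macro-averaged (per-class) error and ROC utilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn import metrics
from sklearn.svm import SVC

__all__ = [
    "kruskal_wallis",
    "discretize_mean_std",
    "information_gain",
    "chi_square_statistic",
    "contingency_table",
    "rank_features_baseline",
    "lda_weights",
    "nna_classify",
    "svm_classify_hierarchical",
    "per_class_error",
    "roc_curve",
]


def kruskal_wallis(values: np.ndarray, group_labels: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    Requires at least two groups; a fully tied sample has H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in np.unique(group_labels)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def discretize_mean_std(values: np.ndarray) -> np.ndarray:
    """3-level coding with thresholds mean ± std: 0 below, 1 within, 2 above.

    Boundary values (including the constant-vector case, std = 0) code 1.
    """
    v = np.asarray(values, dtype=float)
    mu, sd = v.mean(), v.std()
    codes = np.ones(v.shape, dtype=int)
    codes[v < mu - sd] = 0
    codes[v > mu + sd] = 2
    return codes


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(discrete_feature: np.ndarray, labels: np.ndarray) -> float:
    """Mutual information H(S) - H(S|x) in bits between a coded feature and labels."""
    x = np.asarray(discrete_feature)
    y = np.asarray(labels)
    _, y_counts = np.unique(y, return_counts=True)
    h_s = _entropy_bits(y_counts)
    n = len(y)
    h_cond = 0.0
    for code in np.unique(x):
        mask = x == code
        _, sub = np.unique(y[mask], return_counts=True)
        h_cond += mask.sum() / n * _entropy_bits(sub)
    return h_s - h_cond


def contingency_table(discrete_feature: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Counts A_ij with rows = discretization intervals, columns = classes."""
    return pd.crosstab(pd.Series(discrete_feature), pd.Series(labels)).to_numpy()


def chi_square_statistic(table: np.ndarray) -> float:
    """Pearson chi-square sum (A_ij - E_ij)^2 / E_ij with E_ij = M_i B_j / N.

    Cells whose expected count is zero contribute nothing.
    """
    a = np.asarray(table, dtype=float)
    n = a.sum()
    if n == 0:
        return 0.0
    e = np.outer(a.sum(axis=1), a.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(e > 0, (a - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
    return float(terms.sum())


def rank_features_baseline(
    matrix, labels: Sequence[int] | np.ndarray | None = None, method: str = "kw"
) -> list[str]:
    """Rank features by a univariate selector: ``kw``, ``ig`` or ``chi2``.

    ``kw`` orders by ascending Kruskal-Wallis p-value; ``ig`` and ``chi2``
    order by descending statistic computed on mean±std-discretized values.
    Ties are broken by KW p-value, then lexicographic feature name.
    """
    values = matrix.values if hasattr(matrix, "values") else pd.DataFrame(matrix)
    if labels is None:
        labels = matrix.labels.to_numpy()
    y = np.asarray(labels)
    keys = []
    for name in values.index:
        row = values.loc[name].to_numpy(dtype=float)
        _, p = kruskal_wallis(row, y)
        if method == "kw":
            stat = -p  # descending by -p == ascending by p
        elif method == "ig":
            stat = information_gain(discretize_mean_std(row), y)
        elif method == "chi2":
            stat = chi_square_statistic(contingency_table(discretize_mean_std(row), y))
        else:
            raise ValueError(f"unknown method {method!r}; use kw, ig or chi2")
        keys.append((-stat, p, name))
    return [name for _, _, name in sorted(keys)]


def _scatter_matrices(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between- and within-class scatter, normalized by K-1 and N-K."""
    classes = np.unique(y)
    kk, n = len(classes), len(y)
    m = x.mean(axis=0)
    sb = np.zeros((x.shape[1], x.shape[1]))
    sw = np.zeros_like(sb)
    for c in classes:
        xc = x[y == c]
        d = xc.mean(axis=0) - m
        sb += len(xc) * np.outer(d, d)
        r = xc - xc.mean(axis=0)
        sw += r.T @ r
    sb /= max(kk - 1, 1)
    if n > kk:
        sw /= n - kk
    return sb, sw


def _leading_direction(sb: np.ndarray, sw: np.ndarray, ridge: float) -> np.ndarray:
    # regularize only when S_W is rank-deficient to working tolerance
    eigvals = linalg.eigvalsh(sw)
    tol = max(sw.shape[0], 1) * np.finfo(float).eps * max(eigvals.max(), 0.0)
    if eigvals.min() <= tol:
        scale = np.mean(np.diag(sw))
        sw = sw + (ridge * scale if scale > 0 else ridge) * np.eye(sw.shape[0])
    _, vecs = linalg.eigh(sb, sw)
    return vecs[:, -1]


def lda_weights(x: np.ndarray, labels: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Fisher LDA direction maximizing the Rayleigh quotient a'S_B a / a'S_W a.

    Solved via the symmetric generalized eigenproblem; a singular within-class
    scatter is ridge-regularized (``ridge`` times the mean diagonal added to
    the diagonal).  When there are more features than samples the problem is
    solved exactly in the data row-space (the optimum lies there once the
    ridge is added) to keep the eigenproblem at sample-count size.  The
    returned vector has unit Euclidean norm and a positive first nonzero
    component.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("LDA needs at least two classes")
    n, p = x.shape
    if p == 1:
        return np.ones(1)
    if p > n:
        # orthonormal basis of the row space; alpha = V beta
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        rank = int((s > s[0] * max(n, p) * np.finfo(float).eps).sum()) if s.size else 0
        rank = max(rank, 1)
        v = vt[:rank]
        beta = _leading_direction(*_scatter_matrices(x @ v.T, y), ridge)
        alpha = v.T @ beta
    else:
        alpha = _leading_direction(*_scatter_matrices(x, y), ridge)
    norm = np.linalg.norm(alpha)
    if norm == 0:
        alpha = np.zeros(p)
        alpha[0] = 1.0
        return alpha
    alpha = alpha / norm
    nz = np.flatnonzero(np.abs(alpha) > 1e-12)
    if nz.size and alpha[nz[0]] < 0:
        alpha = -alpha
    return alpha


def nna_classify(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray
) -> np.ndarray:
    """1-nearest-neighbour, Euclidean; distance ties go to the smallest class code."""
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    train_y = np.asarray(train_y)
    d2 = (
        (test_x**2).sum(axis=1)[:, None]
        - 2 * test_x @ train_x.T
        + (train_x**2).sum(axis=1)[None, :]
    )
    preds = np.empty(len(test_x), dtype=train_y.dtype)
    for i, row in enumerate(d2):
        tied = np.flatnonzero(np.isclose(row, row.min()))
        preds[i] = train_y[tied].min()
    return preds


@dataclass
class LinearSVMBackend:
    """fit/predict wrapper over a linear-kernel SVM; swap kernel via options."""

    kernel: str = "linear"
    C: float = 1.0

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LinearSVMBackend":
        self._clf = SVC(kernel=self.kernel, C=self.C)
        self._clf.fit(x, y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._clf.predict(x)


def svm_classify_hierarchical(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    svm_backend=None,
    normal_class: int | None = None,
) -> np.ndarray:
    """Hierarchical SVM for a 3-class problem (normal vs disease, then within disease).

    Stage 1 separates the ``normal_class`` (default: the smallest class code)
    from the pooled remaining classes; stage 2 separates the remaining two
    classes among the stage-1 positives.  A 2-class input falls through to a
    single SVM.  A stage-1 misrouting is never corrected downstream.
    """
    backend_factory = svm_backend or LinearSVMBackend
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)
    if len(classes) <= 2:
        clf = backend_factory().fit(train_x, train_y)
        return np.asarray(clf.predict(test_x))
    if len(classes) != 3:
        raise ValueError("hierarchical SVM supports at most 3 classes")
    normal = classes.min() if normal_class is None else normal_class
    disease = classes[classes != normal]
    stage1_y = np.where(train_y == normal, 0, 1)
    s1 = backend_factory().fit(train_x, stage1_y)
    is_disease = np.asarray(s1.predict(test_x)) == 1
    preds = np.full(len(np.atleast_2d(test_x)), normal, dtype=train_y.dtype)
    if is_disease.any():
        mask2 = np.isin(train_y, disease)
        s2 = backend_factory().fit(np.asarray(train_x)[mask2], train_y[mask2])
        preds[is_disease] = s2.predict(np.atleast_2d(test_x)[is_disease])
    return preds


def per_class_error(true_labels: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class error rates and their unweighted (macro) mean.

    The macro mean is insensitive to class imbalance, which is why it is the
    error measure used throughout.
    """
    y = np.asarray(true_labels)
    p = np.asarray(predicted)
    errs = np.array([np.mean(p[y == c] != c) for c in np.unique(y)])
    return errs, float(errs.mean())


def roc_curve(scores: np.ndarray, binary_labels: np.ndarray) -> np.ndarray:
    """ROC points (FPR, TPR) over all score thresholds, from (0,0) to (1,1)."""
    fpr, tpr, _ = metrics.roc_curve(binary_labels, scores)
    return np.column_stack([fpr, tpr])
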