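"""The PMF agglomeration loop: iterative merging of k-mer features into motifs.

Per motif length, all candidate pairs are ranked by phylogenetic distance
(site-wise Jaccard over generalized letters, antisense-aware); distance ties
are ordered by the class-association gain of the prospective merge

    KW = (1 - p_new) - mean_i(1 - p_i^original)

where p_new is the Kruskal-Wallis p-value of the merged profile and p_i are
the p-values of the covered original k-mers.  The top floor(n_k/2) candidates
pass a greedy redundancy filter that keeps at most floor(sqrt(n_k)) mutually
disjoint pairs, which are then merged in a batch.  A merged motif's profile is
the LDA-weighted linear combination of the profiles of ALL original k-mers it
covers (the original matrix is retained read-only for this), so the weights
are re-estimated from scratch at every merge.  After each merge a model
snapshot (dimension, cross-validated macro training error) is recorded; the
loop for a length ends when a single motif remains, so a full run performs
exactly sum_k (n_k - 1) merges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .alphabet import (
    ALPHABET,
    Motif,
    members,
    merge_motifs,
    site_difference,
)
from .baselines import kruskal_wallis, lda_weights
from .profiles import KmerProfileMatrix
from .selection import ModelRecord, cv_training_error

__all__ = [
    "MergeCandidate",
    "MergeRecord",
    "PMFResult",
    "kw_merge_score",
    "candidate_pairs",
    "remove_redundant_pairs",
    "lda_merge_profiles",
    "pmf_iterate",
    "features_at_step",
    "transform",
]


@dataclass(frozen=True)
class MergeCandidate:
    """A scored pair of current same-length features."""

    i: int
    j: int
    distance: float
    use_antisense: bool
    kw_score: float


@dataclass
class MergeRecord:
    """One committed merge: enough to replay the agglomeration."""

    step: int
    new_serial: int
    parent_serials: tuple[int, int]
    motif: str
    covered: tuple[str, ...]
    weights: np.ndarray
    dimension_after: int


@dataclass(eq=False)
class _Feature:
    serial: int
    motif: Motif
    profile: np.ndarray
    p_value: float


@dataclass
class PMFResult:
    """Merge history plus model snapshots from one pmf_iterate run."""

    history: list[MergeRecord]
    records: list[ModelRecord]
    matrix: KmerProfileMatrix  # the (filtered) input the run started from


def kw_merge_score(p_new: float, p_originals: Sequence[float]) -> float:
    """Class-association gain of a merge: (1 - p_new) - mean_i(1 - p_i)."""
    if len(p_originals) == 0:
        raise ValueError("no original p-values")
    vals = list(p_originals) + [p_new]
    if any(not 0.0 <= p <= 1.0 for p in vals):
        raise ValueError("p-values must lie in [0, 1]")
    return (1.0 - p_new) - sum(1.0 - p for p in p_originals) / len(p_originals)


# ---------------------------------------------------------------------------
# vectorized pairwise motif distances

_CODE = {s: sum(1 << "ACGT".index(b) for b in members(s)) for s in ALPHABET}
_SYM_OF_CODE = {v: k for k, v in _CODE.items()}
_RC_CODE = np.zeros(16, dtype=np.uint8)
for _s in ALPHABET:
    comp = sum(1 << "ACGT".index({"A": "T", "T": "A", "C": "G", "G": "C"}[b]) for b in members(_s))
    _RC_CODE[_CODE[_s]] = comp

_SITE_LUT = np.zeros((16, 16))
for _a in ALPHABET:
    for _b in ALPHABET:
        _SITE_LUT[_CODE[_a], _CODE[_b]] = site_difference(_a, _b)


def _encode(motifs: Sequence[str]) -> np.ndarray:
    return np.array([[_CODE[s] for s in m] for m in motifs], dtype=np.uint8)


def _pairwise_distances(motifs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(distance, use_antisense) matrices over all motif pairs, vectorized."""
    m = _encode(motifs)
    rc = _RC_CODE[m[:, ::-1]]
    n, kk = m.shape
    direct = np.zeros((n, n))
    anti = np.zeros((n, n))
    for s in range(kk):
        direct += _SITE_LUT[np.ix_(m[:, s], m[:, s])]
        anti += _SITE_LUT[m[:, s][:, None], rc[:, s][None, :]]
    use_anti = anti < direct
    return np.where(use_anti, anti, direct), use_anti


# ---------------------------------------------------------------------------


def lda_merge_profiles(
    original_profiles: np.ndarray, labels: np.ndarray, ridge: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Merged profile of a motif: LDA-weighted combination of covered originals.

    ``original_profiles`` is samples x covered.  Returns ``(profile, weights)``
    where the weights are the leading Fisher discriminant direction (unit
    norm, first nonzero component positive).
    """
    x = np.atleast_2d(np.asarray(original_profiles, dtype=float))
    if x.shape[1] < 1:
        raise ValueError("merge needs at least one covered profile")
    w = lda_weights(x, labels, ridge)
    return x @ w, w


class _Merger:
    """Run-time state shared by candidate scoring and committed merges."""

    def __init__(self, matrix: KmerProfileMatrix, ridge: float):
        self.values = matrix.values  # original features x samples, read-only
        self.labels = matrix.labels.to_numpy()
        self.ridge = ridge
        self.p_original = {
            name: kruskal_wallis(self.values.loc[name].to_numpy(), self.labels)[1]
            for name in self.values.index
        }
        self._score_cache: dict[tuple[int, int], float] = {}

    def merged_profile(self, covered: Sequence[str]) -> tuple[np.ndarray, np.ndarray, float]:
        names = sorted(covered)
        x = self.values.loc[names].to_numpy().T
        profile, w = lda_merge_profiles(x, self.labels, self.ridge)
        p_new = kruskal_wallis(profile, self.labels)[1]
        return profile, w, p_new

    def score(self, f1: _Feature, f2: _Feature) -> float:
        key = (f1.serial, f2.serial) if f1.serial < f2.serial else (f2.serial, f1.serial)
        cached = self._score_cache.get(key)
        if cached is not None:
            return cached
        covered = f1.motif.covered | f2.motif.covered
        _, _, p_new = self.merged_profile(covered)
        score = kw_merge_score(p_new, [self.p_original[c] for c in sorted(covered)])
        self._score_cache[key] = score
        return score


def candidate_pairs(
    features: Sequence,
    labels: np.ndarray | None = None,
    limit: int | None = None,
    merger: _Merger | None = None,
    matrix: KmerProfileMatrix | None = None,
) -> list[MergeCandidate]:
    """Rank same-length feature pairs by (distance, Eq-1 score desc, lex motifs).

    All pairs are scored by motif distance; the ``limit`` smallest-distance
    pairs are retained, with the class-association score (computed lazily,
    only for pairs at or below the boundary distance) ordering equal-distance
    ties and motif strings breaking the rest.  ``features`` may be a list of
    internal feature objects or of plain :class:`~pmf.alphabet.Motif`.
    """
    feats = [
        f if isinstance(f, _Feature) else _Feature(i, f if isinstance(f, Motif) else Motif(f), None, 1.0)
        for i, f in enumerate(features)
    ]
    n = len(feats)
    if n < 2:
        return []
    if merger is None and matrix is not None:
        merger = _Merger(matrix, 1e-6)
    if limit is None:
        limit = max(n // 2, 1)
    dist, use_anti = _pairwise_distances([f.motif.sites for f in feats])
    iu, ju = np.triu_indices(n, k=1)
    d = dist[iu, ju]
    order = np.argsort(d, kind="stable")
    limit = min(limit, len(d))
    boundary = d[order[limit - 1]]
    eligible = order[d[order] <= boundary + 1e-12]

    def sort_key(idx: int):
        i, j = int(iu[idx]), int(ju[idx])
        score = merger.score(feats[i], feats[j]) if merger is not None else 0.0
        lex = tuple(sorted((feats[i].motif.sites, feats[j].motif.sites)))
        return (d[idx], -score, lex)

    keyed = sorted(((sort_key(idx), idx) for idx in eligible), key=lambda t: t[0])
    out = []
    for (dd, neg_score, _), idx in keyed[:limit]:
        i, j = int(iu[idx]), int(ju[idx])
        out.append(MergeCandidate(i, j, float(dd), bool(use_anti[i, j]), -neg_score))
    return out


def remove_redundant_pairs(
    sorted_pairs: Sequence[MergeCandidate], m_max: int
) -> list[MergeCandidate]:
    """Greedy scan keeping mutually disjoint pairs, at most ``m_max`` of them."""
    kept: list[MergeCandidate] = []
    used: set[int] = set()
    for c in sorted_pairs:
        if len(kept) >= m_max:
            break
        if c.i in used or c.j in used:
            continue
        kept.append(c)
        used.update((c.i, c.j))
    return kept


def pmf_iterate(
    matrix: KmerProfileMatrix,
    classifier: str | Callable = "nna",
    folds: int = 5,
    seed: int = 0,
    snapshot_every: int = 1,
    ridge: float = 1e-6,
    progress: Callable[[str], None] | None = None,
) -> PMFResult:
    """Run the full agglomeration over every motif length present in the matrix.

    The matrix must already have zero-variance features removed.  Lengths are
    processed independently (ascending); the model dimension recorded after a
    merge counts the current features of all lengths.  ``snapshot_every``
    evaluates the cross-validated training error only every B-th merge (the
    final state of each length is always evaluated); it is a performance
    knob, not a semantic change.
    """
    labels = matrix.labels.to_numpy()
    merger = _Merger(matrix, ridge)
    serial = 0
    by_len: dict[int, list[_Feature]] = {}
    for name in matrix.values.index:
        f = _Feature(
            serial,
            Motif(name),
            matrix.values.loc[name].to_numpy(dtype=float),
            merger.p_original[name],
        )
        by_len.setdefault(len(name), []).append(f)
        serial += 1

    history: list[MergeRecord] = []
    records: list[ModelRecord] = []
    step = 0
    total_merges = sum(len(v) - 1 for v in by_len.values())

    def snapshot(force: bool) -> None:
        if not force and snapshot_every > 1 and step % snapshot_every != 0:
            return
        x = np.vstack([f.profile for fs in by_len.values() for f in fs]).T
        err = cv_training_error(x, labels, classifier, folds, seed)
        records.append(ModelRecord(step, x.shape[1], err))

    for klen in sorted(by_len):
        feats = by_len[klen]
        while len(feats) > 1:
            n_k = len(feats)
            cands = candidate_pairs(feats, limit=max(n_k // 2, 1), merger=merger)
            kept = remove_redundant_pairs(cands, max(int(np.sqrt(n_k)), 1))
            # pairs are disjoint, so batch commits are equivalent to sequential
            batch = [(feats[c.i], feats[c.j], c.use_antisense) for c in kept]
            for f1, f2, use_anti in batch:
                new_motif = merge_motifs(f1.motif, f2.motif, use_anti)
                profile, w, p_new = merger.merged_profile(new_motif.covered)
                new_feat = _Feature(serial, new_motif, profile, p_new)
                serial += 1
                feats.remove(f1)
                feats.remove(f2)
                feats.append(new_feat)
                step += 1
                history.append(
                    MergeRecord(
                        step,
                        new_feat.serial,
                        (f1.serial, f2.serial),
                        new_motif.sites,
                        tuple(sorted(new_motif.covered)),
                        w,
                        sum(len(v) for v in by_len.values()),
                    )
                )
                snapshot(force=step == total_merges)
            if progress is not None:
                progress(f"k={klen}: {len(feats)} features left (step {step}/{total_merges})")
    return PMFResult(history, records, matrix)


def features_at_step(result: PMFResult, step: int) -> pd.DataFrame:
    """Reconstruct the feature-by-sample profile matrix after ``step`` merges.

    Replays the stored merge history (motifs, covered sets, LDA weights)
    against the retained original matrix; column names are motif strings.
    """
    values = result.matrix.values
    alive: dict[int, tuple[str, np.ndarray]] = {
        i: (name, values.loc[name].to_numpy(dtype=float))
        for i, name in enumerate(values.index)
    }
    for rec in result.history:
        if rec.step > step:
            break
        for p in rec.parent_serials:
            alive.pop(p, None)
        profile = values.loc[list(rec.covered)].to_numpy().T @ rec.weights
        alive[rec.new_serial] = (rec.motif, profile)
    names = [alive[s][0] for s in sorted(alive)]
    data = np.vstack([alive[s][1] for s in sorted(alive)])
    return pd.DataFrame(data, index=names, columns=values.columns)


def covered_at_step(result: PMFResult, step: int) -> dict[str, frozenset[str]]:
    """Covered original k-mers per live feature name after ``step`` merges.

    When several live features share a motif string the covered sets pool.
    """
    alive: dict[int, tuple[str, frozenset[str]]] = {
        i: (name, frozenset({name})) for i, name in enumerate(result.matrix.values.index)
    }
    for rec in result.history:
        if rec.step > step:
            break
        for p in rec.parent_serials:
            alive.pop(p, None)
        alive[rec.new_serial] = (rec.motif, frozenset(rec.covered))
    out: dict[str, frozenset[str]] = {}
    for name, cov in alive.values():
        out[name] = out.get(name, frozenset()) | cov
    return out


def transform(
    result: PMFResult, step: int, new_matrix: KmerProfileMatrix
) -> pd.DataFrame:
    """Project another sample set onto the motif features of a recorded step.

    Original k-mers absent from ``new_matrix`` contribute zero.  Used to map
    a held-out test set into the space of the selected model.
    """
    base = new_matrix.values.reindex(result.matrix.values.index).fillna(0.0)
    alive: dict[int, tuple[str, np.ndarray]] = {
        i: (name, base.loc[name].to_numpy(dtype=float))
        for i, name in enumerate(base.index)
    }
    for rec in result.history:
        if rec.step > step:
            break
        for p in rec.parent_serials:
            alive.pop(p, None)
        profile = base.loc[list(rec.covered)].to_numpy().T @ rec.weights
        alive[rec.new_serial] = (rec.motif, profile)
    names = [alive[s][0] for s in sorted(alive)]
    data = np.vstack([alive[s][1] for s in sorted(alive)])
    return pd.DataFrame(data, index=names, columns=base.columns)
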