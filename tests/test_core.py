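"""The PMF merge loop: Eq-1 scoring, candidate ranking, batch merging."""

import numpy as np
import pandas as pd
import pytest

from pmf.alphabet import motif_covers
from pmf.core import (
    candidate_pairs,
    covered_at_step,
    features_at_step,
    kw_merge_score,
    lda_merge_profiles,
    pmf_iterate,
    remove_redundant_pairs,
    transform,
    MergeCandidate,
)
from pmf.profiles import KmerProfileMatrix
from pmf.simulate import generate_profile_matrix


class TestKwMergeScore:
    @pytest.mark.parametrize(
        "p_new,p_orig,expected",
        [
            (0.0, [1.0, 1.0], 1.0),
            (0.5, [0.5, 0.5], 0.0),
            (1.0, [0.0], -1.0),
        ],
    )
    def test_examples(self, p_new, p_orig, expected):
        assert kw_merge_score(p_new, p_orig) == pytest.approx(expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            kw_merge_score(0.5, [])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kw_merge_score(1.5, [0.5])


class TestCandidatePairs:
    def test_minimum_distance_pair_first(self):
        # distances: (AA,AT)=1, (AA,CC)=2, (AT,CC)=2 -> (AA,AT) leads
        feats = ["AA", "AT", "CC"]
        cands = candidate_pairs(feats, limit=3)
        first = cands[0]
        assert {feats[first.i], feats[first.j]} == {"AA", "AT"}
        assert first.distance == pytest.approx(1.0)

    def test_zero_distance_pair_ranks_first(self):
        cands = candidate_pairs(["AC", "GT", "TT"], limit=3)
        top = cands[0]
        assert top.distance == 0.0  # GT is the antisense of AC
        assert top.use_antisense

    def test_limit_respected(self):
        cands = candidate_pairs(["AA", "AT", "CC", "GG"], limit=1)
        assert len(cands) == 1

    def test_fewer_than_two_features(self):
        assert candidate_pairs(["AA"], limit=1) == []


class TestRedundancyRemoval:
    def _mk(self, i, j):
        return MergeCandidate(i, j, 0.0, False, 0.0)

    def test_overlapping_pair_dropped(self):
        pairs = [self._mk(1, 2), self._mk(2, 3), self._mk(4, 5)]
        kept = remove_redundant_pairs(pairs, m_max=2)
        assert [(c.i, c.j) for c in kept] == [(1, 2), (4, 5)]

    def test_single_pair_kept(self):
        assert len(remove_redundant_pairs([self._mk(1, 2)], m_max=5)) == 1

    def test_m_max_truncates_disjoint_pairs(self):
        pairs = [self._mk(1, 2), self._mk(3, 4), self._mk(5, 6)]
        kept = remove_redundant_pairs(pairs, m_max=2)
        assert [(c.i, c.j) for c in kept] == [(1, 2), (3, 4)]


class TestLdaMergeProfiles:
    def test_single_column_identity(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        prof, w = lda_merge_profiles(col[:, None], np.array([0, 0, 1, 1]))
        assert w == pytest.approx([1.0])
        assert prof == pytest.approx(col)

    def test_informative_column_dominates(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 25)
        x = np.column_stack([y + rng.normal(0, 0.1, 50), rng.normal(0, 1, 50)])
        prof, w = lda_merge_profiles(x, y)
        corr = np.corrcoef(prof, x[:, 0])[0, 1]
        assert abs(corr) > 0.99
        assert abs(w[0]) > abs(w[1])

    def test_identical_class_distributions_no_error(self):
        x = np.ones((10, 2))
        prof, w = lda_merge_profiles(x, np.repeat([0, 1], 5))
        assert np.isfinite(prof).all()
        assert np.linalg.norm(w) == pytest.approx(1.0)


def _tiny_matrix(names, data, labels):
    cols = [f"s{i}" for i in range(len(labels))]
    df = pd.DataFrame(data, index=names, columns=cols)
    return KmerProfileMatrix(df, pd.Series(labels, index=cols))


class TestPmfIterate:
    def test_three_features_terminate_in_two_merges(self):
        rng = np.random.default_rng(0)
        m = _tiny_matrix(["AA", "AC", "AG"], rng.random((3, 8)), [0] * 4 + [1] * 4)
        res = pmf_iterate(m, "nna", folds=2)
        assert len(res.history) == 2
        assert res.records[-1].dimension == 1

    def test_mixed_lengths_independent_loops(self):
        rng = np.random.default_rng(1)
        m = _tiny_matrix(
            ["AA", "AC", "AAA", "AAC"], rng.random((4, 8)), [0] * 4 + [1] * 4
        )
        res = pmf_iterate(m, "nna", folds=2)
        assert len(res.history) == 2  # (2-1) + (2-1)
        assert res.records[-1].dimension == 2
        lengths = {len(rec.motif) for rec in res.history}
        assert lengths == {2, 3}

    def test_structural_invariants_medium(self):
        # strict dimension decrease, merge count, batch bounds, coverage
        m = generate_profile_matrix(30, (10, 10), effect_features=5,
                                    effect_size=1.0, k=4, seed=3)
        res = pmf_iterate(m, "nna", folds=5, seed=0)
        assert len(res.history) == 29
        dims = [r.dimension for r in res.records]
        assert all(a > b for a, b in zip(dims, dims[1:]))
        for rec in res.history:
            for kmer in rec.covered:
                assert motif_covers(rec.motif, kmer)

    def test_merging_improves_cv_error_on_planted_signal(self):
        m = generate_profile_matrix(24, (12, 12), effect_features=6,
                                    effect_size=0.6, k=4, seed=7)
        res = pmf_iterate(m, "nna", folds=4, seed=0)
        errors = [r.training_error for r in res.records]
        assert min(errors) <= errors[0]


class TestReconstruction:
    def test_features_at_step_replays_history(self):
        m = generate_profile_matrix(12, (8, 8), effect_features=3,
                                    effect_size=1.0, k=3, seed=2)
        res = pmf_iterate(m, "nna", folds=4)
        mid = len(res.history) // 2
        prof = features_at_step(res, mid)
        assert prof.shape == (12 - mid, 16)
        cov = covered_at_step(res, mid)
        assert set().union(*cov.values()) == set(m.values.index)

    def test_transform_matches_train_reconstruction(self):
        m = generate_profile_matrix(12, (8, 8), effect_features=3,
                                    effect_size=1.0, k=3, seed=2)
        res = pmf_iterate(m, "nna", folds=4)
        step = len(res.history)
        train_prof = features_at_step(res, step)
        projected = transform(res, step, m)
        np.testing.assert_allclose(projected.to_numpy(), train_prof.to_numpy())

    def test_transform_fills_missing_kmers_with_zero(self):
        m = generate_profile_matrix(8, (6, 6), effect_features=2,
                                    effect_size=1.0, k=3, seed=4)
        res = pmf_iterate(m, "nna", folds=3)
        partial = KmerProfileMatrix(
            m.values.iloc[:4, :2].copy(), m.labels.iloc[:2]
        )
        out = transform(res, len(res.history), partial)
        assert np.isfinite(out.to_numpy()).all()
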