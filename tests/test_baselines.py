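"""Feature selectors, LDA direction, 1-NN, hierarchical SVM, evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pmf.baselines import (
    chi_square_statistic,
    contingency_table,
    discretize_mean_std,
    information_gain,
    kruskal_wallis,
    lda_weights,
    nna_classify,
    per_class_error,
    rank_features_baseline,
    roc_curve,
    svm_classify_hierarchical,
)
from pmf.profiles import KmerProfileMatrix


class TestKruskalWallis:
    def test_hand_computed_h(self):
        h, p = kruskal_wallis(np.array([1, 2, 3, 4, 5, 6.0]), np.repeat([0, 1], 3))
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups_high_p(self):
        h, p = kruskal_wallis(np.array([1, 2, 1, 2.0]), np.array([0, 0, 1, 1]))
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.9

    def test_all_tied_values(self):
        h, p = kruskal_wallis(np.ones(9), np.repeat([0, 1, 2], 3))
        assert h == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis(np.arange(4.0), np.zeros(4))

    def test_chi2_p_close_to_permutation_oracle(self):
        # exact permutation distribution of H on a small two-group problem
        values = np.array([3.1, 1.2, 5.0, 2.2, 4.4, 0.7, 6.1, 2.9, 3.8, 1.9])
        labels = np.repeat([0, 1], 5)
        h_obs, p_chi2 = kruskal_wallis(values, labels)
        count = total = 0
        for idx in itertools.combinations(range(10), 5):
            perm = np.ones(10, dtype=int)
            perm[list(idx)] = 0
            h, _ = kruskal_wallis(values, perm)
            count += h >= h_obs - 1e-12
            total += 1
        p_exact = count / total
        assert abs(p_chi2 - p_exact) < 0.1


class TestDiscretize:
    def test_constant_vector_all_middle(self):
        assert (discretize_mean_std(np.full(5, 3.3)) == 1).all()

    def test_outlier_coded_high(self):
        codes = discretize_mean_std(np.array([0.0, 0, 0, 10]))
        assert codes.tolist() == [1, 1, 1, 2]

    def test_normal_sample_middle_fraction(self):
        rng = np.random.default_rng(0)
        codes = discretize_mean_std(rng.normal(size=20000))
        frac = (codes == 1).mean()
        assert abs(frac - 0.683) < 0.02


class TestInformationGain:
    def test_perfect_feature_one_bit(self):
        y = np.repeat([0, 1], 10)
        assert information_gain(y.copy(), y) == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        y = np.repeat([0, 1], 10)
        assert information_gain(np.zeros(20, dtype=int), y) == pytest.approx(0.0)

    def test_bounded_by_label_entropy(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 60)
        x = rng.integers(0, 3, 60)
        ig = information_gain(x, y)
        h_s = information_gain(y.copy(), y)
        assert 0.0 <= ig <= h_s + 1e-12

    def test_symmetric_under_code_relabeling(self):
        y = np.repeat([0, 1], 8)
        x = np.tile([0, 1, 2, 1], 4)
        relabeled = np.array([2, 0, 1, 0] * 4)  # permute the code alphabet
        assert information_gain(x, y) == pytest.approx(information_gain(relabeled, y))


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[10, 0], [0, 10]], 20.0),
            ([[5, 5], [5, 5]], 0.0),
            ([[3, 1], [1, 3]], 2.0),
        ],
    )
    def test_hand_computed(self, table, expected):
        assert chi_square_statistic(np.array(table)) == pytest.approx(expected)

    def test_contingency_margins(self):
        x = np.array([0, 0, 1, 1, 2, 2])
        y = np.array([0, 1, 0, 1, 0, 1])
        t = contingency_table(x, y)
        assert t.sum() == 6
        assert t.sum(axis=1).tolist() == [2, 2, 2]


class TestRankFeatures:
    @pytest.fixture()
    def matrix_with_signal(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 20)
        data = rng.normal(size=(6, 40))
        data[2] = y * 4 + rng.normal(0, 0.2, 40)  # the separating feature
        names = ["AAAA", "AAAC", "AAAG", "AAAT", "AACA", "AACC"]
        df = pd.DataFrame(data, index=names, columns=[f"s{i}" for i in range(40)])
        return KmerProfileMatrix(df, pd.Series(y, index=df.columns))

    @pytest.mark.parametrize("method", ["kw", "ig", "chi2"])
    def test_signal_feature_first(self, matrix_with_signal, method):
        ranked = rank_features_baseline(matrix_with_signal, method=method)
        assert ranked[0] == "AAAG"

    def test_constant_features_lexicographic(self):
        df = pd.DataFrame(np.ones((3, 6)), index=["CC", "AA", "GG"],
                          columns=[f"s{i}" for i in range(6)])
        m = KmerProfileMatrix(df, pd.Series([0, 0, 0, 1, 1, 1], index=df.columns))
        assert rank_features_baseline(m, method="ig") == ["AA", "CC", "GG"]


class TestLdaWeights:
    def test_one_feature_unit(self):
        w = lda_weights(np.arange(6.0)[:, None], np.repeat([0, 1], 3))
        assert w == pytest.approx([1.0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lda_weights(np.random.default_rng(0).normal(size=(6, 2)), np.zeros(6))

    def test_duplicated_columns_handled_by_ridge(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=20)
        x = np.column_stack([col, col])  # singular within-class scatter
        w = lda_weights(x, np.repeat([0, 1], 10))
        assert np.isfinite(w).all()
        assert np.linalg.norm(w) == pytest.approx(1.0)

    def _rayleigh(self, x, y, direction):
        from pmf.baselines import _scatter_matrices

        sb, sw = _scatter_matrices(x, y)
        denom = direction @ sw @ direction
        return (direction @ sb @ direction) / denom if denom > 0 else np.inf

    def test_beats_random_directions(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 20)
        x = np.column_stack([y + rng.normal(0, 0.5, 40), rng.normal(size=40),
                             rng.normal(size=40)])
        w = lda_weights(x, y)
        q_opt = self._rayleigh(x, y, w)
        dirs = rng.normal(size=(1000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        q_rand = max(self._rayleigh(x, y, d) for d in dirs)
        assert q_opt >= q_rand - 1e-9

    def test_grid_search_oracle_two_features(self):
        # the returned direction's quotient matches a dense angular grid
        rng = np.random.default_rng(7)
        for trial in range(10):
            y = np.repeat([0, 1], 15)
            x = rng.normal(size=(30, 2))
            x[y == 1] += rng.normal(0, 1, size=2)
            w = lda_weights(x, y)
            q_opt = self._rayleigh(x, y, w)
            angles = np.linspace(0, np.pi, 3600, endpoint=False)
            grid = np.column_stack([np.cos(angles), np.sin(angles)])
            q_grid = max(self._rayleigh(x, y, g) for g in grid)
            assert q_opt >= q_grid * (1 - 0.01)

    def test_more_features_than_samples_row_space_solution(self):
        rng = np.random.default_rng(11)
        y = np.repeat([0, 1], 6)
        x = rng.normal(size=(12, 40))
        x[y == 1, 0] += 3.0
        w = lda_weights(x, y)
        assert w.shape == (40,)
        assert np.linalg.norm(w) == pytest.approx(1.0)
        proj = x @ w
        assert abs(proj[y == 1].mean() - proj[y == 0].mean()) > 0


class TestClassifiers:
    def test_nna_exact_match(self):
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0, 1, 2])
        assert nna_classify(x, y, np.array([[1.0]]))[0] == 1

    def test_nna_nearer_point_wins(self):
        x = np.array([[0.0], [10.0]])
        y = np.array([0, 1])
        assert nna_classify(x, y, np.array([[2.0]]))[0] == 0

    def test_nna_tie_smallest_class(self):
        x = np.array([[0.0], [2.0]])
        y = np.array([2, 0])
        # query at 1.0 is equidistant; class 0 must win
        assert nna_classify(x, y, np.array([[1.0]]))[0] == 0

    def test_svm_two_class_plain(self):
        x = np.concatenate([np.zeros(10), np.ones(10) * 4])[:, None]
        y = np.repeat([0, 1], 10)
        preds = svm_classify_hierarchical(x, y, x)
        assert (preds == y).all()

    def test_svm_three_class_separable(self):
        rng = np.random.default_rng(0)
        centers = {0: (0, 0), 1: (10, 0), 2: (0, 10)}
        x = np.vstack([rng.normal(centers[c], 0.3, size=(10, 2)) for c in (0, 1, 2)])
        y = np.repeat([0, 1, 2], 10)
        preds = svm_classify_hierarchical(x, y, x, normal_class=0)
        assert (preds == y).all()

    def test_svm_stage1_mistake_propagates(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal((0, 0), 0.3, (10, 2)),
                       rng.normal((10, 0), 0.3, (10, 2)),
                       rng.normal((0, 10), 0.3, (10, 2))])
        y = np.repeat([0, 1, 2], 10)
        # a probe deep inside the normal region can never come out CAP/HAP
        probe = np.array([[-1.0, -1.0]])
        assert svm_classify_hierarchical(x, y, probe, normal_class=0)[0] == 0


class TestEvaluation:
    def test_perfect_prediction_zero_errors(self):
        errs, macro = per_class_error([0, 0, 1, 1], [0, 0, 1, 1])
        assert errs.tolist() == [0.0, 0.0] and macro == 0.0

    def test_one_class_fully_wrong(self):
        errs, macro = per_class_error([0, 0, 1, 1], [0, 0, 0, 0])
        assert errs.tolist() == [0.0, 1.0] and macro == 0.5

    def test_macro_invariant_to_duplication(self):
        y = np.array([0, 0, 1])
        p = np.array([0, 1, 1])
        _, macro1 = per_class_error(y, p)
        _, macro2 = per_class_error(np.r_[y, [0, 0]], np.r_[p, [0, 1]])
        assert macro1 == pytest.approx(macro2)

    def test_roc_perfect_and_inverted(self):
        y = np.repeat([0, 1], 10)
        pts = roc_curve(y.astype(float), y)
        auc = np.trapezoid(pts[:, 1], pts[:, 0])
        assert auc == pytest.approx(1.0)
        pts_inv = roc_curve(-y.astype(float), y)
        assert np.trapezoid(pts_inv[:, 1], pts_inv[:, 0]) == pytest.approx(0.0)

    def test_roc_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        pts = roc_curve(rng.normal(size=4000), y)
        auc = np.trapezoid(pts[:, 1], pts[:, 0])
        assert abs(auc - 0.5) < 0.05
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
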