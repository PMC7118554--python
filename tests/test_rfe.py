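"""Nonlinear SVM-RFE: grid search, the kernel dJ criterion, subset selection."""

import numpy as np
import pytest
from sklearn.svm import SVC

from dfcpipe.rfe import (
    KernelParams,
    grid_search,
    rank_features,
    select_optimal_subset,
    svm_rfe,
)


def brute_delta_j(x, y, params, feature):
    """Independent dJ: explicit double sums of alpha_i alpha_j y_i y_j K
    with and without the feature, alphas from a freshly trained SVM."""
    model = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
    model.fit(x, y)
    sv = model.support_vectors_
    a = model.dual_coef_.ravel()  # alpha_i * y_i

    def kernel_sum(cols):
        total = 0.0
        for i in range(len(sv)):
            for j in range(len(sv)):
                d2 = sum((sv[i, c] - sv[j, c]) ** 2 for c in cols)
                total += a[i] * a[j] * np.exp(-params.gamma * d2)
        return 0.5 * total

    cols = list(range(x.shape[1]))
    reduced = [c for c in cols if c != feature]
    return kernel_sum(cols) - kernel_sum(reduced)


class TestGridSearch:
    def test_tie_break_smallest_c_then_gamma(self):
        x = np.r_[np.full((10, 2), -3.0), np.full((10, 2), 3.0)]
        x += np.random.default_rng(0).normal(0, 0.1, x.shape)
        y = np.r_[-np.ones(10), np.ones(10)].astype(int)
        params = grid_search(x, y, c_grid=(1.0, 10.0), gamma_grid=(0.1, 1.0),
                             folds=5, seed=0)
        assert (params.C, params.gamma) == (1.0, 0.1)

    def test_rbf_solves_xor_where_linear_fails(self, rng):
        centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], float)
        x = np.vstack([c + rng.normal(0, 0.15, (12, 2)) for c in centers])
        y = np.r_[np.ones(24), -np.ones(24)].astype(int)
        params = grid_search(x, y, folds=4, seed=0)
        from sklearn.model_selection import cross_val_score

        rbf_acc = cross_val_score(
            SVC(C=params.C, gamma=params.gamma, kernel="rbf"), x, y, cv=4
        ).mean()
        lin_acc = cross_val_score(SVC(C=1.0, kernel="linear"), x, y, cv=4).mean()
        assert rbf_acc > 0.9
        assert lin_acc < 0.65

    def test_deterministic_under_fixed_seed(self, rng):
        x = rng.standard_normal((30, 4))
        y = np.r_[np.ones(15), -np.ones(15)].astype(int)
        a = grid_search(x, y, c_grid=(0.5, 2.0), gamma_grid=(0.05, 0.5), seed=4)
        b = grid_search(x, y, c_grid=(0.5, 2.0), gamma_grid=(0.05, 0.5), seed=4)
        assert a == b

    def test_degenerate_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            grid_search(rng.standard_normal((6, 2)), np.ones(6, dtype=int))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            KernelParams(C=-1.0, gamma=0.1)


class TestRankFeatures:
    def test_delta_j_matches_bruteforce(self, rng):
        x = rng.standard_normal((8, 3))
        y = np.r_[np.ones(4), -np.ones(4)].astype(int)
        params = KernelParams(C=1.0, gamma=0.3)
        from dfcpipe.rfe import _delta_j

        model = SVC(C=1.0, gamma=0.3, kernel="rbf")
        model.fit(x, y)
        dj = _delta_j(model.support_vectors_, model.dual_coef_.ravel(), 0.3)
        for f in range(3):
            assert dj[f] == pytest.approx(brute_delta_j(x, y, params, f),
                                          abs=1e-10)

    def test_duplicated_columns_tie_broken_by_lower_index(self, rng):
        x = rng.standard_normal((20, 4))
        x[:, 2] = x[:, 1]  # duplicate pair
        y = np.r_[np.ones(10), -np.ones(10)].astype(int)
        res = rank_features(x, y, KernelParams(C=1.0, gamma=0.1))
        order = list(res.elimination_order)
        # lower-index duplicate is eliminated before its twin
        assert order.index(1) < order.index(2)

    def test_separating_feature_survives_to_final_round(self):
        survived = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.r_[np.ones(30), -np.ones(30)].astype(int)
            x = rng.standard_normal((60, 50))
            x[:, 0] = y * 2 + rng.standard_normal(60) * 0.1
            res = rank_features(x, y, KernelParams(C=1.0, gamma=0.02))
            survived += res.ranking[0] == 0
        assert survived >= 9

    def test_ranking_is_permutation(self, rng):
        x = rng.standard_normal((16, 7))
        y = np.r_[np.ones(8), -np.ones(8)].astype(int)
        res = rank_features(x, y, KernelParams(C=1.0, gamma=0.1))
        assert sorted(res.ranking) == list(range(7))
        np.testing.assert_array_equal(res.ranking, res.elimination_order[::-1])

    def test_zero_dj_feature_removal_keeps_decision_values(self, rng):
        x = rng.standard_normal((20, 4))
        x[:, 3] = 2.5  # constant: no pairwise differences, dJ exactly 0
        y = np.r_[np.ones(10), -np.ones(10)].astype(int)
        params = KernelParams(C=1.0, gamma=0.2)
        full = SVC(C=1.0, gamma=0.2, kernel="rbf").fit(x, y)
        reduced = SVC(C=1.0, gamma=0.2, kernel="rbf").fit(x[:, :3], y)
        np.testing.assert_allclose(
            full.decision_function(x), reduced.decision_function(x[:, :3]),
            atol=1e-8,
        )

    def test_single_feature_rejected(self, rng):
        with pytest.raises(ValueError, match="2 features"):
            rank_features(rng.standard_normal((10, 1)),
                          np.r_[np.ones(5), -np.ones(5)].astype(int),
                          KernelParams())


class TestSubsetSelection:
    def test_pure_noise_curve_stays_moderate(self):
        """On noise the curve is selection-biased above 0.5 (ranking saw
        the CV folds) but shows no strong structure."""
        maxs, means = [], []
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            y = np.r_[np.ones(20), -np.ones(20)].astype(int)
            x = rng.standard_normal((40, 20))
            res = svm_rfe(x, y, KernelParams(C=1.0, gamma=0.05),
                          n_max=20, folds=5, seed=seed)
            maxs.append(res.auc_curve.max())
            means.append(res.auc_curve.mean())
        assert 0.40 <= np.mean(means) <= 0.75
        assert np.mean(maxs) < 0.95

    def test_planted_informative_features_recovered(self):
        recalls, optimal_ns = [], []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = np.r_[np.ones(30), -np.ones(30)].astype(int)
            x = rng.standard_normal((60, 100))
            x[:, :5] += y[:, None] * 0.6
            res = svm_rfe(x, y, KernelParams(C=1.0, gamma=0.01),
                          n_max=30, folds=5, seed=seed)
            recalls.append(len(set(res.selected) & set(range(5))) / 5)
            optimal_ns.append(res.optimal_n)
        assert np.median(recalls) >= 0.8
        assert np.median(optimal_ns) <= 15

    def test_weights_linear_rescale_of_ranks(self, rng):
        x = rng.standard_normal((20, 6))
        x[:, 0] += np.r_[np.ones(10), -np.ones(10)] * 2
        y = np.r_[np.ones(10), -np.ones(10)].astype(int)
        res = rank_features(x, y, KernelParams(C=1.0, gamma=0.1))
        res.auc_curve = np.array([0.6, 0.7, 0.9, 0.85])
        res.optimal_n = 3
        res.selected = res.ranking[:3]
        res.weights = np.linspace(1.0, 0.0, 3)
        np.testing.assert_allclose(res.weights, [1.0, 0.5, 0.0])

    def test_argmax_tie_goes_to_smallest_subset(self, rng):
        x = rng.standard_normal((24, 5))
        x[:, 0] += np.r_[np.ones(12), -np.ones(12)] * 4  # saturates early
        y = np.r_[np.ones(12), -np.ones(12)].astype(int)
        res = svm_rfe(x, y, KernelParams(C=1.0, gamma=0.1),
                      n_max=5, folds=4, seed=0)
        ties = np.flatnonzero(res.auc_curve == res.auc_curve.max())
        assert res.optimal_n == ties[0] + 1

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((30, 12))
        y = np.r_[np.ones(15), -np.ones(15)].astype(int)
        a = svm_rfe(x, y, KernelParams(C=1.0, gamma=0.05), folds=5, seed=3)
        b = svm_rfe(x, y, KernelParams(C=1.0, gamma=0.05), folds=5, seed=3)
        np.testing.assert_array_equal(a.ranking, b.ranking)
        np.testing.assert_array_equal(a.auc_curve, b.auc_curve)
        assert a.optimal_n == b.optimal_n
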