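"""ROC/AUC, repeated k-fold, LOOCV, and the hold-out protocol."""

import numpy as np
import pytest

from dfcpipe.evaluation import (
    holdout_protocol,
    loocv,
    repeated_kfold,
    roc_auc,
)
from dfcpipe.rfe import KernelParams

PARAMS = KernelParams(C=1.0, gamma=0.1)


def mann_whitney_auc(scores, labels):
    """Independent oracle: probability a random positive outscores a random
    negative, ties counted one half."""
    pos = scores[labels == +1]
    neg = scores[labels == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_separable(n_per_class, rng, spread=4.0):
    x = np.r_[rng.normal(-spread, 0.3, (n_per_class, 2)),
              rng.normal(spread, 0.3, (n_per_class, 2))]
    y = np.r_[-np.ones(n_per_class), np.ones(n_per_class)].astype(int)
    return x, y


class TestRocAuc:
    def test_hand_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([-1, -1, +1, +1])
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.75, abs=1e-12)

    def test_perfect_ordering(self):
        _, auc = roc_auc(np.array([1, 2, 3, 4.0]), np.array([-1, -1, 1, 1]))
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc(np.zeros(6), np.array([1, 1, 1, -1, -1, -1]))
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(20):
            n = rng.integers(6, 30)
            labels = np.where(rng.random(n) < 0.5, 1, -1)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.standard_normal(n), 1)  # force some ties
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels),
                                        abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestRepeatedKfold:
    def test_separable_gives_perfect_metrics_every_round(self, rng):
        x, y = make_separable(15, rng)
        rep = repeated_kfold(x, y, PARAMS, k=5, rounds=5, seed=0)
        assert rep.accuracy == 1.0 and rep.auc == 1.0
        assert np.all(rep.round_metrics["auc"] == 1.0)

    def test_accuracy_identity_with_sens_spec(self, rng):
        x = rng.standard_normal((30, 3))
        y = np.r_[np.ones(12), -np.ones(18)].astype(int)
        rep = repeated_kfold(x, y, PARAMS, k=3, rounds=4, seed=1)
        for r in range(4):
            sens = rep.round_metrics["sensitivity"][r]
            spec = rep.round_metrics["specificity"][r]
            acc = rep.round_metrics["accuracy"][r]
            assert acc == pytest.approx((sens * 12 + spec * 18) / 30, abs=1e-12)

    def test_seeded_reproducibility(self, rng):
        x = rng.standard_normal((24, 4))
        y = np.r_[np.ones(12), -np.ones(12)].astype(int)
        a = repeated_kfold(x, y, PARAMS, k=4, rounds=3, seed=9)
        b = repeated_kfold(x, y, PARAMS, k=4, rounds=3, seed=9)
        np.testing.assert_array_equal(a.round_metrics["auc"],
                                      b.round_metrics["auc"])

    def test_k_exceeding_group_size_rejected(self, rng):
        x = rng.standard_normal((12, 2))
        y = np.r_[np.ones(3), -np.ones(9)].astype(int)
        with pytest.raises(ValueError, match="smaller group"):
            repeated_kfold(x, y, PARAMS, k=5, rounds=1)


class TestLoocv:
    def test_separable_perfect(self, rng):
        x, y = make_separable(8, rng)
        rep = loocv(x, y, PARAMS)
        assert rep.accuracy == 1.0 and rep.auc == 1.0

    def test_two_subject_degenerate_contract(self):
        """n=2, one per class: each training fold is single-class, the
        degenerate model predicts the lone class, so both held-out
        subjects are assigned the opposite class."""
        x = np.array([[0.0], [1.0]])
        y = np.array([+1, -1])
        with pytest.warns(UserWarning, match="single-class"):
            rep = loocv(x, y, PARAMS)
        assert rep.accuracy == 0.0
        with pytest.warns(UserWarning):
            rep2 = loocv(x, y, PARAMS)
        assert rep2.accuracy == rep.accuracy  # deterministic

    def test_agrees_with_kfold_at_k_equals_n(self, rng):
        x = rng.standard_normal((10, 2)) + \
            np.r_[np.ones(5), -np.ones(5)][:, None]
        y = np.r_[np.ones(5), -np.ones(5)].astype(int)
        loo = loocv(x, y, PARAMS)
        kf = repeated_kfold(x, y, PARAMS, k=10, rounds=1, seed=0,
                            stratified=False)
        assert kf.accuracy == pytest.approx(loo.accuracy)
        assert kf.auc == pytest.approx(loo.auc)

    def test_invariant_under_subject_reordering(self, rng):
        x = rng.standard_normal((14, 3))
        y = np.r_[np.ones(7), -np.ones(7)].astype(int)
        perm = rng.permutation(14)
        a = loocv(x, y, PARAMS)
        b = loocv(x[perm], y[perm], PARAMS)
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.auc == pytest.approx(b.auc)


class TestHoldout:
    def test_paper_shaped_split_smoke(self, rng):
        """99 subjects split ~80/20 (73 train / 26 test) runs end-to-end
        and reports both metric sets."""
        y = np.r_[np.ones(43), -np.ones(56)].astype(int)
        x = rng.standard_normal((99, 300))
        x[:, :10] += y[:, None] * 1.5
        cov = np.column_stack([rng.integers(0, 2, 99), rng.normal(13, 4, 99)])
        rep = holdout_protocol(x, y, cov, split_fraction=26, seed=0,
                               params=PARAMS, alpha=0.01, screen_scope="full",
                               n_max=15, inner_folds=4, train_cv_k=5,
                               train_cv_rounds=2)
        assert rep.n_train == 73 and rep.n_test == 26
        assert 0.0 <= rep.test.auc <= 1.0
        assert rep.train.protocol.startswith("holdout-train-cv")
        assert rep.test.protocol == "holdout-test"

    def test_train_only_scope_runs_screening_inside_folds(self, rng):
        y = np.r_[np.ones(20), -np.ones(20)].astype(int)
        x = rng.standard_normal((40, 120))
        x[:, :6] += y[:, None] * 1.5
        cov = rng.standard_normal((40, 2))
        rep = holdout_protocol(x, y, cov, split_fraction=0.25, seed=1,
                               params=PARAMS, alpha=0.01,
                               screen_scope="train_only", n_max=10,
                               inner_folds=3, train_cv_k=3, train_cv_rounds=2)
        assert rep.train.protocol == "holdout-train-cv[train_only]"

    def test_planted_effect_test_auc_tracks_train_cv(self):
        """With a real signal the held-out AUC stays close to the train-CV
        estimate (median over seeds)."""
        gaps = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.r_[np.ones(30), -np.ones(30)].astype(int)
            x = rng.standard_normal((60, 200))
            x[:, :8] += y[:, None] * 1.0
            cov = rng.standard_normal((60, 2))
            rep = holdout_protocol(x, y, cov, split_fraction=0.25, seed=seed,
                                   params=KernelParams(C=1.0, gamma=0.02),
                                   alpha=0.01, screen_scope="full", n_max=12,
                                   inner_folds=4, train_cv_k=5,
                                   train_cv_rounds=3)
            gaps.append(abs(rep.test.auc - rep.train.auc))
        assert np.median(gaps) <= 0.15

    def test_single_class_split_rejected(self, rng):
        x = rng.standard_normal((10, 5))
        y = np.r_[np.ones(9), -np.ones(1)].astype(int)
        with pytest.raises(ValueError):
            holdout_protocol(x, y, rng.standard_normal((10, 2)),
                             split_fraction=0.2, params=PARAMS)

    def test_unknown_scope_rejected(self, rng):
        x = rng.standard_normal((20, 5))
        y = np.r_[np.ones(10), -np.ones(10)].astype(int)
        with pytest.raises(ValueError, match="screen_scope"):
            holdout_protocol(x, y, rng.standard_normal((20, 2)),
                             params=PARAMS, screen_scope="everything")
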