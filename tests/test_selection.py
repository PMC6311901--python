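import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from ribofeat import (
    ConfusionCounts,
    FeatureMatrix,
    accuracy,
    confusion,
    default_grid,
    fit_l1_lr,
    report_features,
    select_C,
    sweep_C,
    synthetic_feature_matrix,
)
from ribofeat.selection import SweepResult


def separable_fixture(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    x = np.where(y == 1, 0.8, 0.2) + rng.normal(0, 0.02, n)
    X = np.column_stack([x, rng.random(n)])
    return X, y


class TestFit:
    def test_tiny_c_zeroes_everything(self):
        X, y = separable_fixture()
        m = fit_l1_lr(X, y, C=1e-6)
        assert np.all(m.w == 0.0)
        assert m.c == 0.0

    def test_separating_feature_gets_positive_weight(self):
        X, y = separable_fixture()
        m = fit_l1_lr(X, y, C=100.0)
        assert m.w[0] > 0
        assert accuracy(confusion(y, m.predict(X))) == 1.0
        # agrees in direction with an (effectively) unpenalised fit
        ref = LogisticRegression(C=1e6, max_iter=2000).fit(X, y)
        assert np.sign(ref.coef_[0][0]) == np.sign(m.w[0])

    def test_duplicated_column_splits_l1_mass(self):
        X, y = separable_fixture()
        single = fit_l1_lr(X[:, :1], y, C=1.0)
        dup = fit_l1_lr(np.column_stack([X[:, 0], X[:, 0]]), y, C=1.0)
        assert len(dup.nonzero) <= 2
        assert dup.w.sum() == pytest.approx(single.w[0], rel=0.05)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 2))
        with pytest.raises(ValueError):
            fit_l1_lr(X, np.zeros(10, dtype=int), C=1.0)

    def test_objective_no_worse_than_zero_model(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            fm, _ = synthetic_feature_matrix(40, 6, {"f01": 0.1}, seed=seed)
            X, y = fm.X.to_numpy(), fm.y
            for C in (0.01, 0.1, 1.0):
                m = fit_l1_lr(X, y, C=C)
                zero = fit_l1_lr(X, y, C=C)
                zero.w = np.zeros_like(zero.w)
                zero.c = 0.0
                assert m.objective(X, y) <= zero.objective(X, y) + 1e-6


class TestAccuracy:
    @pytest.mark.parametrize(
        "cc,expected",
        [
            (ConfusionCounts(3, 2, 1, 2), 0.625),
            (ConfusionCounts(4, 6, 0, 0), 1.0),
            (ConfusionCounts(0, 0, 3, 2), 0.0),
        ],
    )
    def test_values(self, cc, expected):
        assert accuracy(cc) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))


class TestSweep:
    def test_zero_model_baseline_equals_majority_fraction(self):
        fm, _ = synthetic_feature_matrix(40, 6, {"f00": 0.1}, seed=3)
        # unbalance the classes: drop some positives
        keep = np.concatenate([np.arange(40), np.arange(40, 70)])
        fm = FeatureMatrix(fm.X.iloc[keep], fm.y[keep])
        sweep = sweep_C(fm, grid=[1e-6, 0.5], split_seed=1)
        yte = fm.y[sweep.test_idx]
        majority = max((yte == 0).mean(), (yte == 1).mean())
        assert sweep.nonzero_counts[0] == 0
        assert sweep.accuracies[0] == pytest.approx(majority)

    def test_nonzero_counts_grow_along_path(self):
        fm, _ = synthetic_feature_matrix(50, 8, {"f00": 0.1, "f05": -0.1}, seed=4)
        sweep = sweep_C(fm, grid=[1e-4, 1.0], split_seed=0)
        assert sweep.nonzero_counts[0] <= sweep.nonzero_counts[-1]

    def test_rerun_is_bit_identical(self):
        fm, _ = synthetic_feature_matrix(30, 5, {"f02": 0.1}, seed=5)
        g = default_grid(0.01, 0.5, 0.05)
        s1 = sweep_C(fm, grid=g, split_seed=7)
        s2 = sweep_C(fm, grid=g, split_seed=7)
        assert np.array_equal(s1.accuracies, s2.accuracies)
        assert np.array_equal(s1.nonzero_counts, s2.nonzero_counts)
        assert np.array_equal(s1.cv_accuracies, s2.cv_accuracies)

    def test_empty_grid_rejected(self):
        fm, _ = synthetic_feature_matrix(20, 4, {}, seed=6)
        with pytest.raises(ValueError):
            sweep_C(fm, grid=[])


def fake_sweep(grid, accs):
    grid = np.asarray(grid, dtype=float)
    n = 40
    rng = np.random.default_rng(0)
    X = rng.random((n, 2))
    y = np.array([0, 1] * (n // 2))
    return SweepResult(
        grid=grid,
        nonzero_counts=np.zeros(len(grid), dtype=int),
        accuracies=np.asarray(accs, dtype=float),
        cv_accuracies=np.asarray(accs, dtype=float),
        split_seed=0,
        train_idx=np.arange(n),
        test_idx=np.arange(n),
        feature_names=["a", "b"],
        X=X,
        y=y,
    )


class TestSelectC:
    def test_flat_curve_chooses_smallest(self):
        s = fake_sweep([0.01, 0.1, 1.0], [0.8, 0.8, 0.8])
        assert select_C(s)[0] == 0.01

    def test_rise_then_plateau(self):
        s = fake_sweep([0.01, 0.05, 0.1, 0.5, 1.0], [0.55, 0.70, 0.82, 0.825, 0.82])
        assert select_C(s)[0] == 0.1

    def test_epsilon_zero_is_argmax_with_smallest_tie(self):
        s = fake_sweep([0.01, 0.1, 1.0], [0.7, 0.9, 0.9])
        assert select_C(s, epsilon=0.0)[0] == 0.1


class TestReport:
    def test_sorted_by_magnitude_with_signs(self):
        fm, _ = synthetic_feature_matrix(30, 3, {}, seed=8)
        m = fit_l1_lr(fm.X.to_numpy(), fm.y, C=1.0, feature_names=["a", "b", "c"])
        m.w = np.array([0.0, 0.9, -0.3])
        rep = report_features(m)
        assert [(r.feature, r.sign, r.rank) for r in rep] == [("b", "+", 1), ("c", "-", 2)]

    def test_all_zero_model_empty_report(self):
        fm, _ = synthetic_feature_matrix(30, 3, {}, seed=9)
        m = fit_l1_lr(fm.X.to_numpy(), fm.y, C=1e-6)
        assert report_features(m) == []
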