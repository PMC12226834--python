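"""SVM training, tuning and exhaustive leave-two-out cross-validation."""

import numpy as np
import pandas as pd
import pytest

from cubsign.classify import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    SvmConfig,
    classification_metrics,
    leave_two_out_cv,
    train_svm,
    tune,
)

from conftest import FAST_GRID


def clusters(n_pos=8, n_neg=8, gap=6.0, sd=0.5, seed=0, n_features=3):
    rng = np.random.default_rng(seed)
    Xp = rng.normal(0.0, sd, size=(n_pos, n_features))
    Xn = rng.normal(0.0, sd, size=(n_neg, n_features))
    Xn[:, 0] += gap
    X = np.vstack([Xp, Xn])
    y = np.array([POSITIVE_LABEL] * n_pos + [NEGATIVE_LABEL] * n_neg)
    return X, y


def as_frame(X, y):
    idx = [f"s{i}" for i in range(len(y))]
    cols = [f"f{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, index=idx, columns=cols), pd.Series(y, index=idx)


class TestTrainSvm:
    def test_separable_training_accuracy(self):
        X, y = clusters()
        clf = train_svm(X, y, SvmConfig(kernel="linear", cost=100.0))
        assert (clf.predict(X) == y).all()

    def test_label_swap_flips_predictions(self):
        X, y = clusters(seed=2)
        y_swapped = np.where(y == POSITIVE_LABEL, NEGATIVE_LABEL, POSITIVE_LABEL)
        cfg = SvmConfig(kernel="radial", cost=5.0)
        p1 = train_svm(X, y, cfg).predict(X)
        p2 = train_svm(X, y_swapped, cfg).predict(X)
        assert (p1 != p2).all()

    def test_duplicating_samples_preserves_boundary(self):
        X, y = clusters(seed=3)
        cfg = SvmConfig(kernel="linear", cost=1.0, class_weights={
            POSITIVE_LABEL: 1.0, NEGATIVE_LABEL: 1.0})
        probe = np.random.default_rng(4).normal(0, 3, size=(50, X.shape[1]))
        p1 = train_svm(X, y, cfg).predict(probe)
        p2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]), cfg).predict(probe)
        assert (p1 == p2).all()

    def test_single_class_rejected(self):
        X, y = clusters(n_neg=0)
        with pytest.raises(ValueError):
            train_svm(X, y, SvmConfig())

    def test_inverse_frequency_weighting_default(self):
        # 2:1 imbalance with overlapping classes: weighting keeps the
        # minority class from being swallowed
        X, y = clusters(n_pos=20, n_neg=10, gap=1.0, sd=1.0, seed=5)
        clf = train_svm(X, y, SvmConfig(kernel="linear", cost=1.0))
        assert clf.class_weight_[list(clf.classes_).index(NEGATIVE_LABEL)] > 1.0


class TestTune:
    def test_single_point_grid_returned_directly(self):
        X, y = clusters()
        cfg = tune(X, y, kernels=("sigmoid",), costs=(3.0,))
        assert (cfg.kernel, cfg.cost) == ("sigmoid", 3.0)

    def test_separable_data_reaches_perfect_config(self):
        X, y = clusters()
        cfg = tune(X, y, kernels=("linear", "radial"), costs=(1.0, 10.0), seed=0)
        from cubsign.classify import _inner_cv_accuracy

        assert _inner_cv_accuracy(X, y, cfg, seed=0) == 1.0

    def test_cost_tie_breaks_low(self):
        # trivially separable: every cost ties at accuracy 1, smallest wins
        X, y = clusters(gap=20.0)
        cfg = tune(X, y, kernels=("linear",), costs=(5.0, 0.5, 50.0), seed=0)
        assert cfg.cost == 0.5

    def test_kernel_tie_breaks_by_order(self):
        X, y = clusters(gap=20.0)
        cfg = tune(X, y, kernels=("sigmoid", "linear"), costs=(1.0,), seed=0)
        assert cfg.kernel == "linear"

    def test_empty_grid_rejected(self):
        X, y = clusters()
        with pytest.raises(ValueError):
            tune(X, y, kernels=(), costs=())


class TestClassificationMetrics:
    def test_all_correct(self):
        df = pd.DataFrame(
            {"true": [POSITIVE_LABEL, NEGATIVE_LABEL], "pred": [POSITIVE_LABEL, NEGATIVE_LABEL]}
        )
        assert classification_metrics(df) == (1.0, 1.0, 1.0)

    def test_one_sided_failure(self):
        df = pd.DataFrame(
            {
                "true": [POSITIVE_LABEL] * 5 + [NEGATIVE_LABEL] * 5,
                "pred": [POSITIVE_LABEL] * 10,
            }
        )
        assert classification_metrics(df) == (1.0, 0.0, 0.5)

    def test_arithmetic(self):
        true = [POSITIVE_LABEL] * 10 + [NEGATIVE_LABEL] * 10
        pred = (
            [POSITIVE_LABEL] * 9 + [NEGATIVE_LABEL]
            + [NEGATIVE_LABEL] * 8 + [POSITIVE_LABEL] * 2
        )
        sens, spec, acc = classification_metrics(pd.DataFrame({"true": true, "pred": pred}))
        assert (sens, spec, acc) == (0.9, 0.8, 0.85)


class TestLeaveTwoOut:
    def test_iteration_and_prediction_counts(self):
        X, y = as_frame(*clusters(n_pos=3, n_neg=2, seed=1))
        rep = leave_two_out_cv(X, y, **FAST_GRID, seed=0)
        assert rep.n_iterations == 6
        assert len(rep.predictions) == 12

    def test_every_sample_tested_once_per_opposite(self):
        X, y = as_frame(*clusters(n_pos=4, n_neg=3, seed=2))
        rep = leave_two_out_cv(X, y, **FAST_GRID, seed=0)
        counts = rep.predictions.groupby("sample_id").size()
        for sid in X.index:
            expected = 3 if y[sid] == POSITIVE_LABEL else 4
            assert counts[sid] == expected

    def test_perfectly_separable_classes(self):
        X, y = as_frame(*clusters(n_pos=5, n_neg=5, gap=10.0, seed=3))
        rep = leave_two_out_cv(X, y, **FAST_GRID, seed=0)
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (1.0, 1.0, 1.0)

    def test_balanced_accuracy_identity(self):
        X, y = as_frame(*clusters(n_pos=6, n_neg=6, gap=1.0, sd=2.0, seed=4))
        rep = leave_two_out_cv(X, y, **FAST_GRID, seed=0)
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2
        )

    def test_deterministic_given_seed(self):
        X, y = as_frame(*clusters(n_pos=4, n_neg=4, gap=1.5, sd=1.5, seed=5))
        r1 = leave_two_out_cv(X, y, seed=9, kernels=("linear", "radial"), costs=(0.1, 1.0))
        r2 = leave_two_out_cv(X, y, seed=9, kernels=("linear", "radial"), costs=(0.1, 1.0))
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)

    def test_small_class_rejected(self):
        X, y = as_frame(*clusters(n_pos=1, n_neg=5))
        with pytest.raises(ValueError):
            leave_two_out_cv(X, y, **FAST_GRID)

    def test_summary_mentions_counts(self):
        X, y = as_frame(*clusters(n_pos=3, n_neg=3, seed=6))
        rep = leave_two_out_cv(X, y, **FAST_GRID, seed=0, tune_mode="once")
        s = rep.summary()
        assert "iterations" in s and "9" in s


class TestFoldIsolation:
    def test_canary_feature_never_leaks_into_fold_scalers(self):
        # canary: constant (0) in the training fold of the first iteration,
        # extreme only in that iteration's two withheld samples. If test rows
        # leaked into fold standardization, the canary (and the other
        # columns' parameters) would shift; instead the fold scaler must be
        # blind to it.
        X, y = as_frame(*clusters(n_pos=4, n_neg=4, gap=3.0, seed=7))
        base = leave_two_out_cv(
            X, y, **FAST_GRID, seed=0, record_fold_details=True
        )
        Xc = X.copy()
        Xc["canary"] = 0.0
        first_present = X.index[(y == POSITIVE_LABEL).to_numpy()][0]
        first_absent = X.index[(y == NEGATIVE_LABEL).to_numpy()][0]
        Xc.loc[[first_present, first_absent], "canary"] = 1e6
        with pytest.warns(UserWarning, match="zero-variance"):
            rep = leave_two_out_cv(
                Xc, y, **FAST_GRID, seed=0, record_fold_details=True
            )
        # iteration 0 withholds exactly (first_present, first_absent)
        s_base, s_can = base.fold_scalers[0], rep.fold_scalers[0]
        assert "canary" in s_can.zero_variance
        pd.testing.assert_series_equal(s_base.mean_, s_can.mean_[s_base.mean_.index])
        pd.testing.assert_series_equal(s_base.sd_, s_can.sd_[s_base.sd_.index])
        # and that fold's predictions are unchanged by the canary
        it0 = rep.predictions["iteration"] == 0
        pd.testing.assert_frame_equal(
            rep.predictions[it0].drop(columns=[]),
            base.predictions[base.predictions["iteration"] == 0],
        )
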