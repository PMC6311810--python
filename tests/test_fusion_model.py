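"""Unit tests for QC, normalization, splitting, the ANN and evaluation."""

import numpy as np
import pytest

from pulsebp.errors import ParameterError, PredictionRefused
from pulsebp.fusion_model import (
    BPModel,
    FeatureVector,
    NormStats,
    ThresholdMatrix,
    TrainConfig,
    TrainLog,
    denormalize,
    evaluate,
    normalize_apply,
    normalize_fit,
    predict,
    qc_filter,
    split_data,
    train_ann,
)


def make_vector(rng, period=0.8, amplitude=1.0):
    values = np.concatenate([
        rng.uniform(0.1, 0.9, size=5),  # FC, Sss, Sds, Tft, Tst
        [rng.uniform(5.0, 20.0)],       # SL
        rng.uniform(0.0, 1.0, size=3),  # A1-A3
        rng.uniform(-np.pi + 0.01, np.pi, size=3),  # P1-P3
    ])
    return FeatureVector(values=values, raw={"period": period, "amplitude": amplitude})


class TestFeatureVector:
    def test_requires_12_entries(self):
        with pytest.raises(ParameterError):
            FeatureVector(values=np.zeros(11))


class TestQcFilter:
    def test_all_within_bounds_accepted(self):
        rng = np.random.default_rng(0)
        vectors = [make_vector(rng) for _ in range(20)]
        accepted, report = qc_filter(vectors, ThresholdMatrix.default())
        assert len(accepted) == 20
        assert report == {}

    def test_period_violation_rejected(self):
        rng = np.random.default_rng(1)
        vectors = [make_vector(rng) for _ in range(5)]
        vectors[2].raw["period"] = 2.5
        accepted, report = qc_filter(vectors, ThresholdMatrix.default())
        assert len(accepted) == 4
        assert report == {"period": 1}
        assert vectors[2].qc_pass is False

    def test_planted_amplitude_outliers(self):
        rng = np.random.default_rng(2)
        vectors = [make_vector(rng, amplitude=1.0) for _ in range(100)]
        for i in range(7):
            vectors[i * 13].raw["amplitude"] = 100.0
        tm = ThresholdMatrix.default(amplitude_median=1.0)
        accepted, report = qc_filter(vectors, tm)
        assert len(accepted) == 93
        assert report == {"amplitude": 7}

    def test_nonfinite_rejected(self):
        rng = np.random.default_rng(3)
        v = make_vector(rng)
        v.values[0] = np.nan
        accepted, report = qc_filter([v], ThresholdMatrix.default())
        assert accepted == []
        assert report == {"finite": 1}

    def test_empty_input(self):
        accepted, report = qc_filter([], ThresholdMatrix.default())
        assert accepted == [] and report == {}

    def test_invalid_bounds_raise(self):
        with pytest.raises(ParameterError):
            ThresholdMatrix(bounds={"period": (2.0, 0.3)})


class TestNormalization:
    def test_two_point_column(self):
        Xn, stats = normalize_fit(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(Xn, [[-1.0], [1.0]])
        assert stats.mean[0] == 2.0 and stats.scale[0] == 1.0

    def test_idempotence(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 4))
        Xn, _ = normalize_fit(X)
        Xnn, _ = normalize_fit(Xn)
        np.testing.assert_allclose(Xnn, Xn, atol=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3)) * 10 + 5
        Xn, stats = normalize_fit(X)
        np.testing.assert_allclose(denormalize(Xn, stats), X, atol=1e-12)
        np.testing.assert_allclose(normalize_apply(X, stats), Xn, atol=1e-12)

    def test_constant_column_warns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning):
            Xn, stats = normalize_fit(X)
        np.testing.assert_allclose(Xn[:, 0], 0.0)
        assert stats.constant_columns[0] and not stats.constant_columns[1]

    def test_normalized_moments(self):
        rng = np.random.default_rng(6)
        Xn, _ = normalize_fit(rng.normal(size=(200, 5)))
        np.testing.assert_allclose(Xn.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xn.std(axis=0), 1.0, atol=1e-12)


class TestSplitData:
    def test_sizes_100(self):
        s = split_data(100, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (70, 15, 15)

    def test_sizes_10_remainder_to_train(self):
        s = split_data(10, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (8, 1, 1)

    def test_disjoint_exhaustive_property(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(10, 500))
            seed = int(rng.integers(0, 2**31 - 1))
            s = split_data(n, seed=seed)
            union = np.concatenate([s.train, s.validation, s.test])
            assert len(union) == n
            assert len(np.unique(union)) == n

    def test_determinism(self):
        a, b = split_data(123, seed=9), split_data(123, seed=9)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_invalid_fractions(self):
        with pytest.raises(ParameterError):
            split_data(100, fractions=(0.5, 0.3, 0.3), seed=0)
        with pytest.raises(ParameterError):
            split_data(5, seed=0)


def linear_problem(n=200, p=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    w = rng.normal(size=(p, 2))
    y = X @ w + np.array([120.0, 80.0])
    return X, y


class TestTrainAnn:
    def test_zero_targets_trivial_convergence(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 3))
        Y = np.zeros((50, 2))
        model = train_ann((X, Y), config=TrainConfig(hidden=5, seed=0, max_iter=2))
        # zero-initialized output layer + zero targets: loss already zero
        np.testing.assert_allclose(model.forward(X), 0.0, atol=1e-9)

    def test_learns_linear_map(self):
        X, y = linear_problem()
        model = train_ann((X, y), config=TrainConfig(hidden=10, seed=0, max_iter=500))
        rmse = np.sqrt(np.mean((model.forward(X) - y) ** 2))
        assert rmse < 0.5

    def test_seed_determinism(self):
        X, y = linear_problem(seed=1)
        cfg = TrainConfig(hidden=8, seed=3, max_iter=100)
        m1 = train_ann((X, y), config=cfg)
        m2 = train_ann((X, y), config=cfg)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(m1.w2, m2.w2)

    def test_architecture(self):
        X, y = linear_problem(p=12)
        model = train_ann((X, y), config=TrainConfig(hidden=30, seed=0, max_iter=5))
        assert model.architecture == (12, 30, 2)
        assert model.w1.shape == (12, 30)
        assert model.w2.shape == (30, 2)

    def test_early_stopping_logs(self):
        X, y = linear_problem(n=120, seed=2)
        s = split_data(len(X), seed=0)
        model = train_ann(
            (X[s.train], y[s.train]),
            (X[s.validation], y[s.validation]),
            TrainConfig(hidden=10, seed=0, max_iter=1000),
        )
        assert model.log.iterations > 0
        assert len(model.log.val_trace) > 0

    def test_gradient_matches_finite_differences(self):
        from pulsebp.fusion_model import _loss_grad

        rng = np.random.default_rng(10)
        n_in, hidden, n_out = 3, 4, 2
        Xn = rng.normal(size=(20, n_in))
        Yn = rng.normal(size=(20, n_out))
        n_par = n_in * hidden + hidden + hidden * n_out + n_out
        theta = rng.normal(size=n_par) * 0.5
        loss0, grad = _loss_grad(theta, Xn, Yn, n_in, hidden, n_out)
        eps = 1e-6
        for k in rng.choice(n_par, size=10, replace=False):
            step = np.zeros(n_par)
            step[k] = eps
            lp, _ = _loss_grad(theta + step, Xn, Yn, n_in, hidden, n_out)
            lm, _ = _loss_grad(theta - step, Xn, Yn, n_in, hidden, n_out)
            assert grad[k] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-8)

    def test_nonfinite_data_raises(self):
        from pulsebp.errors import TrainingError

        X, y = linear_problem(n=20)
        X[0, 0] = np.nan
        with pytest.raises(TrainingError):
            train_ann((X, y))


@pytest.fixture(scope="module")
def trained():
    X, y = linear_problem(n=300, seed=4)
    model = train_ann((X, y), config=TrainConfig(hidden=10, seed=0, max_iter=500))
    return model, X, y


class TestPredictEvaluate:

    def test_training_row_consistency(self, trained):
        model, X, y = trained
        pred = model.forward(X[:1])[0]
        assert abs(pred[0] - y[0, 0]) < 2.0

    def test_duplicated_inputs_identical(self, trained):
        model, X, _ = trained
        p = model.forward(np.vstack([X[0], X[0]]))
        np.testing.assert_array_equal(p[0], p[1])

    def test_mean_point_within_target_range(self, trained):
        model, X, y = trained
        pred = model.forward(X.mean(axis=0))[0]
        for k in range(2):
            lo, hi = y[:, k].min(), y[:, k].max()
            assert lo - 5 <= pred[k] <= hi + 5

    def test_refuses_failed_qc(self, trained):
        model, _, _ = trained
        vec = FeatureVector(values=np.zeros(12), qc_pass=False)
        with pytest.raises(PredictionRefused):
            predict(model, vec)

    def test_perfect_predictor_report(self):
        # identity-like model: evaluate against its own outputs
        stats = NormStats(np.zeros(2), np.ones(2), np.zeros(2, dtype=bool))
        model = BPModel(
            w1=np.zeros((2, 3)), b1=np.zeros(3),
            w2=np.zeros((3, 2)), b2=np.array([120.0, 80.0]),
            x_stats=stats,
            y_stats=NormStats(np.zeros(2), np.ones(2), np.zeros(2, dtype=bool)),
            architecture=(2, 3, 2), config=TrainConfig(), log=TrainLog(),
        )
        X = np.zeros((5, 2))
        y = np.tile([120.0, 80.0], (5, 1))
        report = evaluate(model, X, y)
        assert report.max_abs_error == 0.0
        assert np.isnan(report.pearson_r).all()  # constant targets flagged

    def test_offset_predictor_report(self):
        stats = NormStats(np.zeros(1), np.ones(1), np.zeros(1, dtype=bool))
        model = BPModel(
            w1=np.zeros((1, 2)), b1=np.zeros(2),
            w2=np.zeros((2, 2)), b2=np.array([1.0, 1.0]),
            x_stats=stats,
            y_stats=NormStats(np.zeros(2), np.ones(2), np.zeros(2, dtype=bool)),
            architecture=(1, 2, 2), config=TrainConfig(), log=TrainLog(),
        )
        X = np.zeros((8, 1))
        y = np.zeros((8, 2))  # predictor constant 1, targets 0 -> error 1
        report = evaluate(model, X, y)
        assert report.max_abs_error == pytest.approx(1.0)
        np.testing.assert_allclose(report.rmse, 1.0)

    def test_histogram_bin_width(self, trained):
        model, X, y = trained
        report = evaluate(model, X, y)
        widths = np.diff(report.bin_edges)
        np.testing.assert_allclose(widths, 0.5, atol=1e-12)
        assert report.hist_sbp.sum() == len(X)

    def test_empty_test_set_raises(self, trained):
        model, _, _ = trained
        with pytest.raises(ParameterError):
            evaluate(model, np.zeros((0, 4)), np.zeros((0, 2)))
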