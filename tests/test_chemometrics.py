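"""Autoscaling, NIPALS PLSR, LOOCV, metrics, outlier screening."""

import numpy as np
import pytest

from astaxmap.chemometrics import (
    autoscale_apply,
    autoscale_fit,
    loocv_select,
    metrics,
    plsr_fit,
    predict,
    screen_outliers,
)
from astaxmap.cube_model import DomainError, ShapeError


def loocv_naive(x, y, a_max):
    """Oracle: refit a fresh model per fold *and* per component count."""
    n = x.shape[0]
    press = np.zeros(a_max)
    for a in range(1, a_max + 1):
        for i in range(n):
            keep = np.arange(n) != i
            model = plsr_fit(x[keep], y[keep], a)
            press[a - 1] += (y[i] - predict(model, x[i])) ** 2
    return np.sqrt(press / n)


class TestAutoscale:
    def test_training_columns_standardized(self, rng):
        x = rng.normal(2, 5, size=(30, 6))
        xs = autoscale_apply(x, autoscale_fit(x))
        assert np.max(np.abs(xs.mean(axis=0))) < 1e-12
        assert np.max(np.abs(xs.std(axis=0, ddof=1) - 1)) < 1e-12

    def test_hand_computed_two_by_two(self):
        x = np.array([[0.0, 10.0], [2.0, 30.0]])
        xs = autoscale_apply(x, autoscale_fit(x))
        a = 1 / np.sqrt(2)  # both columns scale to +-1/sqrt(2) with ddof=1
        assert np.allclose(xs, [[-a, -a], [a, a]], atol=1e-12)

    def test_new_data_uses_training_parameters(self, rng):
        x_train = rng.normal(size=(20, 3))
        params = autoscale_fit(x_train)
        x_new = rng.normal(10, 1, size=(5, 3))
        expected = (x_new - x_train.mean(0)) / x_train.std(0, ddof=1)
        assert autoscale_apply(x_new, params) == pytest.approx(expected)

    def test_constant_column_named_in_error(self, rng):
        x = rng.normal(size=(10, 4))
        x[:, 2] = 7.0
        with pytest.raises(DomainError, match="2"):
            autoscale_fit(x)


class TestPLSR:
    def test_exact_fit_of_noiseless_linear_response(self, rng):
        x = rng.normal(size=(25, 8))
        y = x @ rng.normal(size=8) + 3.0
        model = plsr_fit(x, y, 8)
        assert np.max(np.abs(predict(model, x) - y)) < 1e-8

    @pytest.mark.parametrize("seed", range(20))
    def test_full_component_model_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(8, 16), rng.integers(2, 6)
        x = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        model = plsr_fit(x, y, min(p, n - 1))
        xc = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(xc, y, rcond=None)[0]
        assert np.max(np.abs(predict(model, x) - xc @ beta)) < 1e-10

    def test_single_column_equals_simple_regression(self, rng):
        x = rng.normal(size=(15, 1))
        y = 2.5 * x[:, 0] + 1.0 + rng.normal(0, 0.1, 15)
        model = plsr_fit(x, y, 1)
        slope = np.cov(x[:, 0], y, ddof=1)[0, 1] / np.var(x[:, 0], ddof=1)
        intercept = y.mean() - slope * x[:, 0].mean()
        assert predict(model, x) == pytest.approx(
            slope * x[:, 0] + intercept, abs=1e-10
        )

    def test_matches_reference_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        x = rng.normal(size=(20, 7))
        y = x @ rng.normal(size=7) + rng.normal(0, 0.5, 20)
        for a in (1, 3, 5):
            model = plsr_fit(x, y, a)
            ref = sklearn.PLSRegression(n_components=a, scale=True).fit(x, y)
            assert predict(model, x) == pytest.approx(
                ref.predict(x).ravel(), abs=1e-8
            )

    def test_coef_reproduces_loadings_path(self, rng):
        x = rng.normal(size=(18, 6))
        y = rng.normal(size=18)
        model = plsr_fit(x, y, 4)
        xs = autoscale_apply(x, model.autoscale)
        # loadings-path prediction: scores then y-loadings
        t = np.zeros((18, model.n_components))
        xd = xs.copy()
        for a in range(model.n_components):
            t[:, a] = xd @ model.weights[:, a]
            xd = xd - np.outer(t[:, a], model.x_loadings[:, a])
        yhat = model.y_mean + (t @ model.y_loadings) * model.y_sd
        assert predict(model, x) == pytest.approx(yhat, abs=1e-10)

    def test_prediction_is_affine(self, rng):
        x = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        model = plsr_fit(x, y, 3)
        u, v = rng.normal(size=5), rng.normal(size=5)
        lhs = predict(model, u + v) + predict(model, np.zeros(5))
        rhs = predict(model, u) + predict(model, v)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_training_mean_predicts_mean_response(self, rng):
        x = rng.normal(size=(14, 4))
        y = rng.normal(size=14)
        model = plsr_fit(x, y, 2)
        assert predict(model, x.mean(axis=0)) == pytest.approx(
            y.mean(), abs=1e-10
        )

    def test_component_count_out_of_range(self, rng):
        with pytest.raises(DomainError):
            plsr_fit(rng.normal(size=(10, 4)), rng.normal(size=10), 10)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(DomainError):
            plsr_fit(rng.normal(size=(10, 4)), np.ones(10), 2)

    def test_band_mismatch_on_predict(self, rng):
        model = plsr_fit(rng.normal(size=(10, 4)), rng.normal(size=10), 2)
        with pytest.raises(ShapeError):
            predict(model, np.zeros(5))


class TestLOOCV:
    def test_one_factor_data_selects_single_component(self, rng):
        t = rng.normal(size=20)
        x = np.outer(t, rng.uniform(0.5, 2.0, size=6))
        y = 3.0 * t + 1.0
        cv = loocv_select(x, y, a_max=4)
        # a single latent factor: nothing left after component 1, so the
        # curve is flat and the tie resolves to A = 1
        assert cv.chosen == 1
        assert cv.rmsecv[0] < 1e-8

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_refit_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, p, a_max = 12, 5, 4
        x = rng.normal(size=(n, p))
        y = x @ rng.normal(size=p) + rng.normal(0, 0.3, n)
        cv = loocv_select(x, y, a_max=a_max)
        assert cv.rmsecv == pytest.approx(loocv_naive(x, y, a_max), abs=1e-10)

    def test_excessive_a_max_capped_with_warning(self, rng):
        x = rng.normal(size=(6, 10))
        y = rng.normal(size=6)
        with pytest.warns(RuntimeWarning, match="capping"):
            cv = loocv_select(x, y, a_max=8)
        assert len(cv.rmsecv) == 4  # min(p, n - 2)

    def test_tie_resolves_to_smallest_count(self):
        from astaxmap.chemometrics import CVResult

        cv = CVResult(rmsecv=np.array([0.5, 0.5, 0.7]), chosen=1)
        assert cv.chosen == 1
        with pytest.raises(DomainError):
            CVResult(rmsecv=np.array([0.5, 0.4]), chosen=1)


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmsep == 0.0
        assert m.r2 == 1.0

    def test_hand_computed_example(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert m.rmsep == pytest.approx(np.sqrt(1 / 3))
        assert m.r2 == pytest.approx(0.5)

    def test_null_model_has_zero_r2(self, rng):
        y = rng.normal(size=30)
        m = metrics(y, np.full(30, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_std_error_definition(self, rng):
        y = rng.normal(size=25)
        yhat = y + rng.normal(0, 0.5, 25)
        m = metrics(y, yhat)
        assert m.std_error == pytest.approx(
            np.std(y - yhat, ddof=1) / np.sqrt(25)
        )

    def test_constant_truth_rejected(self):
        with pytest.raises(DomainError):
            metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestOutlierScreening:
    def test_null_flag_rate_near_alpha(self):
        # under the null, about 2.5% of samples exceed the 97.5% T2 quantile
        rates = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            x = rng.normal(size=(200, 6))
            rep_result = screen_outliers(x, n_pc=2, alpha=0.975)
            rates.append(rep_result.flagged.size / 200)
        assert 0.01 < np.mean(rates) < 0.045

    def test_gross_outlier_flagged(self, rng):
        x = rng.normal(size=(50, 5))
        x[7] += 10 * x.std(axis=0)
        rep = screen_outliers(x)
        assert 7 in rep.flagged

    def test_invariant_to_column_order(self, rng):
        x = rng.normal(size=(60, 6))
        x[3] += 8.0
        a = screen_outliers(x).flagged
        b = screen_outliers(x[:, ::-1]).flagged
        assert np.array_equal(a, b)

    def test_scores_reported_for_review(self, rng):
        rep = screen_outliers(rng.normal(size=(30, 5)), n_pc=2)
        assert rep.scores.shape == (30, 2)
        assert rep.t_squared.shape == (30,)
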