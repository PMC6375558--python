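"""Path-seeking solver: gradients, the 1%-step rule, path structure, agreement
with coordinate-descent lasso oracles, and cross-validated stopping."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso, LinearRegression

from chrde.data import ImputedDataset
from chrde.path import (
    cross_validate_path,
    lambda_ratio,
    loss_gradient,
    seek_path,
    select_on_path,
    step_size,
)
from chrde.penalties import ChrHyperparams, PenaltyPlugin, get_plugin


def make_imputed(X, y):
    X = np.asarray(X, float)
    return ImputedDataset(np.column_stack([np.ones(len(X)), X]), np.asarray(y, float))


class TestGradient:
    def test_hand_example(self):
        # one sample, x=1, y=2, beta=0: phi = (2/1) * 1 * 2 = 4
        data = make_imputed([[1.0]], [2.0])
        np.testing.assert_allclose(loss_gradient([0.0, 0.0], data), [4.0])

    def test_matches_finite_differences(self, small_imputed, rng):
        from chrde.data import aft_loss

        beta = rng.standard_normal(small_imputed.X.shape[1]) * 0.3
        phi = loss_gradient(beta, small_imputed)
        h = 1e-6
        for j in range(1, len(beta)):
            bp, bm = beta.copy(), beta.copy()
            bp[j] += h
            bm[j] -= h
            fd = -(aft_loss(bp, small_imputed) - aft_loss(bm, small_imputed)) / (2 * h)
            assert phi[j - 1] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_lambda_ratio_rejects_bad_slope(self, small_imputed):
        bad = PenaltyPlugin("bad", value=lambda b: b, slope=lambda b: np.zeros_like(b))
        with pytest.raises(ValueError, match="non-positive slope"):
            lambda_ratio(np.zeros(small_imputed.X.shape[1]), small_imputed, bad)


class TestStepSize:
    def test_one_percent_reduction_closed_form(self):
        # L(d) = 1 - 2d + d^2; the 1% rule wants L(d) = 0.99
        d, new_loss = step_size(2.0, 1.0, 1.0)
        assert new_loss == pytest.approx(0.99)
        assert d == pytest.approx((2.0 - np.sqrt(4.0 - 0.04)) / 2.0)
        assert 1.0 - 2 * d + d * d == pytest.approx(0.99)

    def test_negative_gradient_gives_negative_step(self):
        d, new_loss = step_size(-2.0, 1.0, 1.0)
        assert d < 0
        assert new_loss == pytest.approx(0.99)

    def test_capped_at_coordinate_minimum(self):
        # phi tiny: 1% of the loss is unreachable, step to the 1-D minimiser
        d, new_loss = step_size(1e-4, 1.0, 1.0)
        assert d == pytest.approx(5e-5)
        assert new_loss == pytest.approx(1.0 - 1e-8 / 4.0)

    def test_zero_curvature(self):
        assert step_size(1.0, 0.0, 1.0) == (0.0, 1.0)


class TestPathStructure:
    def test_single_predictor_reaches_ols(self, rng):
        x = rng.standard_normal(100)
        y = 2.0 * x + 0.1 * rng.standard_normal(100)
        data = make_imputed(x[:, None], y)
        trace = seek_path(data, get_plugin("lasso"))
        assert trace.converged
        ols = LinearRegression().fit(x[:, None], y)
        end = trace.beta_at(-1)
        assert end[1] == pytest.approx(ols.coef_[0], rel=1e-3)
        assert end[0] == pytest.approx(ols.intercept_, abs=1e-3)

    def test_one_coordinate_per_step(self, rng):
        X = rng.standard_normal((50, 6))
        y = X[:, 0] - X[:, 3] + 0.1 * rng.standard_normal(50)
        data = make_imputed(X, y)
        trace = seek_path(data, get_plugin("lasso"), max_steps=200)
        for i in range(1, min(len(trace), 100)):
            moved = trace.beta_at(i)[1:] - trace.beta_at(i - 1)[1:]
            assert np.count_nonzero(moved) == 1

    def test_loss_strictly_decreasing(self, small_imputed):
        for name in ("lasso", "l12", "enet"):
            trace = seek_path(small_imputed, get_plugin(name), max_steps=400)
            assert np.all(np.diff(trace.loss) < 0)

    def test_nu_increasing_from_zero(self, small_imputed):
        trace = seek_path(small_imputed, get_plugin("lasso"), max_steps=300)
        assert trace.nu[0] == 0.0
        assert np.all(np.diff(trace.nu) > 0)

    def test_most_correlated_feature_enters_first(self, rng):
        # orthogonal design with well-separated correlations
        n = 400
        X = rng.standard_normal((n, 5))
        X -= X.mean(axis=0)
        y = 0.2 * X[:, 0] + 1.0 * X[:, 2] + 0.5 * X[:, 4]
        data = make_imputed(X, y)
        trace = seek_path(data, get_plugin("lasso"), max_steps=50)
        assert trace.step_coord[0] == 2

    def test_chr_path_runs(self, small_imputed):
        plugin = get_plugin("chr", ChrHyperparams(0.5, 0.5, 0.5))
        trace = seek_path(small_imputed, plugin, max_steps=500)
        assert len(trace) > 10
        assert np.all(np.diff(trace.loss) < 0)

    def test_truncation_flag_and_warning(self, small_imputed):
        with pytest.warns(UserWarning, match="truncated"):
            trace = seek_path(small_imputed, get_plugin("lasso"), max_steps=5)
        assert not trace.converged
        assert len(trace) == 6

    def test_beta_at_negative_index(self, small_imputed):
        trace = seek_path(small_imputed, get_plugin("lasso"), max_steps=50)
        np.testing.assert_array_equal(trace.beta_at(-1), trace.beta_at(len(trace) - 1))


class TestAgainstCoordinateDescent:
    def _problem(self, seed=0, n=200, k=10):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, k))
        beta = np.zeros(k)
        beta[:4] = [3.0, -2.0, 1.5, 1.0]
        y = X @ beta + 0.5 * rng.standard_normal(n)
        return X, y

    def test_endpoint_matches_ols(self):
        X, y = self._problem()
        trace = seek_path(make_imputed(X, y), get_plugin("lasso"))
        end = trace.beta_at(-1)[1:]
        ols = LinearRegression().fit(X, y).coef_
        assert np.linalg.norm(end - ols) <= 0.05 * np.linalg.norm(ols)

    def test_midpath_matches_lasso_at_same_penalty_level(self):
        # match points to the coordinate-descent solution through the
        # stationarity level: at penalty weight alpha the oracle satisfies
        # max_j |phi_j| = 2*alpha, so compare at the path point whose
        # max-gradient is closest to that level
        X, y = self._problem()
        data = make_imputed(X, y)
        trace = seek_path(data, get_plugin("lasso"))
        levels = []
        for i in range(len(trace)):
            phi = loss_gradient(trace.beta_at(i), data)
            levels.append(np.abs(phi).max())
        levels = np.asarray(levels)
        for alpha in (0.4, 0.15, 0.05):
            oracle = Lasso(alpha=alpha, fit_intercept=True, tol=1e-10, max_iter=100000)
            oracle.fit(X, y)
            i = int(np.argmin(np.abs(levels - 2.0 * alpha)))
            ours = trace.beta_at(i)[1:]
            err = np.linalg.norm(ours - oracle.coef_)
            assert err <= 0.05 * np.linalg.norm(oracle.coef_)


class TestCrossValidation:
    def test_noiseless_recovery(self, rng):
        X = rng.standard_normal((120, 10))
        y = 2.0 * X[:, 1] - 1.0 * X[:, 7]
        data = make_imputed(X, y)
        plugin = get_plugin("lasso")
        trace = seek_path(data, plugin, max_steps=2000)
        sel = cross_validate_path(data, plugin, trace, folds=5, seed=0)
        beta = sel.point.beta[1:]
        chosen = set(np.flatnonzero(np.abs(beta) > 1e-3))
        assert chosen == {1, 7}

    def test_pure_noise_selects_near_start(self, rng):
        X = rng.standard_normal((100, 20))
        y = rng.standard_normal(100)
        data = make_imputed(X, y)
        plugin = get_plugin("lasso")
        trace = seek_path(data, plugin, max_steps=1500)
        sel = cross_validate_path(data, plugin, trace, folds=5, seed=0)
        # with no signal the CV minimum sits close to the null model
        assert sel.point.active_count <= 5

    def test_selection_matches_cv_minimum(self, small_imputed):
        plugin = get_plugin("lasso")
        trace = seek_path(small_imputed, plugin, max_steps=400)
        sel = cross_validate_path(small_imputed, plugin, trace, folds=5, seed=1)
        assert sel.point.step_index == int(np.argmin(sel.cv_errors))
        assert sel.n_steps_used == len(sel.cv_errors)
        assert len(sel.fold_lengths) == 5

    def test_match_by_nu_close_to_index(self, small_imputed):
        plugin = get_plugin("lasso")
        trace = seek_path(small_imputed, plugin, max_steps=400)
        a = cross_validate_path(small_imputed, plugin, trace, folds=5, seed=1)
        b = cross_validate_path(
            small_imputed, plugin, trace, folds=5, seed=1, match="nu"
        )
        # both matchings must land in the same low-error region
        assert a.cv_errors.min() == pytest.approx(b.cv_errors.min(), rel=0.5)

    def test_invalid_folds(self, small_imputed):
        plugin = get_plugin("lasso")
        trace = seek_path(small_imputed, plugin, max_steps=50)
        with pytest.raises(ValueError, match="folds"):
            cross_validate_path(small_imputed, plugin, trace, folds=1)
        with pytest.raises(ValueError, match="match"):
            cross_validate_path(
                small_imputed, plugin, trace, folds=3, match="bogus"
            )

    def test_select_on_path_wrapper(self, small_imputed):
        plugin = get_plugin("lasso")
        trace = seek_path(small_imputed, plugin, max_steps=200)
        point = select_on_path(trace, small_imputed, plugin, folds=4, seed=2)
        ref = cross_validate_path(small_imputed, plugin, trace, folds=4, seed=2)
        assert point.step_index == ref.point.step_index

    def test_deterministic_given_seed(self, small_imputed):
        plugin = get_plugin("l12")
        trace = seek_path(small_imputed, plugin, max_steps=300)
        s1 = cross_validate_path(small_imputed, plugin, trace, folds=5, seed=9)
        s2 = cross_validate_path(small_imputed, plugin, trace, folds=5, seed=9)
        assert s1.point.step_index == s2.point.step_index
        np.testing.assert_array_equal(s1.cv_errors, s2.cv_errors)
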