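"""BCP core: projection, cost, golden-section search, and the estimator."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from bcperf import (
    BCPEstimator,
    NoiseSpec,
    NoiseWeights,
    PhysioParams,
    SearchSettings,
    TimeSeriesPair,
    bcp_cost,
    estimate_baselines,
    fit_bcp,
    fit_epochs,
    flow_nonlinearity,
    golden_section_fraction,
    golden_section_minimize,
    project_to_model,
    simulate_measured_pair,
    simulate_truth,
)

F0, B0 = 28.0, 11200.0


def curve_b(f, k, f0=F0, b0=B0):
    return b0 * (1.0 + k * flow_nonlinearity(f / f0))


def weighted_dist(a, b, f, k, w):
    return w.w_asl * (a - f) ** 2 + w.w_bold * (b - curve_b(f, k)) ** 2


class TestProjection:
    def test_on_curve_points_unchanged(self, nominal_weights):
        f = np.array([0.8, 1.0, 1.46, 2.0]) * F0
        b = curve_b(f, 0.0495)
        f_hat, b_hat = project_to_model(f, b, 0.0495, F0, B0, nominal_weights)
        assert np.allclose(f_hat, f, atol=1e-6)
        assert np.allclose(b_hat, b, atol=1e-4)

    def test_k_zero_degenerates_to_horizontal_line(self, nominal_weights):
        a = np.array([20.0, 28.0, 40.0])
        b = np.array([B0 - 30, B0, B0 + 50])
        f_hat, b_hat = project_to_model(a, b, 0.0, F0, B0, nominal_weights)
        assert np.allclose(f_hat, a, atol=1e-8)
        assert np.allclose(b_hat, B0)

    def test_matches_dense_grid_search(self, rng, nominal_weights):
        # brute-force oracle: 1e5-point grid over the admissible flow range
        a = F0 * (1 + rng.normal(0, 0.36, 40))
        b = B0 * (1 + rng.normal(0, 0.005, 40))
        k = 0.05
        f_hat, _ = project_to_model(a, b, k, F0, B0, nominal_weights)
        grid = np.linspace(0.05 * F0, 5.0 * F0, 100_000)
        J_all = (
            nominal_weights.w_asl * (a[:, None] - grid) ** 2
            + nominal_weights.w_bold * (b[:, None] - curve_b(grid, k)) ** 2
        )
        J_grid = J_all.min(axis=1)
        f_grid = grid[J_all.argmin(axis=1)]
        J_mine = weighted_dist(a, b, f_hat, k, nominal_weights)
        # never worse than the oracle, and in the same grid cell
        assert np.all(J_mine <= J_grid * (1 + 1e-6) + 1e-15)
        assert np.all(np.abs(f_hat - f_grid) <= grid[1] - grid[0])

    def test_local_minimum_in_free_coordinate(self, rng, nominal_weights):
        a = F0 * (1 + rng.normal(0, 0.3, 30))
        b = B0 * (1 + rng.normal(0, 0.004, 30))
        f_hat, _ = project_to_model(a, b, 0.05, F0, B0, nominal_weights)
        J0 = weighted_dist(a, b, f_hat, 0.05, nominal_weights)
        for eps in (0.99, 1.01):
            J = weighted_dist(a, b, f_hat * eps, 0.05, nominal_weights)
            assert np.all(J >= J0 - 1e-10)

    def test_non_finite_input_rejected(self, nominal_weights):
        with pytest.raises(ValueError):
            project_to_model(np.nan, 1.0, 0.05, F0, B0, nominal_weights)


class TestCost:
    def test_zero_at_true_k_for_noise_free_pair(self, noise_free_pair, nominal_weights):
        truth, pair = noise_free_pair
        assert bcp_cost(pair, truth.params.k, nominal_weights) < 1e-12

    def test_zero_for_baseline_samples_at_any_k(self, nominal_weights):
        pair = TimeSeriesPair(np.full(10, F0), np.full(10, B0), 2.5, f0=F0, b0=B0)
        for k in (-0.05, 0.0, 0.1, 0.3):
            assert bcp_cost(pair, k, nominal_weights) < 1e-14

    def test_matches_independent_reimplementation(self, noisy_pair, nominal_weights):
        # oracle: per-point bounded scalar minimization via scipy, summed
        _, pair = noisy_pair
        k = 0.07

        def dist(f, a, b):
            model_b = pair.b0 * (1 + k * (f - pair.f0) / f)
            return (
                nominal_weights.w_asl * (a - f) ** 2
                + nominal_weights.w_bold * (b - model_b) ** 2
            )

        total = 0.0
        for a, b in zip(pair.asl, pair.bold):
            res = minimize_scalar(
                dist,
                args=(a, b),
                bounds=(0.05 * pair.f0, 5.0 * pair.f0),
                method="bounded",
                options={"xatol": 1e-10},
            )
            total += res.fun
        assert bcp_cost(pair, k, nominal_weights) == pytest.approx(total, rel=1e-9)


class TestGoldenSection:
    def test_fraction_value(self):
        assert 100 * golden_section_fraction() == pytest.approx(38.197, abs=5e-4)

    def test_quadratic_analytic_minimum(self):
        s = SearchSettings(0.0, 0.3, 1e-3)
        k_hat, diag = golden_section_minimize(lambda k: (k - 0.05) ** 2, s)
        assert k_hat == pytest.approx(0.05, abs=1e-3)
        assert diag["bracket"][1] - diag["bracket"][0] <= 1e-3

    def test_matches_grid_argmin_on_random_instances(self, nominal_weights):
        # >= 20 randomized small instances vs exhaustive grid at step 1e-4
        ks = np.arange(-0.1, 0.3 + 1e-12, 1e-4)
        s = SearchSettings()
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = int(r.integers(8, 33))
            flow = 1 + 0.46 * r.random(n)
            k_true = float(r.uniform(0.0, 0.15))
            a = F0 * flow + r.normal(0, 0.1 * F0, n)
            b = curve_b(F0 * flow, k_true) + r.normal(0, 0.003 * B0, n)
            pair = TimeSeriesPair(a, b, 2.5, f0=F0, b0=B0)
            k_hat, _ = golden_section_minimize(
                lambda k: bcp_cost(pair, k, nominal_weights, s), s
            )
            costs = [bcp_cost(pair, k, nominal_weights, s) for k in ks]
            k_grid = ks[int(np.argmin(costs))]
            assert abs(k_hat - k_grid) <= s.tolerance + 1e-4

    def test_non_finite_objective_names_offender(self):
        with pytest.raises(FloatingPointError, match="k="):
            golden_section_minimize(lambda k: np.nan, SearchSettings(0.0, 1.0))


class TestFitBCP:
    def test_noise_free_recovery(self, noise_free_pair, nominal_weights):
        truth, pair = noise_free_pair
        res = fit_bcp(pair, nominal_weights)
        assert res.k_hat == pytest.approx(truth.params.k, abs=1e-3)
        assert np.max(np.abs(res.f_hat / pair.f0 - truth.flow)) < 0.01
        assert res.bracket[1] - res.bracket[0] <= 1e-3

    def test_result_self_consistency(self, noisy_pair, nominal_weights):
        _, pair = noisy_pair
        res = fit_bcp(pair, nominal_weights)
        # every fitted point lies exactly on the curve at k_hat
        on_curve = curve_b(res.f_hat, res.k_hat, f0=pair.f0, b0=pair.b0)
        assert np.allclose(res.b_hat, on_curve, atol=1e-8)
        recomputed = float(
            nominal_weights.w_asl * np.sum((pair.asl - res.f_hat) ** 2)
            + nominal_weights.w_bold * np.sum((pair.bold - res.b_hat) ** 2)
        )
        assert res.cost == pytest.approx(recomputed, rel=1e-12)
        # global consistency: no grid k beats the fitted cost
        for k in np.linspace(-0.1, 0.3, 81):
            w = NoiseWeights(nominal_weights.var_asl, nominal_weights.var_bold)
            assert res.cost <= bcp_cost(pair, k, w) * (1 + 1e-9) + 1e-12

    def test_bold_dominant_limit(self, noisy_pair):
        # as the BOLD noise variance -> 0, b_hat -> measured BOLD and f_hat
        # solves the model inversion of each BOLD sample
        _, pair = noisy_pair
        w = NoiseWeights(var_asl=(0.36 * F0) ** 2, var_bold=1e-10)
        res = fit_bcp(pair, w)
        assert np.allclose(res.b_hat, pair.bold, atol=0.5)
        db = pair.bold / pair.b0 - 1.0
        u = db / res.k_hat
        expected_f = pair.f0 / (1.0 - u)
        ok = (u < 0.9) & (expected_f > 0.06 * F0) & (expected_f < 4.9 * F0)
        assert np.allclose(res.f_hat[ok], expected_f[ok], rtol=1e-3)

    def test_sixteen_sample_epoch_window_fits(self, noisy_pair, nominal_weights):
        _, pair = noisy_pair
        res = fit_bcp(pair.subset(np.arange(28, 44)), nominal_weights)
        assert np.isfinite(res.k_hat) and res.f_hat.size == 16

    def test_scale_equivariance(self, noisy_pair, nominal_weights):
        _, pair = noisy_pair
        res = fit_bcp(pair, nominal_weights)
        for c in (0.5, 3.0):
            scaled = TimeSeriesPair(
                pair.asl * c, pair.bold, pair.tr, f0=pair.f0 * c, b0=pair.b0
            )
            w = NoiseWeights(nominal_weights.var_asl * c**2, nominal_weights.var_bold)
            res_c = fit_bcp(scaled, w)
            assert res_c.k_hat == pytest.approx(res.k_hat, abs=1e-3)
            assert np.allclose(res_c.f_hat, c * res.f_hat, rtol=1e-4)

    def test_missing_baselines_rejected(self, nominal_weights):
        pair = TimeSeriesPair(np.ones(10) * F0, np.ones(10) * B0, 2.5)
        with pytest.raises(ValueError):
            fit_bcp(pair, nominal_weights)


class TestFitEpochs:
    def test_stationary_truth_recovered_in_all_epochs(
        self, paper_design, default_params, nominal_weights
    ):
        from bcperf import epoch_windows_from_design

        truth = simulate_truth(paper_design, default_params)
        pair = simulate_measured_pair(truth, noise=NoiseSpec(0.0, 0.0))
        epochs = epoch_windows_from_design(paper_design)
        results = fit_epochs(pair, epochs, nominal_weights)
        assert set(results) == set(epochs)
        for name, res in results.items():
            if name == "undershoot":
                # flow is back at baseline there: the curve families converge
                # at the origin, so k is only loosely constrained
                continue
            assert res.k_hat == pytest.approx(default_params.k, abs=2e-3)

    def test_two_regime_k_recovered(self, nominal_weights):
        # first half generated at k1, second half at k2, zero noise
        r = np.random.default_rng(7)
        flow = 1 + 0.46 * r.random(32)
        k1, k2 = 0.03, 0.09
        f = F0 * flow
        b = np.concatenate([curve_b(f[:16], k1), curve_b(f[16:], k2)])
        pair = TimeSeriesPair(f, b, 2.5, f0=F0, b0=B0)
        res = fit_epochs(
            pair, {"first": np.arange(16), "second": np.arange(16, 32)},
            nominal_weights,
        )
        assert res["first"].k_hat == pytest.approx(k1, abs=1e-3)
        assert res["second"].k_hat == pytest.approx(k2, abs=1e-3)

    def test_empty_epoch_rejected(self, noisy_pair, nominal_weights):
        _, pair = noisy_pair
        with pytest.raises(ValueError):
            fit_epochs(pair, {"empty": np.array([], dtype=int)}, nominal_weights)


class TestSklearnInterface:
    def _X(self):
        from bcperf import StimulusDesign

        truth = simulate_truth(StimulusDesign(), PhysioParams())
        pair = simulate_measured_pair(truth, noise=NoiseSpec(seed=3))
        return np.column_stack([pair.asl, pair.bold]), truth

    def test_fit_sets_trailing_underscore_attributes(self, nominal_weights):
        X, truth = self._X()
        est = BCPEstimator(
            f0=F0, b0=B0,
            var_asl=nominal_weights.var_asl, var_bold=nominal_weights.var_bold,
        ).fit(X)
        assert np.isfinite(est.k_hat_)
        assert est.f_hat_.shape == (X.shape[0],)
        assert est.bracket_[1] - est.bracket_[0] <= est.tol

    def test_get_params_set_params_clone(self):
        est = BCPEstimator(tol=1e-4, bracket=(-0.05, 0.2))
        params = est.get_params()
        assert params["tol"] == 1e-4
        est2 = clone(est)
        assert est2.get_params() == params
        est.set_params(tol=1e-3)
        assert est.tol == 1e-3

    def test_transform_requires_fit_and_projects(self, nominal_weights):
        X, _ = self._X()
        est = BCPEstimator(f0=F0, b0=B0,
                           var_asl=nominal_weights.var_asl,
                           var_bold=nominal_weights.var_bold)
        with pytest.raises(NotFittedError):
            est.transform(X)
        out = est.fit(X).transform(X)
        assert out.shape == X.shape
        assert np.allclose(out[:, 0], est.f_hat_)
        assert np.allclose(out[:, 1], curve_b(out[:, 0], est.k_hat_), atol=1e-8)

    def test_baselines_estimated_from_first_samples(self):
        X, _ = self._X()
        est = BCPEstimator(baseline_n=20).fit(X)
        assert est.f0_ == pytest.approx(X[:20, 0].mean())
        assert est.b0_ == pytest.approx(X[:20, 1].mean())

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            BCPEstimator().fit(np.ones((5, 3)))
        with pytest.raises(ValueError):
            BCPEstimator(var_asl=1.0).fit(np.ones((5, 2)))
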