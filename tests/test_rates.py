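import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cagefold.kinetics import SchemeRates, delta_g_from_rates, lambda_of_substrate
from cagefold.rates import (
    Chi2Surface,
    GridSpec,
    LambdaSeries,
    chi2_surface,
    classify_mechanism,
    fit_lambda_curve,
)
from cagefold.simulate import NoiseSpec, simulate_lambda_series, simulate_scheme_ode
from cagefold.progress import fit_progress_curve


class TestLambdaSeries:
    def test_duplicate_substrates_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            LambdaSeries(S=np.array([1e-5, 1e-5, 2e-5, 3e-5]), lam=np.full(4, 1e-3))

    def test_from_measurements_averages_duplicates(self):
        S = np.array([1e-5, 1e-5, 5e-5, 5e-5])
        lam = np.array([4e-3, 6e-3, 2e-3, 4e-3])
        series = LambdaSeries.from_measurements(S, lam)
        assert np.allclose(series.S, [1e-5, 5e-5])
        assert np.allclose(series.lam, [5e-3, 3e-3])
        assert series.lam_err is not None and np.all(series.lam_err > 0)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            LambdaSeries(S=np.array([1e-5, 2e-5, 3e-5, 4e-5]), lam=np.array([1e-3, 0.0, 1e-3, 1e-3]))


class TestFitLambdaCurve:
    def test_noiseless_round_trip(self, reference_rates, substrate_grid):
        series = LambdaSeries(S=substrate_grid, lam=lambda_of_substrate(substrate_grid, reference_rates))
        fit = fit_lambda_curve(series)
        assert fit.rates.k1 == pytest.approx(reference_rates.k1, rel=1e-6)
        assert fit.rates.k_minus1 == pytest.approx(reference_rates.k_minus1, rel=1e-6)
        assert fit.rates.Ka == pytest.approx(reference_rates.Ka, rel=1e-6)
        assert not fit.flags

    def test_median_recovery_under_noise(self, substrate_grid):
        # identifiable truth; see the acceptance suite for the rationale
        truth = SchemeRates(k1=1.4e-3, k_minus1=7.3e-3, Ka=3571.0)
        k1s, km1s = [], []
        for i in range(50):
            series, _ = simulate_lambda_series(
                truth, substrate_grid,
                NoiseSpec("gaussian", 0.05, seed=i, relative=True),
            )
            fit = fit_lambda_curve(series)
            k1s.append(fit.rates.k1)
            km1s.append(fit.rates.k_minus1)
        assert abs(np.median(k1s) / truth.k1 - 1) < 0.15
        assert abs(np.median(km1s) / truth.k_minus1 - 1) < 0.15

    def test_flat_series_flagged(self, substrate_grid):
        rng = np.random.default_rng(0)
        lam = 4e-3 * (1.0 + 1e-12 * rng.normal(size=8))
        series = LambdaSeries(S=substrate_grid, lam=lam)
        fit = fit_lambda_curve(series)
        assert fit.rates.k_minus1 < 1e-6
        assert "Ka_unidentifiable" in fit.flags

    def test_equivariance_under_concentration_rescaling(self, reference_rates, substrate_grid):
        lam = lambda_of_substrate(substrate_grid, reference_rates)
        base = fit_lambda_curve(LambdaSeries(S=substrate_grid, lam=lam))
        c = 50.0
        scaled = fit_lambda_curve(LambdaSeries(S=substrate_grid * c, lam=lam))
        assert scaled.rates.k1 == pytest.approx(base.rates.k1, rel=1e-6)
        assert scaled.rates.k_minus1 == pytest.approx(base.rates.k_minus1, rel=1e-6)
        assert scaled.rates.Ka == pytest.approx(base.rates.Ka / c, rel=1e-6)

    def test_fix_ka(self, reference_rates, substrate_grid):
        series = LambdaSeries(S=substrate_grid, lam=lambda_of_substrate(substrate_grid, reference_rates))
        fit = fit_lambda_curve(series, fix_Ka=3571.0)
        assert fit.rates.Ka == 3571.0
        assert fit.Ka_err == 0.0
        assert fit.rates.k1 == pytest.approx(reference_rates.k1, rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_lambda_curve(LambdaSeries(S=np.array([1e-5, 2e-5, 3e-5]), lam=np.full(3, 1e-3)))

    def test_delta_g_within_surface_interval(self, reference_rates, substrate_grid):
        series, _ = simulate_lambda_series(
            reference_rates, substrate_grid,
            NoiseSpec("gaussian", 0.03, seed=42, relative=True),
        )
        fit = fit_lambda_curve(series)
        dg = delta_g_from_rates(fit.rates)
        k1_lo, k1_hi = fit.confidence_intervals["k1"]
        km1_lo, km1_hi = fit.confidence_intervals["k_minus1"]
        consts_rt = 1.987e-3 * 296.15
        dg_lo = consts_rt * np.log(km1_lo / k1_hi)
        dg_hi = consts_rt * np.log(km1_hi / k1_lo)
        assert dg_lo <= dg.delta_g <= dg_hi


class TestChi2Surface:
    @pytest.fixture
    def noisy_fit(self, reference_rates, substrate_grid):
        series, _ = simulate_lambda_series(
            reference_rates, substrate_grid,
            NoiseSpec("gaussian", 0.05, seed=7, relative=True),
        )
        fit = fit_lambda_curve(series)
        return series, fit

    def test_minimum_matches_fit(self, noisy_fit):
        series, fit = noisy_fit
        surface = chi2_surface(series, fit)
        assert surface.values.min() == pytest.approx(fit.reduced_chi2, abs=1e-6)

    def test_axes_contain_estimates(self, noisy_fit):
        series, fit = noisy_fit
        surface = chi2_surface(series, fit)
        assert surface.k1_axis[0] <= fit.rates.k1 <= surface.k1_axis[-1]
        assert surface.k_minus1_axis[0] <= fit.rates.k_minus1 <= surface.k_minus1_axis[-1]

    def test_profiles_quasi_convex(self, noisy_fit):
        # away from the minimum the per-axis profile must not decrease
        series, fit = noisy_fit
        surface = chi2_surface(series, fit)
        for axis in (0, 1):
            profile = surface.values.min(axis=1 - axis)
            k = int(np.argmin(profile))
            assert np.all(np.diff(profile[k:]) >= -1e-9)
            assert np.all(np.diff(profile[:k + 1]) <= 1e-9)

    def test_nodes_match_brute_force_ka_profile(self, noisy_fit):
        series, fit = noisy_fit
        surface = chi2_surface(series, fit)
        w = series.weights()
        dof = surface.dof
        rng = np.random.default_rng(1)
        for _ in range(5):
            i = rng.integers(0, len(surface.k1_axis))
            j = rng.integers(0, len(surface.k_minus1_axis))
            k1 = surface.k1_axis[i]
            km1 = surface.k_minus1_axis[j]

            def chi2_of_log_ka(q):
                ka = np.exp(q)
                resid = series.lam - (k1 + km1 / (ka * series.S + 1.0))
                return float(np.sum(w * resid**2))

            best = minimize_scalar(
                chi2_of_log_ka,
                bounds=(np.log(fit.rates.Ka) - 7, np.log(fit.rates.Ka) + 7),
                method="bounded",
                options={"xatol": 1e-12},
            )
            assert surface.values[i, j] * dof == pytest.approx(best.fun, rel=1e-4, abs=1e-9)

    def test_marginal_intervals_contain_estimate(self, noisy_fit):
        series, fit = noisy_fit
        surface = chi2_surface(series, fit)
        lo, hi = surface.marginal_interval("k1")
        assert lo <= fit.rates.k1 <= hi
        lo, hi = surface.marginal_interval("k_minus1")
        assert lo <= fit.rates.k_minus1 <= hi

    def test_explicit_range_must_contain_minimum(self, noisy_fit):
        series, fit = noisy_fit
        bad = GridSpec(k1_range=(fit.rates.k1 * 5.0, fit.rates.k1 * 10.0))
        with pytest.raises(ValueError, match="does not contain"):
            chi2_surface(series, fit, bad)

    def test_export_columns(self, noisy_fit):
        series, fit = noisy_fit
        surface = chi2_surface(series, fit)
        cols = surface.to_arrays()
        n = len(surface.k1_axis) * len(surface.k_minus1_axis)
        assert all(len(v) == n for v in cols.values())


class TestTwoStagePipeline:
    def test_ode_to_rates_recovery(self, fast_binding_rates, substrate_grid):
        lams = []
        for S0 in substrate_grid:
            lam_true = lambda_of_substrate(S0, fast_binding_rates)
            t = np.linspace(0.0, 6.0 / lam_true, 400)
            curve, _ = simulate_scheme_ode(fast_binding_rates, 40e-9, float(S0), 350e-6, t)
            lams.append(fit_progress_curve(curve).lam)
        fit = fit_lambda_curve(LambdaSeries(S=substrate_grid, lam=np.array(lams)))
        assert fit.rates.k1 == pytest.approx(fast_binding_rates.k1, rel=0.10)
        assert fit.rates.k_minus1 == pytest.approx(fast_binding_rates.k_minus1, rel=0.10)


class TestClassifyMechanism:
    def test_conformational_selection(self, reference_rates, substrate_grid):
        series, _ = simulate_lambda_series(
            reference_rates, substrate_grid,
            NoiseSpec("gaussian", 0.05, seed=0, relative=True),
        )
        assert classify_mechanism(series) == "conformational_selection"

    def test_induced_fit(self, substrate_grid):
        rng = np.random.default_rng(1)
        clean = 1e-3 + 6e-3 * substrate_grid / (substrate_grid + 1e-4)
        sd = 0.05 * clean
        series = LambdaSeries(S=substrate_grid, lam=clean + rng.normal(0, 1, 8) * sd, lam_err=sd)
        assert classify_mechanism(series) == "induced_fit_or_penetration"

    def test_flat_null_mostly_indeterminate(self, substrate_grid):
        n_ind = 0
        for i in range(50):
            rng = np.random.default_rng(i)
            sd = np.full(8, 2e-4)
            lam = 4e-3 + rng.normal(0, 1, 8) * sd
            series = LambdaSeries(S=substrate_grid, lam=lam, lam_err=sd)
            n_ind += classify_mechanism(series) == "indeterminate"
        assert n_ind >= 45

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            classify_mechanism(LambdaSeries(S=np.array([1e-5, 2e-5, 3e-5]), lam=np.full(3, 1e-3)))
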