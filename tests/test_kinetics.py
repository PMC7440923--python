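import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cagefold.kinetics import (
    PhysicalConstants,
    SchemeRates,
    StabilityResult,
    delta_g_from_rates,
    delta_g_ligand_shift,
    destabilization,
    lag_progress_model,
    lambda_of_substrate,
)

CONSTS = PhysicalConstants()


class TestTypes:
    def test_constants_defaults(self):
        assert CONSTS.R == pytest.approx(1.987e-3)
        assert CONSTS.T == pytest.approx(296.15)

    @pytest.mark.parametrize("kwargs", [{"T": 0.0}, {"T": -5.0}, {"R": 0.0}])
    def test_constants_rejects_nonpositive(self, kwargs):
        with pytest.raises(ValueError):
            PhysicalConstants(**kwargs)

    def test_ka_derived_from_k2(self):
        r = SchemeRates(k1=1e-3, k_minus1=1e-2, k2=5e4, k_minus2=10.0)
        assert r.Ka == pytest.approx(5e3, rel=1e-12)

    def test_ka_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SchemeRates(k1=1e-3, k_minus1=1e-2, k2=5e4, k_minus2=10.0, Ka=4000.0)

    def test_ka_consistent_value_accepted(self):
        SchemeRates(k1=1e-3, k_minus1=1e-2, k2=5e4, k_minus2=10.0, Ka=5e3)

    @pytest.mark.parametrize("field", ["k1", "k_minus1", "kcat"])
    def test_negative_rates_rejected(self, field):
        kwargs = {"k1": 1e-3, "k_minus1": 1e-2, field: -1.0}
        with pytest.raises(ValueError):
            SchemeRates(**kwargs)

    def test_stability_result_validation(self):
        with pytest.raises(ValueError):
            StabilityResult(float("nan"), 296.15, "rates")
        with pytest.raises(ValueError):
            StabilityResult(1.0, 296.15, "guesswork")
        with pytest.raises(ValueError):
            StabilityResult(1.0, 296.15, "rates", uncertainty=-0.1)


class TestLagModel:
    def test_passes_through_origin(self):
        assert lag_progress_model(0.0, 3.0, -2.0, 0.5) == 0.0

    def test_linear_asymptote(self):
        # exp(-lam*t) vanishes: value -> V*t - A
        V, A, lam = 2e-4, 0.05, 4e-3
        t = 5e4
        assert lag_progress_model(t, V, A, lam) == pytest.approx(V * t - A, rel=1e-12)

    def test_direct_evaluation(self):
        # frozen from V*t + A*(exp(-lam*t)-1) at t=1000, V=2e-4, A=0.05, lam=4e-3
        assert lag_progress_model(1000.0, 2e-4, 0.05, 4e-3) == pytest.approx(
            0.15091578194443672, abs=1e-12
        )

    def test_rejects_negative_time_and_rate(self):
        with pytest.raises(ValueError):
            lag_progress_model(-1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            lag_progress_model(1.0, 1.0, 1.0, -1e-3)

    def test_vectorized(self):
        t = np.linspace(0, 100, 7)
        out = lag_progress_model(t, 1e-3, 0.1, 0.05)
        assert out.shape == t.shape
        assert out[0] == 0.0

    def test_independent_arithmetic_path(self):
        # same quantity via math.exp instead of np.expm1
        t, V, A, lam = 317.0, 3.3e-4, 0.021, 2.7e-3
        alt = V * t + A * (math.exp(-lam * t) - 1.0)
        assert lag_progress_model(t, V, A, lam) == pytest.approx(alt, rel=1e-12)


class TestLambdaOfSubstrate:
    def test_zero_substrate_limit(self, reference_rates):
        assert lambda_of_substrate(0.0, reference_rates) == pytest.approx(
            reference_rates.k1 + reference_rates.k_minus1, rel=1e-15
        )

    def test_saturation_limit(self, reference_rates):
        assert lambda_of_substrate(1e6, reference_rates) == pytest.approx(
            reference_rates.k1, rel=1e-6
        )

    def test_direct_evaluation(self, reference_rates):
        # 1.4e-4 + 7.3e-3 / (3571 * 250e-6 + 1)
        expected = 1.4e-4 + 7.3e-3 / 1.89275
        assert lambda_of_substrate(250e-6, reference_rates) == pytest.approx(
            expected, rel=1e-6
        )

    def test_strictly_decreasing(self, reference_rates):
        S = np.geomspace(1e-7, 1e-2, 200)
        lam = lambda_of_substrate(S, reference_rates)
        assert np.all(np.diff(lam) < 0)

    def test_rejects_negative_substrate(self, reference_rates):
        with pytest.raises(ValueError):
            lambda_of_substrate(-1e-6, reference_rates)

    def test_requires_ka(self):
        with pytest.raises(ValueError):
            lambda_of_substrate(1e-5, SchemeRates(k1=1e-3, k_minus1=1e-2))

    def test_independent_arithmetic_path(self, reference_rates):
        # k_minus2/(k2*S + k_minus2) route must agree to 1e-12
        km2 = 37.0
        r = SchemeRates(
            k1=reference_rates.k1, k_minus1=reference_rates.k_minus1,
            k2=reference_rates.Ka * km2, k_minus2=km2,
        )
        for S in (0.0, 3e-6, 2.5e-4, 8e-3):
            alt = r.k1 + r.k_minus1 * km2 / (r.k2 * S + km2)
            assert lambda_of_substrate(S, r) == pytest.approx(alt, rel=1e-12)


class TestDeltaGFromRates:
    def test_reference_rates_value(self, reference_rates):
        # printed reference: 2.4 +/- 0.2 kcal/mol at 23 degC
        res = delta_g_from_rates(reference_rates)
        assert 2.2 <= res.delta_g <= 2.6
        assert res.delta_g == pytest.approx(2.3267, abs=1e-3)

    def test_equal_rates_give_zero(self):
        res = delta_g_from_rates(SchemeRates(k1=5e-3, k_minus1=5e-3))
        assert res.delta_g == 0.0

    def test_antisymmetry(self):
        a = delta_g_from_rates(SchemeRates(k1=2e-4, k_minus1=9e-3))
        b = delta_g_from_rates(SchemeRates(k1=9e-3, k_minus1=2e-4))
        assert a.delta_g == pytest.approx(-b.delta_g, rel=1e-14)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            delta_g_from_rates(SchemeRates(k1=0.0, k_minus1=1e-3))

    def test_delta_propagation(self, reference_rates):
        r = reference_rates.with_errors(0.4e-4, 0.8e-3)
        res = delta_g_from_rates(r)
        expected = CONSTS.RT * math.hypot(0.4 / 1.4, 0.8 / 7.3)
        assert res.uncertainty == pytest.approx(expected, rel=1e-12)
        assert res.uncertainty == pytest.approx(0.18, abs=0.01)

    def test_mc_propagation_matches_delta(self, reference_rates):
        r = reference_rates.with_errors(0.4e-4, 0.8e-3)
        delta = delta_g_from_rates(r, method="delta")
        mc = delta_g_from_rates(r, method="mc", seed=11)
        assert mc.uncertainty == pytest.approx(delta.uncertainty, rel=0.15)

    @given(
        dg=st.floats(-8.0, 8.0),
        k1=st.floats(1e-6, 1e2),
    )
    def test_round_trip(self, dg, k1):
        # rates constructed so k_minus1/k1 = exp(dg/RT) recover dg exactly
        k_minus1 = k1 * math.exp(dg / CONSTS.RT)
        res = delta_g_from_rates(SchemeRates(k1=k1, k_minus1=k_minus1))
        assert res.delta_g == pytest.approx(dg, abs=1e-9)


class TestLigandShift:
    def test_zero_ligand_no_shift(self):
        assert delta_g_ligand_shift(-3.45, 0.0, 13e-6) == -3.45

    def test_half_saturation_closed_form(self):
        shift = delta_g_ligand_shift(0.0, 13e-6, 13e-6)
        assert shift == pytest.approx(-CONSTS.RT * math.log(2.0), rel=1e-12)
        assert shift == pytest.approx(-0.408, abs=1e-3)

    def test_direct_evaluation(self):
        # -3.45 - RT*ln(1 + 500/13)
        out = delta_g_ligand_shift(-3.45, 500e-6, 13e-6)
        assert out == pytest.approx(-5.6127, abs=1e-3)

    def test_km_validation(self):
        with pytest.raises(ValueError):
            delta_g_ligand_shift(-3.45, 1e-5, 0.0)
        with pytest.raises(ValueError):
            delta_g_ligand_shift(-3.45, -1e-6, 13e-6)

    def test_monotone_decreasing(self):
        S = np.linspace(0, 1e-3, 50)
        out = delta_g_ligand_shift(-3.45, S, 13e-6)
        assert np.all(np.diff(out) < 0)

    @given(st.floats(0.0, 1e-2), st.floats(-6.0, 6.0))
    def test_linkage_identity(self, S, dg0):
        # shift + RT*ln(1+S/Km) is constant in S
        Km = 13e-6
        shifted = delta_g_ligand_shift(dg0, S, Km)
        assert shifted + CONSTS.RT * math.log1p(S / Km) == pytest.approx(dg0, abs=1e-9)


class TestDestabilization:
    def _cage(self, dg=2.4, unc=0.2, T=296.15):
        return StabilityResult(dg, T, "rates", unc)

    def _bulk(self, dg=-3.45, unc=0.09, T=296.15):
        return StabilityResult(dg, T, "extrapolation", unc)

    def test_reference_values(self):
        res = destabilization(self._cage(), self._bulk())
        assert res.delta_g == pytest.approx(5.85, abs=1e-12)
        assert res.delta_g > 5.0

    def test_identical_inputs_zero(self):
        res = destabilization(self._cage(), StabilityResult(2.4, 296.15, "rates", 0.2))
        assert res.delta_g == 0.0

    def test_composition_with_rate_derived_cage(self, reference_rates):
        cage = delta_g_from_rates(reference_rates)
        res = destabilization(cage, self._bulk())
        assert res.delta_g == pytest.approx(5.78, abs=0.01)

    def test_uncertainty_quadrature(self):
        res = destabilization(self._cage(unc=0.3), self._bulk(unc=0.4))
        assert res.uncertainty == pytest.approx(0.5, rel=1e-12)

    def test_temperature_mismatch(self):
        with pytest.raises(ValueError, match="temperature mismatch"):
            destabilization(self._cage(T=298.15), self._bulk())
        res = destabilization(self._cage(T=298.15), self._bulk(), allow_temperature_mismatch=True)
        assert res.delta_g == pytest.approx(5.85)
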