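"""Process analytics: rates, yields, off-gas balances and conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melferm import analytics
from melferm.analytics import OffGasRecord, RateEstimate


def _exp_growth(mu=0.11, x0=0.5, t_end=20.0, n=21):
    t = np.linspace(0.0, t_end, n)
    return t, x0 * np.exp(mu * t)


class TestSpecificGrowthRate:
    def test_regression_exact_on_exponential_series(self):
        t, cx = _exp_growth()
        est = analytics.specific_growth_rate_obs(t, cx, (0.0, 20.0))
        assert est.value == pytest.approx(0.11, rel=1e-10)
        assert est.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_two_point_matches_regression_on_exact_data(self):
        t, cx = _exp_growth()
        two = analytics.specific_growth_rate_obs(t, cx, (0.0, 20.0), method="two-point")
        assert two.value == pytest.approx(0.11, rel=1e-10)
        assert two.method == "two-point"

    def test_window_selects_samples(self):
        t, cx = _exp_growth()
        est = analytics.specific_growth_rate_obs(t, cx, (5.0, 15.0))
        assert est.window == (5.0, 15.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            analytics.specific_growth_rate_obs([0.0, 10.0], [1.0, 2.0], (3.0, 4.0))


class TestConsumptionRateAndYield:
    def _coupled_series(self, mu=0.11, Y=0.17, x0=0.5, s0=30.0):
        t, cx = _exp_growth(mu=mu, x0=x0)
        cs = s0 - (cx - x0) / Y
        return t, cs, cx

    def test_yield_recovered_exactly(self):
        t, cs, cx = self._coupled_series()
        est = analytics.consumption_rate_and_yield(t, cs, t, cx, (0.0, 20.0))
        assert est["Y_X_S"].value == pytest.approx(0.17, rel=1e-10)

    def test_specific_rate_times_yield_equals_growth_rate(self):
        """With the logarithmic-mean biomass, q_S * Y_X/S = mu holds exactly
        on noiseless exponential windows."""
        t, cs, cx = self._coupled_series()
        est = analytics.consumption_rate_and_yield(t, cs, t, cx, (0.0, 20.0),
                                                   method="two-point")
        assert est["q_S"].value * est["Y_X_S"].value == pytest.approx(0.11, rel=1e-10)

    def test_consumption_reported_positive(self):
        t, cs, cx = self._coupled_series()
        est = analytics.consumption_rate_and_yield(t, cs, t, cx, (0.0, 20.0))
        assert est["r_S"].value > 0
        assert est["q_S"].value > 0

    def test_flat_substrate_rejected(self):
        t = np.linspace(0, 10, 6)
        with pytest.raises(ValueError):
            analytics.consumption_rate_and_yield(t, np.full(6, 5.0), t,
                                                 np.linspace(1, 2, 6), (0.0, 10.0))


class TestOffGas:
    RECORD = dict(t=24.0, Q_air=168.0, p_air=101325.0, T=303.15, V_L=4.0)

    def test_no_conversion_means_zero_rates(self):
        our, cer, rq = analytics.our_cer_rq(OffGasRecord(**self.RECORD))
        assert our == pytest.approx(0.0, abs=1e-12)
        assert cer == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(rq)

    def test_oxygen_depletion_gives_positive_our(self):
        rec = OffGasRecord(**self.RECORD, y_O2_out=0.195, y_CO2_out=0.012)
        our, cer, rq = analytics.our_cer_rq(rec)
        assert our > 0
        assert cer > 0
        assert rq == pytest.approx(cer / our, rel=1e-12)

    def test_round_trip_with_inversion(self):
        y_o2, y_co2 = analytics.outlet_fractions_from_rates(
            25.0, 13.0, 168.0, 101325.0, 303.15, 4.0)
        rec = OffGasRecord(**self.RECORD, y_O2_out=y_o2, y_CO2_out=y_co2)
        our, cer, rq = analytics.our_cer_rq(rec)
        assert our == pytest.approx(25.0, rel=1e-9)
        assert cer == pytest.approx(13.0, rel=1e-9)
        assert rq == pytest.approx(0.52, rel=1e-9)

    def test_impossible_uptake_rejected(self):
        with pytest.raises(ValueError):
            analytics.outlet_fractions_from_rates(
                1e5, 10.0, 168.0, 101325.0, 303.15, 4.0)

    @settings(derandomize=True, max_examples=100)
    @given(extra_inert=st.floats(0.0, 5.0))
    def test_inert_flow_scaling_preserves_rates(self, extra_inert):
        """Padding the airflow with proportionally more gas at unchanged
        outlet composition scales OUR/CER by the same factor, leaving RQ
        unchanged — the inert balance is linear in the gas flow."""
        rec = OffGasRecord(**self.RECORD, y_O2_out=0.20, y_CO2_out=0.008)
        scaled = OffGasRecord(**{**self.RECORD,
                                 "Q_air": self.RECORD["Q_air"] * (1 + extra_inert)},
                              y_O2_out=0.20, y_CO2_out=0.008)
        our1, cer1, rq1 = analytics.our_cer_rq(rec)
        our2, cer2, rq2 = analytics.our_cer_rq(scaled)
        assert our2 == pytest.approx(our1 * (1 + extra_inert), rel=1e-9)
        assert cer2 == pytest.approx(cer1 * (1 + extra_inert), rel=1e-9)
        assert rq2 == pytest.approx(rq1, rel=1e-9)


class TestSpecificOxygenUptake:
    def test_constant_specific_uptake_recovered(self):
        t, cx = _exp_growth(n=41)
        our = 4.3 * cx
        est = analytics.specific_o2_and_yield(t, our, t, cx, (0.0, 20.0))
        assert est["q_O2"].value == pytest.approx(4.3, rel=1e-10)

    def test_biomass_yield_from_oxygen(self):
        t = np.linspace(0.0, 10.0, 101)
        our = np.full_like(t, 10.0)           # mmol/L/h
        cx = 1.0 + 0.256 * 10.0 * t           # g/L, Y = 0.0256 g/mmol... scaled
        est = analytics.specific_o2_and_yield(t, our, t, cx, (0.0, 10.0))
        assert est["Y_X_O2"].value == pytest.approx(0.256, rel=1e-9)


class TestOilMelAnalytics:
    def test_rates_and_yields_on_linear_series(self):
        t = np.linspace(50.0, 150.0, 11)
        c_oil = 50.0 - 0.3 * (t - 50.0)
        c_mel = 2.0 + 0.12 * (t - 50.0)
        est = analytics.oil_mel_rates_and_yield(
            t, c_oil, t, c_mel, c_x_growth=5.3, window=(50.0, 150.0),
            total_oil_added=80.0)
        assert est["r_oil"].value == pytest.approx(0.3, rel=1e-10)
        assert est["r_MEL"].value == pytest.approx(0.12, rel=1e-10)
        assert est["q_MEL"].value == pytest.approx(0.12 / 5.3, rel=1e-10)
        assert est["Y_MEL_oil"].value == pytest.approx(0.4, rel=1e-10)
        assert est["Y_MEL_total_oil"].value == pytest.approx(14.0 / 80.0, rel=1e-10)

    def test_requires_positive_catalytic_biomass(self):
        t = np.linspace(0.0, 10.0, 5)
        with pytest.raises(ValueError):
            analytics.oil_mel_rates_and_yield(t, t, t, t, 0.0, (0.0, 10.0))


class TestExtractPurity:
    def test_simple_ratio(self):
        assert analytics.x_mel(11.2, 0.0, 2.7) == pytest.approx(11.2 / 13.9, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(c_mel=st.floats(0.01, 100.0), c_oil=st.floats(0.0, 100.0),
           c_fa=st.floats(0.0, 100.0), scale=st.floats(0.01, 100.0))
    def test_scale_invariance_and_bounds(self, c_mel, c_oil, c_fa, scale):
        x = analytics.x_mel(c_mel, c_oil, c_fa)
        assert 0.0 < x <= 1.0
        assert analytics.x_mel(scale * c_mel, scale * c_oil, scale * c_fa) == \
            pytest.approx(x, rel=1e-9)

    def test_empty_extract_rejected(self):
        with pytest.raises(ValueError):
            analytics.x_mel(0.0, 0.0, 0.0)


class TestConversions:
    def test_od_to_biomass(self):
        assert analytics.od_to_biomass(10.0) == pytest.approx(3.5, rel=1e-12)

    def test_backscatter_chain(self):
        # 0.14 backscatter units correspond to OD 1, i.e. 0.35 g/L
        assert analytics.backscatter_to_biomass(0.14) == pytest.approx(0.35, rel=1e-9)

    def test_feed_substrate_mass_unit_density(self):
        assert analytics.feed_substrate_mass(460.0, 300.0) == pytest.approx(138.0)

    def test_feed_substrate_mass_with_density(self):
        assert analytics.feed_substrate_mass(460.0, 300.0, 1.15) == pytest.approx(120.0)

    def test_rate_estimate_window_validation(self):
        with pytest.raises(ValueError):
            RateEstimate((10.0, 10.0), 1.0)
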