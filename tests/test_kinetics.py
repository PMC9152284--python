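"""Rate laws: worked values, limiting behaviour and flux bookkeeping."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melferm import kinetics
from melferm.params import (
    ExponentialFeedSpec,
    GrowthParameters,
    GrowthState,
    ProductionParameters,
    ProductionState,
)

POSITIVE = st.floats(min_value=0.0, max_value=200.0, allow_nan=False)


def _gstate(c_gluc, c_nano3, c_x=1.0, V=4.0):
    return GrowthState(t=0.0, V_L=V, c_x=c_x, c_gluc=c_gluc, c_nano3=c_nano3)


class TestSpecificGrowthRate:
    def test_glucose_limited_value(self, growth_params):
        # nitrate term 1/1.01 > glucose term 10/11, so glucose limits
        mu = kinetics.specific_growth_rate(_gstate(10.0, 1.0), growth_params)
        assert mu == pytest.approx(0.11 * 10.0 / 11.0, rel=1e-12)

    def test_nitrate_limited_value(self, growth_params):
        mu = kinetics.specific_growth_rate(_gstate(50.0, 0.01), growth_params)
        assert mu == pytest.approx(0.11 * 0.5, rel=1e-2)

    def test_zero_substrate_stops_growth(self, growth_params):
        assert kinetics.specific_growth_rate(_gstate(0.0, 3.0), growth_params) == 0.0
        assert kinetics.specific_growth_rate(_gstate(30.0, 0.0), growth_params) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(c_gluc=POSITIVE, c_nano3=POSITIVE)
    def test_rate_bounded_by_mu_max(self, c_gluc, c_nano3):
        p = GrowthParameters()
        mu = kinetics.specific_growth_rate(_gstate(c_gluc, c_nano3), p)
        assert 0.0 <= mu <= p.mu_max

    @settings(derandomize=True, max_examples=50)
    @given(c_gluc=st.floats(0.1, 100.0), c_nano3=st.floats(0.1, 100.0))
    def test_minimum_operator_picks_the_scarcer_substrate(self, c_gluc, c_nano3):
        p = GrowthParameters()
        mu = kinetics.specific_growth_rate(_gstate(c_gluc, c_nano3), p)
        only_gluc = p.mu_max * c_gluc / (p.K_gluc + c_gluc)
        only_nano3 = p.mu_max * c_nano3 / (p.K_nano3 + c_nano3)
        assert mu == pytest.approx(min(only_gluc, only_nano3), rel=1e-12)


class TestGrowthRhs:
    def test_batch_mass_balance(self, growth_params):
        state = _gstate(30.0, 3.0, c_x=2.0)
        mu = kinetics.specific_growth_rate(state, growth_params)
        dV, dx, dgluc, dnano3 = kinetics.growth_rhs(state, 0.0, None, growth_params)
        assert dV == 0.0
        assert dx == pytest.approx(mu * 2.0, rel=1e-12)
        assert dgluc == pytest.approx(-mu / 0.17 * 2.0, rel=1e-12)
        assert dnano3 == pytest.approx(-mu / 1.7 * 2.0, rel=1e-12)

    def test_feeding_adds_substrate_and_dilutes(self, growth_params):
        feed = ExponentialFeedSpec(t_start=0.0, t_end=10.0, mu_set=0.08,
                                   V0=3.0, cx0=7.6)
        state = _gstate(1.0, 0.5, c_x=8.0, V=3.0)
        F = 0.03
        dV, dx, dgluc, dnano3 = kinetics.growth_rhs(state, F, feed, growth_params)
        D = F / 3.0
        mu = kinetics.specific_growth_rate(state, growth_params)
        assert dV == F
        assert dx == pytest.approx((mu - D) * 8.0, rel=1e-12)
        assert dgluc == pytest.approx(D * (300.0 - 1.0) - mu / 0.17 * 8.0, rel=1e-12)
        assert dnano3 == pytest.approx(D * (30.0 - 0.5) - mu / 1.7 * 8.0, rel=1e-12)

    def test_negative_feed_rejected(self, growth_params):
        with pytest.raises(ValueError):
            kinetics.growth_rhs(_gstate(1.0, 1.0), -0.1, None, growth_params)


class TestExponentialFeedRate:
    FEED = ExponentialFeedSpec(t_start=44.5, t_end=55.0, mu_set=0.08,
                               V0=3.0, cx0=7.6)

    def test_initial_rate_worked_value(self):
        # F0 = V0*cx0*mu_set / (Y * c_feed) = 3*7.6*0.08 / (0.25*300)
        F0 = kinetics.exponential_feed_rate(44.5, self.FEED)
        assert F0 == pytest.approx(0.02432, abs=1e-6)

    def test_exponential_shape(self):
        F0 = kinetics.exponential_feed_rate(44.5, self.FEED)
        F5 = kinetics.exponential_feed_rate(49.5, self.FEED)
        assert F5 / F0 == pytest.approx(math.exp(0.08 * 5.0), rel=1e-12)

    def test_zero_outside_window(self):
        assert kinetics.exponential_feed_rate(44.0, self.FEED) == 0.0
        assert kinetics.exponential_feed_rate(55.5, self.FEED) == 0.0

    def test_rescaled_profile_integrates_to_delivered_volume(self):
        feed = ExponentialFeedSpec(t_start=44.5, t_end=55.0, mu_set=0.08,
                                   V0=3.0, cx0=7.6, delivered_volume_L=0.46)
        # analytic integral of F0*exp(mu (t - t0)) over the window
        F0 = kinetics.exponential_feed_rate(44.5, feed)
        total = F0 / 0.08 * (math.exp(0.08 * 10.5) - 1.0)
        assert total == pytest.approx(0.46, rel=1e-12)

    def test_broth_glucose_override_raises_rate(self):
        base = kinetics.exponential_feed_rate(50.0, self.FEED)
        higher = kinetics.exponential_feed_rate(50.0, self.FEED, c_gluc=50.0)
        assert higher > base

    def test_diverging_feed_law_rejected(self):
        with pytest.raises(ValueError):
            kinetics.exponential_feed_rate(50.0, self.FEED, c_gluc=300.0)


class TestProductionRates:
    def test_hydrolysis_half_saturation(self, production_params):
        q = kinetics.hydrolysis_rate(5.0, 0.0, production_params)
        assert q == pytest.approx(0.05, rel=1e-12)

    def test_hydrolysis_product_inhibition_doubles_apparent_km(self, production_params):
        # at c_fa = K_i the apparent half-saturation doubles
        q = kinetics.hydrolysis_rate(10.0, 20.0, production_params)
        assert q == pytest.approx(0.1 * 10.0 / (10.0 + 5.0 * 2.0), rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(c_oil=POSITIVE, fa_lo=st.floats(0.0, 100.0), fa_extra=st.floats(0.01, 100.0))
    def test_hydrolysis_monotone_decreasing_in_fatty_acids(self, c_oil, fa_lo, fa_extra):
        p = ProductionParameters()
        q_lo = kinetics.hydrolysis_rate(c_oil, fa_lo, p)
        q_hi = kinetics.hydrolysis_rate(c_oil, fa_lo + fa_extra, p)
        assert q_hi <= q_lo
        assert 0.0 <= q_hi <= p.q_max_hyd

    def test_mel_rate_half_saturation(self, production_params):
        assert kinetics.mel_rate(5.0, production_params) == pytest.approx(0.01, rel=1e-12)

    def test_inclusion_rate_half_saturation(self, production_params):
        assert kinetics.inclusion_rate(1.0, production_params) == pytest.approx(
            0.035, rel=1e-12)

    def test_negative_concentrations_rejected(self, production_params):
        with pytest.raises(ValueError):
            kinetics.hydrolysis_rate(-1.0, 0.0, production_params)
        with pytest.raises(ValueError):
            kinetics.mel_rate(-1.0, production_params)


def _pstate(c_oil=20.0, c_fa=5.0, c_mel=2.0, c_x_free=4.0, c_x_incl=1.0,
            c_x_growth=5.3, V=4.0):
    return ProductionState(t=60.0, V_L=V, c_x_free=c_x_free, c_x_incl=c_x_incl,
                           c_oil=c_oil, c_fa=c_fa, c_mel=c_mel,
                           c_x_growth=c_x_growth)


class TestProductionRhs:
    def test_fatty_acid_terms(self, production_params):
        p = production_params
        s = _pstate()
        dV, dxf, dxi, doil, dfa, dmel = kinetics.production_rhs(s, 0.0, 0.0, p)
        q_hyd = kinetics.hydrolysis_rate(s.c_oil, s.c_fa, p)
        q_mel = kinetics.mel_rate(s.c_fa, p)
        q_incl = kinetics.inclusion_rate(s.c_fa, p)
        cx = s.c_x_growth
        assert doil == pytest.approx(-q_hyd * cx, rel=1e-12)
        assert dmel == pytest.approx(q_mel * cx, rel=1e-12)
        assert dfa == pytest.approx(
            p.Y_fa_oil * q_hyd * cx - p.Y_fa_mel * q_mel * cx
            - p.Y_fa_incl * q_incl * s.c_x_free, rel=1e-12)
        assert dxi == pytest.approx(q_incl * s.c_x_free, rel=1e-12)
        assert dxf == pytest.approx(-p.Y_x_free_incl * q_incl * s.c_x_free, rel=1e-12)

    def test_inclusion_drain_matches_inclusion_biomass_flux(self, production_params):
        """The FA drained into inclusions is exactly Y_fa_incl per unit of
        inclusion biomass formed, so inclusion bookkeeping closes."""
        p = production_params
        s = _pstate()
        _, _, dxi, _, dfa, _ = kinetics.production_rhs(s, 0.0, 0.0, p)
        q_hyd = kinetics.hydrolysis_rate(s.c_oil, s.c_fa, p)
        q_mel = kinetics.mel_rate(s.c_fa, p)
        drain = (p.Y_fa_oil * q_hyd - p.Y_fa_mel * q_mel) * s.c_x_growth - dfa
        assert drain == pytest.approx(p.Y_fa_incl * dxi, rel=1e-12)

    def test_catalytic_biomass_drain_variant(self, production_params):
        p = production_params
        s = _pstate()
        _, _, _, _, dfa, _ = kinetics.production_rhs(
            s, 0.0, 0.0, p, inclusion_by_free_biomass=False)
        q_hyd = kinetics.hydrolysis_rate(s.c_oil, s.c_fa, p)
        q_mel = kinetics.mel_rate(s.c_fa, p)
        q_incl = kinetics.inclusion_rate(s.c_fa, p)
        cx = s.c_x_growth
        assert dfa == pytest.approx(
            p.Y_fa_oil * q_hyd * cx - p.Y_fa_mel * q_mel * cx
            - p.Y_fa_incl * q_incl * cx, rel=1e-12)

    def test_total_biomass_scaling_variant(self, production_params):
        s = _pstate()
        _, _, _, doil_g, _, _ = kinetics.production_rhs(s, 0.0, 0.0, production_params)
        _, _, _, doil_t, _, _ = kinetics.production_rhs(
            s, 0.0, 0.0, production_params, scale_by_total_biomass=True)
        q_hyd = kinetics.hydrolysis_rate(s.c_oil, s.c_fa, production_params)
        assert doil_g == pytest.approx(-q_hyd * s.c_x_growth, rel=1e-12)
        assert doil_t == pytest.approx(-q_hyd * s.c_x_total, rel=1e-12)

    def test_continuous_oil_feed_dilution_terms(self, production_params):
        s = _pstate()
        F, c_feed = 0.008, 920.0
        D = F / s.V_L
        dV, dxf, dxi, doil, dfa, dmel = kinetics.production_rhs(
            s, F, c_feed, production_params)
        dV0, dxf0, dxi0, doil0, dfa0, dmel0 = kinetics.production_rhs(
            s, 0.0, 0.0, production_params)
        assert dV == F
        assert doil - doil0 == pytest.approx(D * (c_feed - s.c_oil), rel=1e-12)
        assert dfa - dfa0 == pytest.approx(-D * s.c_fa, rel=1e-12)
        assert dmel - dmel0 == pytest.approx(-D * s.c_mel, rel=1e-12)
        assert dxf - dxf0 == pytest.approx(-D * s.c_x_free, rel=1e-12)
        assert dxi - dxi0 == pytest.approx(-D * s.c_x_incl, rel=1e-12)
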