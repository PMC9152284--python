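"""Shared fixtures and the high-order reference integrator.

The reference integrator solves the same right-hand sides with an adaptive
solver (scipy's LSODA) piecewise between feed discontinuities and applies
bolus mixing at the exact event times; it exists to check the explicit
Euler trajectories, never to produce them.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from melferm import kinetics
from melferm.params import GrowthParameters, GrowthState, ProductionParameters, ProductionState
from melferm.simulate import ProcessConfig
from melferm.synthetic import generate_scenarios


@pytest.fixture(scope="session")
def growth_params() -> GrowthParameters:
    return GrowthParameters()


@pytest.fixture(scope="session")
def production_params() -> ProductionParameters:
    return ProductionParameters()


@pytest.fixture(scope="session")
def scenarios() -> dict[str, ProcessConfig]:
    return generate_scenarios()


def _segment_times(t0, t1, breakpoints):
    pts = sorted({t0, t1, *(b for b in breakpoints if t0 < b < t1)})
    return list(zip(pts[:-1], pts[1:]))


def reference_growth_endpoint(config: ProcessConfig, rtol=1e-9, atol=1e-11):
    """Adaptive-solver endpoint (V, c_x, c_gluc, c_nano3) of the growth phase."""
    s0 = config.initial
    p = config.growth
    feed = config.feed
    breaks = [feed.t_start, feed.t_end] if feed is not None else []

    def rhs(t, y):
        state = GrowthState(t=t, V_L=y[0], c_x=max(y[1], 0.0),
                            c_gluc=max(y[2], 0.0), c_nano3=max(y[3], 0.0))
        F = kinetics.exponential_feed_rate(t, feed) if feed is not None else 0.0
        return kinetics.growth_rhs(state, F, feed, p)

    y = np.array([s0.V_L, s0.c_x, s0.c_gluc, s0.c_nano3])
    for a, b in _segment_times(s0.t, config.t_growth_end, breaks):
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol)
        assert sol.success, sol.message
        y = np.maximum(sol.y[:, -1], 0.0)
    return y


def reference_production_endpoint(config: ProcessConfig, handover,
                                  rtol=1e-9, atol=1e-11):
    """Adaptive-solver endpoint (V, x_free, x_incl, oil, fa, mel) of production."""
    p = config.production
    events = config.oil_feeds
    breaks = []
    for ev in events:
        breaks.append(ev.t_start)
        if ev.kind == "continuous":
            breaks.append(ev.t_end)

    def rhs(t, y):
        state = ProductionState(
            t=t, V_L=y[0], c_x_free=max(y[1], 0.0), c_x_incl=max(y[2], 0.0),
            c_oil=max(y[3], 0.0), c_fa=max(y[4], 0.0), c_mel=max(y[5], 0.0),
            c_x_growth=handover.c_x)
        F = 0.0
        c_feed = 0.0
        for ev in events:
            if ev.kind == "continuous" and ev.t_start <= t < ev.t_end:
                F += ev.rate_L_per_h()
                c_feed = ev.c_oil_feed
        return kinetics.production_rhs(
            state, F, c_feed, p,
            scale_by_total_biomass=config.scale_by_total_biomass,
            inclusion_by_free_biomass=config.inclusion_by_free_biomass)

    y = np.array([handover.V_L, handover.c_x, 0.0, 0.0, 0.0, 0.0])
    t_cursor = handover.t
    for a, b in _segment_times(handover.t, config.t_end, breaks):
        for ev in events:
            if ev.kind == "bolus" and abs(ev.t_start - a) < 1e-9:
                v_new = y[0] + ev.volume_L()
                y[1:] *= y[0] / v_new
                y[3] += ev.mass_g() / v_new
                y[0] = v_new
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol)
        assert sol.success, sol.message
        y = np.concatenate([[sol.y[0, -1]], np.maximum(sol.y[1:, -1], 0.0)])
        t_cursor = b
    return y


@pytest.fixture(scope="session")
def toy_config(scenarios) -> ProcessConfig:
    return scenarios["toy"]
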