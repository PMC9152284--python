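"""Rate laws and ODE right-hand sides of the two-phase fermentation model.

Everything here is a pure function of a state and a parameter set; the
integrator lives in :mod:`melferm.simulate`.
"""

from __future__ import annotations

import math

from .params import (
    ExponentialFeedSpec,
    GrowthParameters,
    GrowthState,
    ProductionParameters,
    ProductionState,
)

__all__ = [
    "specific_growth_rate",
    "growth_rhs",
    "exponential_feed_rate",
    "hydrolysis_rate",
    "mel_rate",
    "inclusion_rate",
    "production_rhs",
]


def specific_growth_rate(state: GrowthState, p: GrowthParameters) -> float:
    """Dual-substrate Monod specific growth rate (1/h).

    The rate is governed by the most limiting of the two non-complementary
    substrates via a minimum operator:

        mu = mu_max * min( c_gluc/(K_gluc + c_gluc),
                           c_nano3/(K_nano3 + c_nano3) )
    """
    if state.c_gluc < 0 or state.c_nano3 < 0:
        raise ValueError("substrate concentrations must be >= 0")
    term_gluc = state.c_gluc / (p.K_gluc + state.c_gluc)
    term_nano3 = state.c_nano3 / (p.K_nano3 + state.c_nano3)
    return p.mu_max * min(term_gluc, term_nano3)


def growth_rhs(
    state: GrowthState,
    F_in: float,
    feed: ExponentialFeedSpec | None,
    p: GrowthParameters,
) -> tuple[float, float, float, float]:
    """Time derivatives (dV_L, dc_x, dc_gluc, dc_nano3) of the growth model.

    Feeding dilutes every species and supplies glucose and nitrate at the
    feed concentrations; substrate consumption is coupled to growth through
    constant yield coefficients.
    """
    if state.V_L <= 0:
        raise ValueError("liquid volume must be > 0")
    if F_in < 0:
        raise ValueError("feed rate must be >= 0")
    mu = specific_growth_rate(state, p)
    D = F_in / state.V_L
    c_gluc_feed = feed.c_gluc_feed if feed is not None else 0.0
    c_nano3_feed = feed.c_nano3_feed if feed is not None else 0.0
    dcx = -D * state.c_x + mu * state.c_x
    dcgluc = D * (c_gluc_feed - state.c_gluc) - (mu / p.Y_x_gluc) * state.c_x
    dcnano3 = D * (c_nano3_feed - state.c_nano3) - (mu / p.Y_x_nano3) * state.c_x
    return (F_in, dcx, dcgluc, dcnano3)


def exponential_feed_rate(
    t: float, feed: ExponentialFeedSpec, c_gluc: float | None = None
) -> float:
    """Volumetric medium-feed rate (L/h) of the exponential feeding law.

    Returns 0 outside [t_start, t_end].  ``c_gluc`` overrides the constant
    broth-glucose value assumed in the denominator (default 0 g/L, i.e.
    glucose-limited feeding).
    """
    if t < feed.t_start or t > feed.t_end:
        return 0.0
    c = feed.c_gluc_broth if c_gluc is None else c_gluc
    if c >= feed.c_gluc_feed:
        raise ValueError(
            "broth glucose at or above feed concentration: feed law diverges"
        )
    F0 = (feed.V0 * feed.cx0 * feed.mu_set) / (
        feed.Y_x_gluc_feed * (feed.c_gluc_feed - c)
    )
    if feed.delivered_volume_L is not None:
        # rescale so the window integral matches the known delivered total
        nominal = F0 / feed.mu_set * (
            math.exp(feed.mu_set * (feed.t_end - feed.t_start)) - 1.0
        )
        F0 *= feed.delivered_volume_L / nominal
    return F0 * math.exp(feed.mu_set * (t - feed.t_start))


def hydrolysis_rate(c_oil: float, c_fa: float, p: ProductionParameters) -> float:
    """Specific oil hydrolysis rate (g oil / g biomass / h).

    Michaelis-Menten in oil with competitive product inhibition by free
    fatty acids (lipase inhibition at high FA):

        q_hyd = q_max_hyd * c_oil / (c_oil + K_m_hyd * (1 + c_fa/K_i_hyd))
    """
    if c_oil < 0 or c_fa < 0:
        raise ValueError("concentrations must be >= 0")
    return p.q_max_hyd * c_oil / (c_oil + p.K_m_hyd * (1.0 + c_fa / p.K_i_hyd))


def mel_rate(c_fa: float, p: ProductionParameters) -> float:
    """Specific MEL formation rate (g MEL / g biomass / h), Michaelis-Menten in FA."""
    if c_fa < 0:
        raise ValueError("c_fa must be >= 0")
    return p.q_max_mel * c_fa / (c_fa + p.K_m_mel)


def inclusion_rate(c_fa: float, p: ProductionParameters) -> float:
    """Specific lipid-inclusion rate (g FA / g biomass / h), Michaelis-Menten in FA."""
    if c_fa < 0:
        raise ValueError("c_fa must be >= 0")
    return p.q_max_incl * c_fa / (c_fa + p.K_m_incl)


def production_rhs(
    state: ProductionState,
    F_in: float,
    c_oil_feed: float,
    p: ProductionParameters,
    scale_by_total_biomass: bool = False,
    inclusion_by_free_biomass: bool = True,
) -> tuple[float, float, float, float, float, float]:
    """Time derivatives (dV_L, dc_x_free, dc_x_incl, dc_oil, dc_fa, dc_mel).

    Hydrolysis and MEL fluxes are catalysed by the biomass frozen at the
    end of the growth phase (``c_x_growth``); set ``scale_by_total_biomass``
    to use the current measurable biomass instead (sensitivity analysis).
    The inclusion reaction converts lipid-free biomass into inclusion
    biomass, so the lipid-free pool carries a negative reaction term.

    By default the fatty-acid drain into inclusions is scaled by the
    lipid-free biomass — exactly ``Y_fa_incl`` times the inclusion-biomass
    formation flux, so inclusion bookkeeping closes and the drain shuts
    down as the lipid-free pool is converted.  Set
    ``inclusion_by_free_biomass=False`` to scale that drain by the
    catalytic biomass like the other fluxes (the drain then persists at
    full strength for the whole production phase).
    """
    if state.V_L <= 0:
        raise ValueError("liquid volume must be > 0")
    if F_in < 0:
        raise ValueError("feed rate must be >= 0")
    cx = state.c_x_total if scale_by_total_biomass else state.c_x_growth
    q_hyd = hydrolysis_rate(state.c_oil, state.c_fa, p)
    q_mel = mel_rate(state.c_fa, p)
    q_incl = inclusion_rate(state.c_fa, p)
    D = F_in / state.V_L

    cx_incl_drive = state.c_x_free if inclusion_by_free_biomass else cx
    d_oil = D * (c_oil_feed - state.c_oil) - q_hyd * cx
    d_fa = (
        D * (0.0 - state.c_fa)
        + p.Y_fa_oil * q_hyd * cx
        - p.Y_fa_mel * q_mel * cx
        - p.Y_fa_incl * q_incl * cx_incl_drive
    )
    d_mel = D * (0.0 - state.c_mel) + q_mel * cx
    d_x_incl = D * (0.0 - state.c_x_incl) + q_incl * state.c_x_free
    d_x_free = D * (0.0 - state.c_x_free) - p.Y_x_free_incl * q_incl * state.c_x_free
    return (F_in, d_x_free, d_x_incl, d_oil, d_fa, d_mel)
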