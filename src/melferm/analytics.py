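"""Process-evaluation calculations for fermentation data.

Implements the standard fermentation analytics used to evaluate the MEL
process: specific growth rate from biomass series, volumetric and
biomass-specific consumption/formation rates and yields over user-chosen
time windows, oxygen uptake / carbon-dioxide emission rates and the
respiratory quotient from dry-gas mole fractions (inert-gas balance), and
the MEL share of the crude lipid extract (extract purity).

Rates and yields over a window are obtained by linear regression by
default — the two-point difference quotient is available as a method
option for worked examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

R_GAS = 8.314  # J/(mol K)

#: dry-air inlet mole fractions used as defaults
Y_O2_AIR = 0.2095
Y_CO2_AIR = 0.0004

OD_TO_BIOMASS = 0.35        # g/L dry biomass per OD625 unit
BACKSCATTER_TO_OD = 1 / 0.14  # OD625 per backscatter (gain 5) unit

__all__ = [
    "OffGasRecord", "RateEstimate",
    "specific_growth_rate_obs", "consumption_rate_and_yield",
    "our_cer_rq", "outlet_fractions_from_rates", "specific_o2_and_yield",
    "oil_mel_rates_and_yield", "x_mel", "od_to_biomass",
    "backscatter_to_biomass", "feed_substrate_mass",
]


@dataclass(frozen=True)
class OffGasRecord:
    """One off-gas balance record (dry-gas mole fractions)."""

    t: float          # h
    Q_air: float      # L/h inlet airflow
    p_air: float      # Pa
    T: float          # K
    V_L: float        # L broth volume
    y_O2_in: float = Y_O2_AIR
    y_CO2_in: float = Y_CO2_AIR
    y_O2_out: float = Y_O2_AIR
    y_CO2_out: float = Y_CO2_AIR

    def __post_init__(self):
        for name in ("y_O2_in", "y_CO2_in", "y_O2_out", "y_CO2_out"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.y_O2_in + self.y_CO2_in >= 1:
            raise ValueError("inlet O2 + CO2 fractions must sum below 1")


@dataclass(frozen=True)
class RateEstimate:
    """A windowed rate or yield estimate with regression diagnostics."""

    window: tuple[float, float]
    value: float
    stderr: float = float("nan")
    r_squared: float = float("nan")
    method: str = "regression"

    def __post_init__(self):
        if not self.window[1] > self.window[0]:
            raise ValueError("window end must exceed window start")


def _window_mask(t, window):
    t = np.asarray(t, dtype=float)
    return (t >= window[0] - 1e-12) & (t <= window[1] + 1e-12)


def specific_growth_rate_obs(t, c_x, window, method="regression") -> RateEstimate:
    """Specific growth rate (1/h) over a window of a biomass series.

    Regression mode fits ln(c_x) against t (slope = mu, exact for
    exponential growth); two-point mode uses the difference quotient
    mu = dc_x/dt / c_x with the logarithmic-mean biomass.
    """
    t = np.asarray(t, dtype=float)
    c_x = np.asarray(c_x, dtype=float)
    m = _window_mask(t, window)
    if m.sum() < 2:
        raise ValueError("need at least two biomass samples in the window")
    tw, cw = t[m], c_x[m]
    if np.any(cw <= 0):
        raise ValueError("biomass must be strictly positive for growth-rate estimation")
    if method == "two-point":
        mu = (math.log(cw[-1]) - math.log(cw[0])) / (tw[-1] - tw[0])
        return RateEstimate((tw[0], tw[-1]), mu, method="two-point")
    res = stats.linregress(tw, np.log(cw))
    return RateEstimate((tw[0], tw[-1]), res.slope, stderr=res.stderr,
                        r_squared=res.rvalue**2, method="regression")


def _log_mean(a: float, b: float) -> float:
    if a <= 0 or b <= 0:
        raise ValueError("log-mean needs positive values")
    if math.isclose(a, b):
        return a
    return (b - a) / (math.log(b) - math.log(a))


def consumption_rate_and_yield(t_s, c_s, t_x, c_x, window, method="regression"):
    """Volumetric rate r_S, yield Y_X/S and specific rate q_S for a substrate.

    Consumption is reported positive.  q_S divides the volumetric rate by
    the logarithmic-mean biomass over the window, so q_S * Y_X/S equals the
    specific growth rate exactly on noiseless exponential data.

    Returns a dict with keys ``r_S``, ``Y_X_S``, ``q_S`` (RateEstimates).
    """
    t_s = np.asarray(t_s, dtype=float); c_s = np.asarray(c_s, dtype=float)
    t_x = np.asarray(t_x, dtype=float); c_x = np.asarray(c_x, dtype=float)
    ms, mx = _window_mask(t_s, window), _window_mask(t_x, window)
    if ms.sum() < 2 or mx.sum() < 2:
        raise ValueError("window not covered by both series")
    ts, cs = t_s[ms], c_s[ms]
    tx, cx = t_x[mx], c_x[mx]
    win = (max(ts[0], tx[0]), min(ts[-1], tx[-1]))

    d_s = cs[-1] - cs[0]
    d_x = cx[-1] - cx[0]
    if abs(d_s) < 1e-12:
        raise ValueError("no substrate change over the window: yield undefined")
    if method == "two-point":
        r = -(d_s) / (ts[-1] - ts[0])
        Y = d_x / (-d_s)
        se_r = se_y = float("nan"); r2 = float("nan")
    else:
        res = stats.linregress(ts, cs)
        r = -res.slope
        se_r = res.stderr
        r2 = res.rvalue**2
        # yield from regression of c_x against c_s on the common grid
        if len(ts) == len(tx) and np.allclose(ts, tx):
            resy = stats.linregress(cs, cx)
            Y, se_y = -resy.slope, resy.stderr
        else:
            Y, se_y = d_x / (-d_s), float("nan")
    cbar = _log_mean(cx[0], cx[-1])
    q = r / cbar
    return {
        "r_S": RateEstimate(win, r, stderr=se_r, r_squared=r2, method=method),
        "Y_X_S": RateEstimate(win, Y, stderr=se_y, method=method),
        "q_S": RateEstimate(win, q, method=method),
    }


def our_cer_rq(rec: OffGasRecord) -> tuple[float, float, float]:
    """OUR and CER (mmol/L/h) and RQ from one off-gas record.

    The molar gas flow is Q_air * p_air / (R * T); the inert-gas (nitrogen)
    balance relates outlet to inlet flow through the ratio of inert mole
    fractions.  RQ = CER / OUR; RQ is NaN when OUR <= 0.
    """
    inert_out = 1.0 - rec.y_O2_out - rec.y_CO2_out
    if inert_out <= 0:
        raise ValueError("outlet O2 + CO2 fractions must sum below 1")
    inert_in = 1.0 - rec.y_O2_in - rec.y_CO2_in
    # ideal gas with Q in L/h: p*Q/(R*T) is numerically mmol gas per hour
    n_flow = rec.Q_air * rec.p_air / (R_GAS * rec.T)
    ratio = inert_in / inert_out
    our = n_flow / rec.V_L * (rec.y_O2_in - ratio * rec.y_O2_out)
    cer = n_flow / rec.V_L * (ratio * rec.y_CO2_out - rec.y_CO2_in)
    rq = cer / our if our > 0 else float("nan")
    return our, cer, rq


def outlet_fractions_from_rates(
    our: float, cer: float, Q_air: float, p_air: float, T: float, V_L: float,
    y_O2_in: float = Y_O2_AIR, y_CO2_in: float = Y_CO2_AIR,
) -> tuple[float, float]:
    """Invert the off-gas balance: outlet mole fractions for given OUR/CER.

    OUR and CER are in mmol/L/h.  The exact inverse of :func:`our_cer_rq`
    (inert flow conserved), used to synthesize off-gas observations.
    """
    n_in = Q_air * p_air / (R_GAS * T)  # mmol/h (Q in L/h)
    o2_out = n_in * y_O2_in - our * V_L
    co2_out = n_in * y_CO2_in + cer * V_L
    inert = n_in * (1.0 - y_O2_in - y_CO2_in)
    n_out = o2_out + co2_out + inert
    if o2_out < 0 or n_out <= 0:
        raise ValueError("requested OUR exceeds the oxygen supplied")
    return o2_out / n_out, co2_out / n_out


def specific_o2_and_yield(t_our, our, t_x, c_x, window):
    """Specific oxygen uptake q_O2 (mmol/g/h) and biomass yield from O2.

    q_O2 = OUR / c_x averaged over the window; Y_X/O2 (g biomass per mmol
    O2) from the biomass change against cumulative oxygen consumed.
    """
    t_our = np.asarray(t_our, dtype=float); our = np.asarray(our, dtype=float)
    t_x = np.asarray(t_x, dtype=float); c_x = np.asarray(c_x, dtype=float)
    mo, mx = _window_mask(t_our, window), _window_mask(t_x, window)
    if mo.sum() < 2 or mx.sum() < 2:
        raise ValueError("window not covered by both series")
    if np.any(c_x[mx] <= 0):
        raise ValueError("biomass must be positive")
    cx_on_our = np.interp(t_our[mo], t_x[mx], c_x[mx])
    q_o2 = float(np.mean(our[mo] / cx_on_our))
    o2_consumed = np.concatenate([[0.0], np.cumsum(
        0.5 * (our[mo][1:] + our[mo][:-1]) * np.diff(t_our[mo]))])
    d_o2 = o2_consumed[-1]
    d_x = c_x[mx][-1] - c_x[mx][0]
    y = d_x / d_o2 if d_o2 > 0 else float("nan")
    win = (t_our[mo][0], t_our[mo][-1])
    return {
        "q_O2": RateEstimate(win, q_o2),
        "Y_X_O2": RateEstimate(win, y),
    }


def oil_mel_rates_and_yield(
    t_oil, c_oil, t_mel, c_mel, c_x_growth, window,
    total_oil_added=None, method="regression",
):
    """Production-phase oil consumption and MEL formation rates and yields.

    Returns volumetric rates r_oil and r_MEL (g/L/h), biomass-specific
    rates q_oil and q_MEL (per gram of end-of-growth biomass), the
    differential yield Y_MEL/oil = dc_MEL/dc_oil, and — when
    ``total_oil_added`` (g/L) is given — the yield related to the total
    amount of oil added.
    """
    t_oil = np.asarray(t_oil, dtype=float); c_oil = np.asarray(c_oil, dtype=float)
    t_mel = np.asarray(t_mel, dtype=float); c_mel = np.asarray(c_mel, dtype=float)
    mo, mm = _window_mask(t_oil, window), _window_mask(t_mel, window)
    if mo.sum() < 2 or mm.sum() < 2:
        raise ValueError("window not covered by both series")
    if c_x_growth <= 0:
        raise ValueError("c_x_growth must be positive")

    def _rate(tw, cw, sign):
        if method == "two-point":
            return RateEstimate((tw[0], tw[-1]),
                                sign * (cw[-1] - cw[0]) / (tw[-1] - tw[0]),
                                method="two-point")
        res = stats.linregress(tw, cw)
        return RateEstimate((tw[0], tw[-1]), sign * res.slope, stderr=res.stderr,
                            r_squared=res.rvalue**2, method="regression")

    r_oil = _rate(t_oil[mo], c_oil[mo], -1.0)
    r_mel = _rate(t_mel[mm], c_mel[mm], +1.0)
    d_mel = c_mel[mm][-1] - c_mel[mm][0]
    d_oil = c_oil[mo][-1] - c_oil[mo][0]
    win = r_mel.window
    out = {
        "r_oil": r_oil,
        "q_oil": RateEstimate(win, r_oil.value / c_x_growth, method=method),
        "r_MEL": r_mel,
        "q_MEL": RateEstimate(win, r_mel.value / c_x_growth, method=method),
    }
    if abs(d_oil) > 1e-12:
        out["Y_MEL_oil"] = RateEstimate(win, d_mel / (-d_oil), method="two-point")
    if total_oil_added is not None:
        if total_oil_added <= 0:
            raise ValueError("total oil added must be positive")
        out["Y_MEL_total_oil"] = RateEstimate(
            win, c_mel[mm][-1] / total_oil_added, method="two-point")
    return out


def x_mel(c_mel: float, c_oil: float, c_fa: float) -> float:
    """MEL share of the crude lipid extract, X_MEL = c_MEL / (c_oil + c_FA + c_MEL)."""
    if min(c_mel, c_oil, c_fa) < 0:
        raise ValueError("concentrations must be >= 0")
    total = c_mel + c_oil + c_fa
    if total <= 0:
        raise ValueError("crude extract is empty: X_MEL undefined")
    return c_mel / total


def od_to_biomass(od625: float) -> float:
    """Dry biomass (g/L) from OD625 via the linear correlation 0.35 g/L per OD."""
    if od625 < 0:
        raise ValueError("OD must be >= 0")
    return OD_TO_BIOMASS * od625


def backscatter_to_biomass(backscatter: float) -> float:
    """Dry biomass (g/L) from a gain-5 backscatter reading (via OD625)."""
    if backscatter < 0:
        raise ValueError("backscatter must be >= 0")
    return od_to_biomass(backscatter * BACKSCATTER_TO_OD)


def feed_substrate_mass(feed_mass_g: float, c_substrate_feed: float,
                        density_g_per_mL: float = 1.0) -> float:
    """Substrate mass (g) delivered by a given mass of feed solution.

    Converts the fed solution mass to volume with the stated density
    (default 1 g/mL, the bookkeeping convention under which 460 g of
    300 g/L glucose feed delivers 138 g glucose) and multiplies by the
    substrate concentration of the feed.
    """
    if feed_mass_g < 0 or c_substrate_feed < 0 or density_g_per_mL <= 0:
        raise ValueError("invalid feed bookkeeping inputs")
    volume_L = feed_mass_g / density_g_per_mL / 1000.0
    return volume_L * c_substrate_feed
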