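"""Synthetic observation tables and the shipped process-scenario library.

The generator emulates the measurement regime of a stirred-tank MEL
fermentation: sparse offline samples (OD, dry biomass, glucose, nitrate,
oil, fatty acids, MEL) with multiplicative lognormal measurement noise,
and a dense off-gas stream whose outlet mole fractions are constructed by
exactly inverting the inert-gas balance from model-implied oxygen uptake
and carbon-dioxide emission rates.

The scenario library reconstructs the six bioreactor processes (B1, B2,
FB1-FB4) from their published phase timings and feed schedules, plus a
fast toy scenario; values the process descriptions do not state (some
feed-spec biomass assumptions, fed-batch start volumes) are reconstructed
and flagged in the builder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analytics
from .params import ExponentialFeedSpec, GrowthParameters, GrowthState
from .simulate import OilFeedEvent, ProcessConfig, Trajectory, simulate_process

__all__ = ["NoiseModel", "generate_observations", "generate_scenarios",
           "OBSERVATION_COLUMNS"]

#: fixed column schema of an observation table CSV
OBSERVATION_COLUMNS = [
    "t_h", "od625", "c_x", "c_gluc", "c_nano3", "c_oil", "c_fa", "c_mel",
    "y_o2_in", "y_co2_in", "y_o2_out", "y_co2_out",
    "q_air_lph", "p_pa", "t_k", "v_l",
]

_OFFLINE_SPECIES = ("od625", "c_x", "c_gluc", "c_nano3", "c_oil", "c_fa", "c_mel")

#: default generator conventions for the off-gas stream
VVM = 0.7                 # aeration, gas volumes per liquid volume per minute
P_AIR = 101325.0          # Pa
T_GAS = 303.15            # K (30 degC)
Q_O2_AT_MU_MAX = 4.3      # mmol/g/h specific O2 uptake at mu_max
RQ_GROWTH = 1.4
RQ_PRODUCTION = 0.52
Q_O2_PRODUCTION = 1.5     # mmol/g/h on c_x_growth (generator convention)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for synthetic observation tables.

    ``rel_sd`` is the multiplicative (lognormal) relative standard
    deviation applied to every offline species; ``floor_sd`` adds a
    half-normal detection floor (g/L) so near-zero species still scatter
    without ever going negative.  ``offgas_sd`` is the absolute standard
    deviation on the outlet mole fractions.
    """

    rel_sd: float = 0.05
    floor_sd: dict = field(default_factory=dict)   # per species, g/L
    offgas_sd: float = 2e-4
    offline_interval: float = 8.0   # h
    offgas_interval: float = 0.2    # h
    seed: int = 0

    def __post_init__(self):
        if self.rel_sd < 0 or self.offgas_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if any(v < 0 for v in self.floor_sd.values()):
            raise ValueError("floor standard deviations must be >= 0")


def generate_observations(
    config: ProcessConfig, noise: NoiseModel | None = None,
    trajectory: Trajectory | None = None,
) -> pd.DataFrame:
    """Simulate a process and sample it like a real fermentation.

    Offline species are sampled every ``offline_interval`` hours (snapped
    to the simulation grid) with lognormal noise; off-gas outlet mole
    fractions are sampled every ``offgas_interval`` hours by inverting
    the gas balance from the model-implied OUR/CER, with absolute
    Gaussian noise.  With all noise set to zero the table lies exactly on
    the simulated trajectory.  Deterministic for a fixed seed.
    """
    noise = noise or NoiseModel()
    traj = trajectory or simulate_process(config)
    rng = np.random.default_rng(noise.seed)
    frame = traj.frame
    t_min, t_max = frame["t_h"].iloc[0], frame["t_h"].iloc[-1]

    cxg = traj.handover.c_x if traj.handover is not None else float("nan")

    def _snap_rows(interval):
        times = np.arange(t_min, t_max + 1e-9, interval)
        idx = sorted({int((frame["t_h"] - t).abs().idxmin()) for t in times})
        return frame.loc[idx]

    records = {}

    for _, row in _snap_rows(noise.offline_interval).iterrows():
        t = float(row["t_h"])
        rec = records.setdefault(t, {"t_h": t})
        true_vals = {
            "od625": row["c_x_total"] / analytics.OD_TO_BIOMASS,
            "c_x": row["c_x_total"],
            "c_gluc": row["c_gluc"],
            "c_nano3": row["c_nano3"],
            "c_oil": row["c_oil"],
            "c_fa": row["c_fa"],
            "c_mel": row["c_mel"],
        }
        for name, value in true_vals.items():
            v = value
            if noise.rel_sd > 0 and v > 0:
                v = v * math.exp(rng.normal(0.0, noise.rel_sd))
            floor = noise.floor_sd.get(name, 0.0)
            if floor > 0:
                v = v + abs(rng.normal(0.0, floor))
            rec[name] = v

    for _, row in _snap_rows(noise.offgas_interval).iterrows():
        t = float(row["t_h"])
        rec = records.setdefault(t, {"t_h": t})
        v_l = float(row["V_L"])
        q_air = VVM * v_l * 60.0  # L/h
        if row["phase"] == "growth":
            y_x_o2 = config.growth.mu_max / Q_O2_AT_MU_MAX
            our = row["mu"] / y_x_o2 * row["c_x_total"]
            cer = RQ_GROWTH * our
        else:
            our = Q_O2_PRODUCTION * cxg
            cer = RQ_PRODUCTION * our
        if our > 0:
            y_o2_out, y_co2_out = analytics.outlet_fractions_from_rates(
                our, cer, q_air, P_AIR, T_GAS, v_l)
        else:
            y_o2_out, y_co2_out = analytics.Y_O2_AIR, analytics.Y_CO2_AIR
        if noise.offgas_sd > 0:
            y_o2_out = min(max(y_o2_out + rng.normal(0.0, noise.offgas_sd), 0.0), 0.999)
            y_co2_out = min(max(y_co2_out + rng.normal(0.0, noise.offgas_sd), 0.0), 0.999)
        rec.update({
            "y_o2_in": analytics.Y_O2_AIR, "y_co2_in": analytics.Y_CO2_AIR,
            "y_o2_out": y_o2_out, "y_co2_out": y_co2_out,
            "q_air_lph": q_air, "p_pa": P_AIR, "t_k": T_GAS, "v_l": v_l,
        })

    table = pd.DataFrame(sorted(records.values(), key=lambda r: r["t_h"]))
    for col in OBSERVATION_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return table[OBSERVATION_COLUMNS].reset_index(drop=True)


def _fed_volume(feed: ExponentialFeedSpec) -> float:
    """Closed-form total volume (L) delivered by an exponential feed."""
    if feed.delivered_volume_L is not None:
        return feed.delivered_volume_L
    F0 = (feed.V0 * feed.cx0 * feed.mu_set) / (
        feed.Y_x_gluc_feed * (feed.c_gluc_feed - feed.c_gluc_broth))
    return F0 / feed.mu_set * (
        math.exp(feed.mu_set * (feed.t_end - feed.t_start)) - 1.0)


def _batch_initial(volume: float, c_gluc: float = 30.0, c_nano3: float = 3.0,
                   c_x: float = 0.21) -> GrowthState:
    # inoculation to OD625 = 0.6 -> 0.21 g/L dry biomass
    return GrowthState(t=0.0, V_L=volume, c_x=c_x, c_gluc=c_gluc, c_nano3=c_nano3)


def generate_scenarios() -> dict[str, ProcessConfig]:
    """Shipped process-scenario reconstructions.

    B1/B2 are batch-growth processes in 4 L; FB1-FB4 start from 3 L and
    add an exponential medium feed.  Feed-spec constants not stated in
    the process descriptions (FB2's assumed biomass, FB4's) are
    reconstructed from the neighbouring processes and the reported feed
    totals; oil bolus reference volumes for the fed-batch processes are
    the broth volume at production start.
    """
    scen: dict[str, ProcessConfig] = {}

    scen["B1"] = ProcessConfig(
        name="B1", initial=_batch_initial(4.0),
        t_growth_end=48.0, t_end=240.0,
        oil_feeds=(OilFeedEvent("bolus", 48.0, 6.0, "pct_vv",
                                reference_volume=4.0),),
    )

    scen["B2"] = ProcessConfig(
        name="B2", initial=_batch_initial(4.0),
        t_growth_end=48.0, t_end=333.0,
        oil_feeds=tuple(
            OilFeedEvent("bolus", t, a, "pct_vv", reference_volume=4.0)
            for t, a in [(48.0, 6.0), (118.0, 4.0), (165.0, 4.0),
                         (215.0, 4.0), (286.0, 4.0)]
        ),
    )

    # Feed totals follow the reported feed-solution masses under the
    # unit-density bookkeeping (460 g -> 0.46 L -> 138 g glucose); the
    # exponential profile shape follows the feed law.
    fb1_feed = ExponentialFeedSpec(t_start=44.5, t_end=55.0, mu_set=0.08,
                                   V0=3.0, cx0=7.6, delivered_volume_L=0.460)
    v55 = 3.0 + _fed_volume(fb1_feed)
    scen["FB1"] = ProcessConfig(
        name="FB1", initial=_batch_initial(3.0), feed=fb1_feed,
        t_growth_end=55.0, t_end=310.0,
        oil_feeds=tuple(
            OilFeedEvent("bolus", t, 6.0, "pct_vv", reference_volume=v55)
            for t in (55.0, 142.0, 190.0, 242.0)
        ),
    )

    fb2_feed = ExponentialFeedSpec(t_start=42.5, t_end=54.0, mu_set=0.09,
                                   V0=3.0, cx0=7.6, delivered_volume_L=0.612)
    v54 = 3.0 + _fed_volume(fb2_feed)
    scen["FB2"] = ProcessConfig(
        name="FB2", initial=_batch_initial(3.0), feed=fb2_feed,
        t_growth_end=54.0, t_end=310.0,
        oil_feeds=(
            OilFeedEvent("bolus", 54.0, 6.0, "pct_vv", reference_volume=v54),
            OilFeedEvent("continuous", 72.0, 11.0, "mL_per_h", t_end=140.0),
        ),
    )

    fb3_feed = ExponentialFeedSpec(t_start=40.0, t_end=51.0, mu_set=0.09,
                                   V0=3.0, cx0=6.0, delivered_volume_L=0.708)
    v51 = 3.0 + _fed_volume(fb3_feed)
    scen["FB3"] = ProcessConfig(
        name="FB3", initial=_batch_initial(3.0), feed=fb3_feed,
        t_growth_end=51.0, t_end=231.0,
        oil_feeds=tuple(
            OilFeedEvent("bolus", t, 6.0, "pct_vv", reference_volume=v51)
            for t in (51.0, 72.0)
        ),
    )

    # FB4: lowered batch medium (2/3 of the standard), early feed start;
    # the assumed feed biomass (4 g/L) is reconstructed from the reported
    # 701 g feed total.
    fb4_feed = ExponentialFeedSpec(t_start=27.0, t_end=44.0, mu_set=0.08,
                                   V0=3.0, cx0=4.0, delivered_volume_L=0.701)
    v44 = 3.0 + _fed_volume(fb4_feed)
    scen["FB4"] = ProcessConfig(
        name="FB4", initial=_batch_initial(3.0, c_gluc=20.0, c_nano3=2.0),
        feed=fb4_feed, t_growth_end=44.5, t_end=307.0,
        oil_feeds=(
            OilFeedEvent("bolus", 44.5, 6.0, "pct_vv", reference_volume=v44),
            OilFeedEvent("continuous", 52.0, 8.0, "mL_per_h", t_end=82.0),
        ),
    )

    scen["toy"] = ProcessConfig(
        name="toy", initial=GrowthState(t=0.0, V_L=1.0, c_x=0.5,
                                        c_gluc=10.0, c_nano3=1.0),
        t_growth_end=10.0, t_end=30.0,
        oil_feeds=(OilFeedEvent("bolus", 10.0, 5.0, "pct_vv",
                                reference_volume=1.0),),
    )
    return scen
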