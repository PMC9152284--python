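"""Explicit-Euler simulation of the two-phase fermentation process.

The growth model (batch + optional exponential fed-batch) and the
production model (oil hydrolysis, MEL formation, lipid inclusion) are
integrated with an explicit Euler scheme — step sizes 0.05 h (growth) and
0.2 h (production) by default — and chained with a hand-over at the
configured end of the growth phase: the biomass reached there is frozen as
the catalytic biomass of the production phase.

Oil is added either as instantaneous boluses (perfect mixing: every
concentration is diluted by the volume ratio and the oil pool gains the
added mass) or as continuous feeds entering through the dilution terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .params import (
    ExponentialFeedSpec,
    GrowthParameters,
    GrowthState,
    ProductionParameters,
    ProductionState,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OilFeedEvent",
    "ProcessConfig",
    "Trajectory",
    "euler_step",
    "simulate_growth",
    "simulate_production",
    "simulate_process",
    "TRAJECTORY_COLUMNS",
]

#: Fixed export column order of a trajectory CSV.
TRAJECTORY_COLUMNS = [
    "t_h", "phase", "V_L", "c_x_free", "c_x_incl", "c_x_total",
    "c_gluc", "c_nano3", "c_oil", "c_fa", "c_mel", "F_in",
]

_NEG_CLAMP_TOL = -1e-6


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite derivative."""


@dataclass(frozen=True)
class OilFeedEvent:
    """One oil addition: an instantaneous bolus or a continuous feed.

    ``amount`` is interpreted according to ``unit``:

    - ``"pct_vv"``: volume percent of ``reference_volume`` (total volume
      for the event, also for continuous feeds);
    - ``"mL"``: absolute volume in millilitres (total for the event);
    - ``"mL_per_h"``: feed rate (continuous events only).
    """

    kind: str                    # "bolus" | "continuous"
    t_start: float               # h
    amount: float
    unit: str = "pct_vv"
    t_end: float | None = None   # h; equals t_start for a bolus
    reference_volume: float = 4.0  # L, basis of % v/v amounts
    oil_density: float = 0.92    # g/mL

    def __post_init__(self):
        if self.kind not in ("bolus", "continuous"):
            raise ValueError(f"unknown oil feed kind {self.kind!r}")
        if self.unit not in ("pct_vv", "mL", "mL_per_h"):
            raise ValueError(f"unknown oil amount unit {self.unit!r}")
        if self.amount <= 0:
            raise ValueError("oil feed amount must be > 0")
        if self.kind == "bolus":
            if self.unit == "mL_per_h":
                raise ValueError("bolus events need a volume, not a rate")
            if self.t_end is not None and self.t_end != self.t_start:
                raise ValueError("bolus events must have t_end == t_start")
        else:
            if self.t_end is None or not self.t_end > self.t_start:
                raise ValueError("continuous events need t_end > t_start")

    @property
    def duration(self) -> float:
        return 0.0 if self.kind == "bolus" else self.t_end - self.t_start

    def volume_L(self) -> float:
        """Total oil volume delivered by the event (L)."""
        if self.unit == "pct_vv":
            return self.amount / 100.0 * self.reference_volume
        if self.unit == "mL":
            return self.amount / 1000.0
        return self.amount / 1000.0 * self.duration  # mL_per_h

    def mass_g(self) -> float:
        """Total oil mass delivered by the event (g)."""
        return self.volume_L() * 1000.0 * self.oil_density

    def rate_L_per_h(self) -> float:
        """Volumetric feed rate of a continuous event (L/h)."""
        if self.kind != "continuous":
            raise ValueError("bolus events have no feed rate")
        return self.volume_L() / self.duration

    @property
    def c_oil_feed(self) -> float:
        """Oil concentration of the (pure oil) feed stream, g/L."""
        return 1000.0 * self.oil_density


@dataclass(frozen=True)
class ProcessConfig:
    """Complete definition of one simulated fermentation."""

    initial: GrowthState
    growth: GrowthParameters = field(default_factory=GrowthParameters)
    production: ProductionParameters = field(default_factory=ProductionParameters)
    feed: ExponentialFeedSpec | None = None
    oil_feeds: tuple[OilFeedEvent, ...] = ()
    t_growth_end: float = 48.0
    t_end: float = 333.0
    dt_growth: float = 0.05
    dt_production: float = 0.2
    seed: int = 0
    scale_by_total_biomass: bool = False
    inclusion_by_free_biomass: bool = True
    name: str = "process"

    def __post_init__(self):
        if self.dt_growth <= 0 or self.dt_production <= 0:
            raise ValueError("step sizes must be > 0")
        if self.t_end < self.t_growth_end:
            raise ValueError("t_end must be >= t_growth_end")
        object.__setattr__(self, "oil_feeds", tuple(self.oil_feeds))

    def replace(self, **kwargs) -> "ProcessConfig":
        return replace(self, **kwargs)

    def total_oil_mass_g(self) -> float:
        return sum(ev.mass_g() for ev in self.oil_feeds)


class Trajectory:
    """Time-ordered simulation records with feed bookkeeping.

    Wraps a :class:`pandas.DataFrame`; the exported CSV columns and their
    order are fixed (:data:`TRAJECTORY_COLUMNS`), diagnostic columns
    (instantaneous rates, cumulative feeds) come after.
    """

    def __init__(self, frame: pd.DataFrame, handover: GrowthState | None = None):
        if not frame["t_h"].is_monotonic_increasing:
            raise ValueError("trajectory times must be increasing")
        self.frame = frame.reset_index(drop=True)
        self.handover = handover

    def __len__(self) -> int:
        return len(self.frame)

    def at(self, t: float) -> pd.Series:
        """Record at the grid time nearest to ``t``."""
        idx = (self.frame["t_h"] - t).abs().idxmin()
        return self.frame.loc[idx]

    def final(self) -> pd.Series:
        return self.frame.iloc[-1]

    @property
    def phases(self) -> pd.Series:
        return self.frame["phase"]

    def concat(self, other: "Trajectory") -> "Trajectory":
        first = self.frame
        # drop the duplicated hand-over time point from the second leg
        second = other.frame
        if len(first) and len(second) and second["t_h"].iloc[0] <= first["t_h"].iloc[-1]:
            second = second.iloc[1:]
        out = pd.concat([first, second], ignore_index=True)
        return Trajectory(out, handover=other.handover or self.handover)


def euler_step(
    y: Sequence[float], dydt: Sequence[float], dt: float,
    names: Sequence[str] | None = None, clamp_from: int = 0,
) -> list[float]:
    """One explicit Euler step with a non-negativity clamp.

    Entries from index ``clamp_from`` on are clamped at zero after the
    step (the Euler scheme can slightly undershoot near substrate
    exhaustion); an undershoot beyond -1e-6 is logged.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    out = []
    for i, (yi, di) in enumerate(zip(y, dydt)):
        if not math.isfinite(di):
            label = names[i] if names else f"component {i}"
            raise IntegrationError(f"non-finite derivative for {label}")
        yn = yi + dt * di
        if i >= clamp_from and yn < 0.0:
            if yn < _NEG_CLAMP_TOL:
                label = names[i] if names else f"component {i}"
                logger.warning("clamping %s from %.3e to 0", label, yn)
            yn = 0.0
        out.append(yn)
    return out


_GROWTH_NAMES = ("V_L", "c_x", "c_gluc", "c_nano3")
_PROD_NAMES = ("V_L", "c_x_free", "c_x_incl", "c_oil", "c_fa", "c_mel")


def _time_grid(t0: float, t1: float, dt: float) -> np.ndarray:
    n = max(1, round((t1 - t0) / dt))
    if abs(t0 + n * dt - t1) > 1e-9:
        n = math.ceil((t1 - t0) / dt - 1e-12)
    grid = t0 + dt * np.arange(n + 1)
    grid[-1] = t1
    return grid


def simulate_growth(config: ProcessConfig) -> Trajectory:
    """Integrate the growth phase: batch, then optional exponential feed."""
    s = config.initial
    p = config.growth
    feed = config.feed
    t_grid = _time_grid(s.t, config.t_growth_end, config.dt_growth)

    y = [s.V_L, s.c_x, s.c_gluc, s.c_nano3]
    cum_feed_vol = 0.0
    rows = []
    for k, t in enumerate(t_grid):
        state = GrowthState(t=t, V_L=y[0], c_x=y[1], c_gluc=y[2], c_nano3=y[3])
        F_in = kinetics.exponential_feed_rate(t, feed) if feed is not None else 0.0
        mu = kinetics.specific_growth_rate(state, p)
        rows.append((t, y[0], y[1], y[2], y[3], F_in, mu, cum_feed_vol))
        if k == len(t_grid) - 1:
            break
        dydt = kinetics.growth_rhs(state, F_in, feed, p)
        dt = t_grid[k + 1] - t
        y = euler_step(y, dydt, dt, names=_GROWTH_NAMES, clamp_from=1)
        cum_feed_vol += F_in * dt

    arr = np.asarray(rows)
    frame = pd.DataFrame({
        "t_h": arr[:, 0],
        "phase": "growth",
        "V_L": arr[:, 1],
        "c_x_free": arr[:, 2],
        "c_x_incl": 0.0,
        "c_x_total": arr[:, 2],
        "c_gluc": arr[:, 3],
        "c_nano3": arr[:, 4],
        "c_oil": 0.0,
        "c_fa": 0.0,
        "c_mel": 0.0,
        "F_in": arr[:, 5],
        "mu": arr[:, 6],
        "q_hyd": 0.0,
        "q_mel": 0.0,
        "q_incl": 0.0,
        "cum_feed_volume_L": arr[:, 7],
        "cum_oil_mass_g": 0.0,
    })
    end = frame.iloc[-1]
    handover = GrowthState(
        t=float(end["t_h"]), V_L=float(end["V_L"]), c_x=float(end["c_x_free"]),
        c_gluc=float(end["c_gluc"]), c_nano3=float(end["c_nano3"]),
    )
    return Trajectory(frame, handover=handover)


def _continuous_oil_inflow(t: float, events: Iterable[OilFeedEvent]) -> tuple[float, float]:
    """Total continuous oil feed rate (L/h) and its oil concentration (g/L) at ``t``."""
    F = 0.0
    mass_rate = 0.0
    for ev in events:
        if ev.kind == "continuous" and ev.t_start <= t < ev.t_end:
            r = ev.rate_L_per_h()
            F += r
            mass_rate += r * ev.c_oil_feed
    return (F, mass_rate / F if F > 0 else 0.0)


def simulate_production(config: ProcessConfig, handover: GrowthState) -> Trajectory:
    """Integrate the production phase from the growth hand-over state.

    The hand-over biomass becomes both the initial lipid-free biomass and
    the frozen catalytic biomass ``c_x_growth``.  Bolus oil additions are
    applied at the nearest grid time at or before their event time as
    instantaneous, perfectly mixed dilutions.
    """
    for ev in config.oil_feeds:
        if ev.t_start < config.t_growth_end - 1e-9:
            raise ValueError(
                f"oil feed at {ev.t_start} h precedes the growth/production "
                f"hand-over at {config.t_growth_end} h"
            )
    p = config.production
    t_grid = _time_grid(handover.t, config.t_end, config.dt_production)

    # assign each bolus to the nearest grid index at or before its time
    boluses: dict[int, list[OilFeedEvent]] = {}
    for ev in config.oil_feeds:
        if ev.kind != "bolus":
            continue
        idx = int(np.searchsorted(t_grid, ev.t_start + 1e-9) - 1)
        idx = max(idx, 0)
        boluses.setdefault(idx, []).append(ev)

    cx_growth = handover.c_x
    y = [handover.V_L, handover.c_x, 0.0, 0.0, 0.0, 0.0]  # V, x_free, x_incl, oil, fa, mel
    c_gluc, c_nano3 = handover.c_gluc, handover.c_nano3  # passively diluted
    cum_feed_vol = 0.0
    cum_oil_mass = 0.0
    rows = []
    for k, t in enumerate(t_grid):
        for ev in boluses.get(k, ()):
            v_old = y[0]
            v_new = v_old + ev.volume_L()
            ratio = v_old / v_new
            y = [v_new] + [c * ratio for c in y[1:]]
            y[3] += ev.mass_g() / v_new
            c_gluc *= ratio
            c_nano3 *= ratio
            cum_feed_vol += ev.volume_L()
            cum_oil_mass += ev.mass_g()
            logger.info("t=%.1f h: oil bolus of %.1f g (%.3f L)", t, ev.mass_g(), ev.volume_L())
        state = ProductionState(
            t=t, V_L=y[0], c_x_free=y[1], c_x_incl=y[2],
            c_oil=y[3], c_fa=y[4], c_mel=y[5], c_x_growth=cx_growth,
        )
        F_in, c_oil_feed = _continuous_oil_inflow(t, config.oil_feeds)
        q_hyd = kinetics.hydrolysis_rate(y[3], y[4], p)
        q_mel = kinetics.mel_rate(y[4], p)
        q_incl = kinetics.inclusion_rate(y[4], p)
        rows.append((t, y[0], y[1], y[2], y[3], y[4], y[5], F_in,
                     q_hyd, q_mel, q_incl, cum_feed_vol, cum_oil_mass,
                     c_gluc, c_nano3))
        if k == len(t_grid) - 1:
            break
        dydt = kinetics.production_rhs(
            state, F_in, c_oil_feed, p,
            scale_by_total_biomass=config.scale_by_total_biomass,
            inclusion_by_free_biomass=config.inclusion_by_free_biomass,
        )
        dt = t_grid[k + 1] - t
        y = euler_step(y, dydt, dt, names=_PROD_NAMES, clamp_from=1)
        if F_in > 0:
            D = F_in / state.V_L
            c_gluc = max(0.0, c_gluc - dt * D * c_gluc)
            c_nano3 = max(0.0, c_nano3 - dt * D * c_nano3)
            cum_feed_vol += F_in * dt
            cum_oil_mass += F_in * c_oil_feed * dt

    arr = np.asarray(rows)
    frame = pd.DataFrame({
        "t_h": arr[:, 0],
        "phase": "production",
        "V_L": arr[:, 1],
        "c_x_free": arr[:, 2],
        "c_x_incl": arr[:, 3],
        "c_x_total": arr[:, 2] + arr[:, 3],
        "c_gluc": arr[:, 13],
        "c_nano3": arr[:, 14],
        "c_oil": arr[:, 4],
        "c_fa": arr[:, 5],
        "c_mel": arr[:, 6],
        "F_in": arr[:, 7],
        "mu": 0.0,
        "q_hyd": arr[:, 8],
        "q_mel": arr[:, 9],
        "q_incl": arr[:, 10],
        "cum_feed_volume_L": arr[:, 11],
        "cum_oil_mass_g": arr[:, 12],
    })
    return Trajectory(frame, handover=handover)


def simulate_process(config: ProcessConfig) -> Trajectory:
    """Chain growth and production phases with the hand-over in between."""
    growth = simulate_growth(config)
    if config.t_end <= config.t_growth_end:
        return growth
    production = simulate_production(config, growth.handover)
    # carry growth-phase feed bookkeeping into the production leg
    base_vol = growth.frame["cum_feed_volume_L"].iloc[-1]
    production.frame["cum_feed_volume_L"] += base_vol
    return growth.concat(production)
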