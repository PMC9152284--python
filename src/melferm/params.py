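"""Parameter sets and state vectors for the two-phase MEL fermentation model.

The fermentation of *Moesziomyces aphidis* is modelled in two decoupled
phases: a growth phase (dual-substrate Monod kinetics on glucose and sodium
nitrate, optionally with exponential fed-batch feeding) and a production
phase (oil hydrolysis, fatty-acid-to-MEL conversion and intracellular lipid
inclusion, all catalysed by the biomass frozen at the end of growth).

The default parameter values shipped here are the published model constants
for this process; they are the single source of rate and yield constants
used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class GrowthParameters:
    """Kinetic constants of the dual-substrate Monod growth model.

    Attributes
    ----------
    mu_max : float
        Maximum specific growth rate (1/h).
    K_gluc : float
        Glucose half-saturation constant (g/L).
    K_nano3 : float
        Sodium-nitrate half-saturation constant (g/L).
    Y_x_gluc : float
        Biomass yield from glucose (g/g).
    Y_x_nano3 : float
        Biomass yield from NaNO3 (g/g).

    The maximum specific consumption rates are derived, not stored:
    ``q_max_gluc = mu_max / Y_x_gluc`` and ``q_max_nano3 = mu_max / Y_x_nano3``.
    """

    mu_max: float = 0.11
    K_gluc: float = 1.0
    K_nano3: float = 0.01
    Y_x_gluc: float = 0.17
    Y_x_nano3: float = 1.7

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self)])

    @property
    def q_max_gluc(self) -> float:
        """Maximum specific glucose consumption rate (g/g/h)."""
        return self.mu_max / self.Y_x_gluc

    @property
    def q_max_nano3(self) -> float:
        """Maximum specific NaNO3 consumption rate (g/g/h)."""
        return self.mu_max / self.Y_x_nano3

    def replace(self, **kwargs) -> "GrowthParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ProductionParameters:
    """Kinetic constants of the production-phase model.

    Hydrolysis of triglyceride oil into free fatty acids follows
    Michaelis-Menten kinetics with competitive product inhibition by fatty
    acids; MEL formation and intracellular lipid inclusion are simple
    Michaelis-Menten terms in the fatty-acid concentration.
    """

    q_max_hyd: float = 0.1       # g_oil/g_x/h
    K_m_hyd: float = 5.0         # g/L
    K_i_hyd: float = 20.0        # g/L, fatty-acid inhibition of the lipase
    Y_fa_oil: float = 0.957      # g FA released per g oil hydrolysed
    q_max_mel: float = 0.02      # g_MEL/g_x/h
    K_m_mel: float = 5.0         # g/L
    Y_fa_mel: float = 1.667      # g FA consumed per g MEL formed
    q_max_incl: float = 0.07     # g FA/g_x/h drawn into lipid inclusions
    K_m_incl: float = 1.0        # g/L
    Y_x_free_incl: float = 0.203  # g lipid-free biomass converted per g inclusion flux
    Y_fa_incl: float = 1.128     # g FA per g inclusion-biomass formed

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self)])

    def replace(self, **kwargs) -> "ProductionParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ExponentialFeedSpec:
    """Open-loop exponential medium feed holding growth at ``mu_set``.

    The volumetric feed rate is

        F_in(t) = (V0 * cx0) * mu_set / (Y_x_gluc_feed * (c_gluc_feed - c_gluc))
                  * exp(mu_set * (t - t_start))

    for t in [t_start, t_end] and zero outside.  The glucose concentration
    in the denominator defaults to a constant 0 g/L (substrate-limited
    feeding), keeping the feed law open-loop.

    When ``delivered_volume_L`` is set, the exponential profile is rescaled
    by a constant factor so its integral over the feed window equals that
    volume — the pump-calibration case where the delivered feed total is
    known from the balance while the profile shape follows the feed law.
    """

    t_start: float
    t_end: float
    mu_set: float
    V0: float                  # L, broth volume at feed start
    cx0: float                 # g/L, biomass assumed at feed start
    Y_x_gluc_feed: float = 0.25
    c_gluc_feed: float = 300.0  # g/L
    c_nano3_feed: float = 30.0  # g/L
    feed_density: float = 1.15  # g/mL, concentrated glucose/nitrate solution
    c_gluc_broth: float = 0.0   # g/L assumed in the feed-law denominator
    delivered_volume_L: float | None = None  # rescale profile to this total

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ValueError("feed t_end must exceed t_start")
        _require_positive(self, ["mu_set", "V0", "cx0", "Y_x_gluc_feed",
                                 "c_gluc_feed", "feed_density"])
        if self.c_gluc_broth >= self.c_gluc_feed:
            raise ValueError("broth glucose must stay below feed glucose")


@dataclass(frozen=True)
class GrowthState:
    """Instantaneous state of the growth-phase model."""

    t: float        # h
    V_L: float      # L
    c_x: float      # g/L dry biomass
    c_gluc: float   # g/L
    c_nano3: float  # g/L

    def __post_init__(self):
        if not self.V_L > 0:
            raise ValueError("V_L must be > 0")
        for name in ("c_x", "c_gluc", "c_nano3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ProductionState:
    """Instantaneous state of the production-phase model.

    ``c_x_growth`` is the biomass concentration frozen at the end of the
    growth phase; it is the catalytic biomass driving every reaction flux.
    Measurable dry biomass is ``c_x_free + c_x_incl``.
    """

    t: float
    V_L: float
    c_x_free: float   # lipid-free biomass, g/L
    c_x_incl: float   # biomass with lipid inclusions, g/L
    c_oil: float      # triglyceride, g/L
    c_fa: float       # free fatty acids, g/L
    c_mel: float      # MEL, g/L
    c_x_growth: float  # frozen catalytic biomass, g/L

    def __post_init__(self):
        if not self.V_L > 0:
            raise ValueError("V_L must be > 0")
        for name in ("c_x_free", "c_x_incl", "c_oil", "c_fa", "c_mel", "c_x_growth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def c_x_total(self) -> float:
        return self.c_x_free + self.c_x_incl
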