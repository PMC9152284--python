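"""Elemental and stoichiometric balances around the fermentation medium.

Covers the nitrogen ceiling of the 3 g/L NaNO3 mineral medium (how much
lipid-free biomass the nitrogen supply permits), the carbon balance of the
30 g/L glucose batch, molar biomass formulas from CHN mass fractions, and
the triolein hydrolysis yield that fixes the fatty-acid-per-oil constant
of the production model.
"""

from __future__ import annotations

from dataclasses import dataclass

ATOMIC_MASS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
}

#: elemental formulas of the compounds the balances use
FORMULAS = {
    "NaNO3": {"Na": 1, "N": 1, "O": 3},
    "glucose": {"C": 6, "H": 12, "O": 6},
    "triolein": {"C": 57, "H": 104, "O": 6},
    "oleic_acid": {"C": 18, "H": 34, "O": 2},
    "glycerol": {"C": 3, "H": 8, "O": 3},
    "water": {"H": 2, "O": 1},
}

__all__ = [
    "BiomassComposition", "GROWTH_COMPOSITION", "PRODUCTION_COMPOSITION",
    "molar_mass", "element_mass_fraction", "nitrogen_balance",
    "carbon_balance", "molar_formula", "triolein_hydrolysis_yield",
]


@dataclass(frozen=True)
class BiomassComposition:
    """CHN mass fractions of dry biomass in g per 100 g (rest treated as O)."""

    w_C: float
    w_H: float
    w_N: float
    w_other: float
    label: str = "growth"

    def __post_init__(self):
        for name in ("w_C", "w_H", "w_N", "w_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = self.w_C + self.w_H + self.w_N + self.w_other
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"mass fractions sum to {total}, expected 100 +- 0.5")


#: average measured compositions of M. aphidis dry biomass
GROWTH_COMPOSITION = BiomassComposition(48.5, 7.1, 6.2, 38.1, label="growth")
PRODUCTION_COMPOSITION = BiomassComposition(62.2, 9.2, 1.3, 27.3, label="production")


def molar_mass(compound: str) -> float:
    """Molar mass (g/mol) of a supported compound."""
    try:
        formula = FORMULAS[compound]
    except KeyError:
        raise ValueError(f"unsupported compound {compound!r}") from None
    return sum(n * ATOMIC_MASS[el] for el, n in formula.items())


def element_mass_fraction(compound: str, element: str) -> float:
    """Mass fraction of an element in a compound (0 if absent)."""
    if element not in ATOMIC_MASS:
        raise ValueError(f"unsupported element {element!r}")
    formula = FORMULAS.get(compound)
    if formula is None:
        raise ValueError(f"unsupported compound {compound!r}")
    n = formula.get(element, 0)
    return n * ATOMIC_MASS[element] / molar_mass(compound)


def nitrogen_balance(c_nano3: float, biomass_N_fraction: float):
    """Nitrogen ceiling of the medium.

    Parameters are the NaNO3 concentration (g/L) and the nitrogen mass
    fraction of lipid-free biomass (g/g).  Returns (available elemental N
    in g/L, maximum biomass in g/L, maximum biomass yield from NaNO3 in
    g/g).
    """
    if c_nano3 <= 0:
        raise ValueError("c_nano3 must be > 0")
    if biomass_N_fraction <= 0:
        raise ValueError("biomass nitrogen fraction must be > 0")
    f_n = element_mass_fraction("NaNO3", "N")
    available_N = c_nano3 * f_n
    max_biomass = available_N / biomass_N_fraction
    max_yield = max_biomass / c_nano3
    return available_N, max_biomass, max_yield


def carbon_balance(c_gluc: float, c_x: float, comp: BiomassComposition):
    """Carbon budget of the batch growth medium.

    Returns (available elemental C in g/L from glucose, elemental C bound
    in the biomass in g/L, fraction of the available carbon recovered in
    biomass).
    """
    if c_gluc < 0 or c_x < 0:
        raise ValueError("concentrations must be >= 0")
    available_C = element_mass_fraction("glucose", "C") * c_gluc
    biomass_C = c_x * comp.w_C / 100.0
    if available_C <= 0:
        raise ValueError("no glucose: carbon fraction undefined")
    return available_C, biomass_C, biomass_C / available_C


def molar_formula(comp: BiomassComposition) -> tuple[float, float, float]:
    """Normalized molar biomass formula CH_a N_b O_c from mass fractions.

    The non-CHN remainder is treated as oxygen.  Returns (a, b, c).
    """
    if comp.w_C <= 0:
        raise ValueError("carbon fraction must be > 0 for a molar formula")
    n_c = comp.w_C / ATOMIC_MASS["C"]
    a = (comp.w_H / ATOMIC_MASS["H"]) / n_c
    b = (comp.w_N / ATOMIC_MASS["N"]) / n_c
    c = (comp.w_other / ATOMIC_MASS["O"]) / n_c
    return a, b, c


def triolein_hydrolysis_yield() -> float:
    """Mass of oleic acid released per mass of triolein hydrolysed.

    Triolein + 3 H2O -> 3 oleic acid + glycerol, so the yield is
    3 M(oleic acid) / M(triolein) ~= 0.957 g/g; the remaining mass (plus
    the water taken up) leaves as glycerol.
    """
    return 3.0 * molar_mass("oleic_acid") / molar_mass("triolein")
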