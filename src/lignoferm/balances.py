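"""Carbon and available-electron recovery balances.

A fermentation balance closes when the carbon (and the available electrons)
of the consumed substrate are found again in the measured products plus
cells.  Electrons are counted as degree of reduction relative to the
CO2/H2O/NH3 reference state:

    gamma = 4*C + H - 2*O - 3*N   (electron equivalents per mol)

so glucose carries 24, ethanol 12, acetate 8, lactate 12, H2 2 and CO2 0.
Cell material is interconverted with dry weight through the empirical
per-carbon formula CH2N0.25O0.5 (25.53 g per C-mol, gamma 4.25 with NH3 as
nitrogen source).  Recoveries near 100% indicate that no major product was
missed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .composition import Compound, SugarEquivalents, get_compound
from .stoichiometry import ProductProfile

__all__ = [
    "BalanceResult",
    "CellBiomass",
    "UndefinedRecoveryError",
    "degree_of_reduction",
    "carbon_recovery",
    "electron_recovery",
    "carbon_to_dry_weight",
    "dry_weight_to_carbon",
    "BIOMASS_CARBON_MOLAR_MASS",
    "GAMMA_BIOMASS",
]

BIOMASS_CARBON_MOLAR_MASS = 25.53  # g per C-mol of CH2N0.25O0.5


class UndefinedRecoveryError(ValueError):
    """Recovery requested against zero consumed substrate."""


def degree_of_reduction(compound: Compound | str) -> float:
    """Available electron equivalents per mol: 4C + H - 2O - 3N."""
    if isinstance(compound, str):
        compound = get_compound(compound)
    return 4.0 * compound.carbon + compound.hydrogen - 2.0 * compound.oxygen - 3.0 * compound.nitrogen


GAMMA_BIOMASS = degree_of_reduction("biomass")  # 4.25 per C-mol


@dataclass(frozen=True)
class CellBiomass:
    """Cell material expressed both as carbon (mM) and dry weight (g/l)."""

    carbon: float  # mM carbon
    dry_weight: float  # g/l

    def __post_init__(self) -> None:
        if self.carbon < 0 or self.dry_weight < 0:
            raise ValueError("cell biomass cannot be negative")

    @classmethod
    def from_carbon(cls, carbon: float, c_molar_mass: float = BIOMASS_CARBON_MOLAR_MASS) -> "CellBiomass":
        return cls(carbon=carbon, dry_weight=carbon_to_dry_weight(carbon, c_molar_mass))

    @classmethod
    def from_dry_weight(cls, dry_weight: float, c_molar_mass: float = BIOMASS_CARBON_MOLAR_MASS) -> "CellBiomass":
        return cls(carbon=dry_weight_to_carbon(dry_weight, c_molar_mass), dry_weight=dry_weight)


def carbon_to_dry_weight(carbon: float, c_molar_mass: float = BIOMASS_CARBON_MOLAR_MASS) -> float:
    """Cell dry weight (g/l) equivalent to *carbon* mM of cell carbon."""
    if carbon < 0 or not math.isfinite(carbon):
        raise ValueError(f"cell carbon must be finite and non-negative, got {carbon}")
    return carbon * c_molar_mass / 1000.0


def dry_weight_to_carbon(dry_weight: float, c_molar_mass: float = BIOMASS_CARBON_MOLAR_MASS) -> float:
    """Cell carbon (mM) in *dry_weight* g/l of cells."""
    if dry_weight < 0 or not math.isfinite(dry_weight):
        raise ValueError(f"dry weight must be finite and non-negative, got {dry_weight}")
    return dry_weight / c_molar_mass * 1000.0


@dataclass(frozen=True)
class BalanceResult:
    """Outcome of a recovery balance.

    ``substrate_total`` and ``product_total`` share one unit (mM carbon for
    the carbon balance, electron meq/l for the electron balance) and
    ``breakdown`` itemises each product's contribution.
    """

    substrate_total: float
    product_total: float
    recovery: float  # %
    breakdown: Mapping[str, float]


_SUGAR_COMPOUNDS = {
    "glucose": "glucose",
    "galactose": "galactose",
    "mannose": "mannose",
    "xylose": "xylose",
    "arabinose": "arabinose",
}


def _substrate_weight_sum(consumed: SugarEquivalents, weight) -> float:
    return sum(
        conc * weight(get_compound(compound))
        for sugar, compound in _SUGAR_COMPOUNDS.items()
        for conc in [getattr(consumed, sugar)]
    )


def _balance(
    consumed: SugarEquivalents,
    profile: ProductProfile,
    cells: CellBiomass | None,
    weight,
    gamma_biomass_weight: float,
) -> BalanceResult:
    substrate = _substrate_weight_sum(consumed, weight)
    breakdown = {
        "ethanol": profile.ethanol * weight(get_compound("ethanol")),
        "acetate": profile.acetate * weight(get_compound("acetate")),
        "lactate": profile.lactate * weight(get_compound("lactate")),
    }
    if profile.co2 is not None:
        breakdown["co2"] = profile.co2 * weight(get_compound("co2"))
    if profile.h2 is not None:
        breakdown["h2"] = profile.h2 * weight(get_compound("h2"))
    if cells is not None:
        breakdown["cells"] = cells.carbon * gamma_biomass_weight
    product_total = sum(breakdown.values())
    if substrate <= 0:
        if product_total > 0:
            raise UndefinedRecoveryError("products measured but no substrate consumed")
        raise UndefinedRecoveryError("no substrate consumed")
    return BalanceResult(
        substrate_total=substrate,
        product_total=product_total,
        recovery=product_total / substrate * 100.0,
        breakdown=breakdown,
    )


def carbon_recovery(
    consumed: SugarEquivalents,
    profile: ProductProfile,
    cells: CellBiomass | None = None,
) -> BalanceResult:
    """Percent of consumed substrate carbon recovered in products + cells.

    Substrate carbon is 6 mM-C per mM hexose equivalent and 5 per pentose;
    products contribute 2 per ethanol and acetate, 3 per lactate, 1 per CO2
    and 1 per mM of cell carbon.
    """
    return _balance(consumed, profile, cells, weight=lambda c: c.carbon, gamma_biomass_weight=1.0)


def electron_recovery(
    consumed: SugarEquivalents,
    profile: ProductProfile,
    cells: CellBiomass | None = None,
    gamma_biomass: float = GAMMA_BIOMASS,
) -> BalanceResult:
    """Percent of consumed available electrons recovered in products + cells.

    Weights are degrees of reduction: hexoses 24, pentoses 20, ethanol and
    lactate 12, acetate 8, H2 2, CO2 0 and cell carbon *gamma_biomass*
    (default 4.25, the NH3-referenced value for CH2N0.25O0.5).
    """
    return _balance(
        consumed, profile, cells, weight=degree_of_reduction, gamma_biomass_weight=gamma_biomass
    )
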