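"""Substrate composition and sugar-equivalent arithmetic.

Pretreated lignocellulose is described by mass fractions of its structural
polysaccharides (glucan, xylan, galactan, arabinan, mannan) plus lignin and
ash.  Full hydrolysis of a loading of such material releases monosaccharides
whose molar amounts follow from the *anhydro* monomer masses: a hexosan unit
weighs 162.14 g/mol (hexose minus water) and a pentosan unit 132.11 g/mol.
These anhydro-sugar equivalents are the molar currency that the capacity,
utilization and balance calculations downstream are expressed in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "Compound",
    "BiomassComposition",
    "SugarEquivalents",
    "UnknownCompoundError",
    "CompositionError",
    "load_registry",
    "get_compound",
    "molar_concentration",
    "sugar_equivalents",
    "consumed_equivalents_from_weight_loss",
    "read_composition_table",
    "ANHYDROHEXOSE_MASS",
    "ANHYDROPENTOSE_MASS",
    "HEXOSANS",
    "PENTOSANS",
]

# IUPAC 2021 standard atomic weights, rounded
_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


class UnknownCompoundError(KeyError):
    """Requested compound is not in the registry."""


class CompositionError(ValueError):
    """A biomass composition violates its validity constraints."""


@dataclass(frozen=True)
class Compound:
    """An elemental formula with a molar mass.

    Atom counts are per molecule; fractional counts are permitted only for
    per-carbon biomass pseudo-formulas such as CH2N0.25O0.5.
    """

    name: str
    carbon: float
    hydrogen: float
    oxygen: float
    nitrogen: float = 0.0
    molar_mass: float = 0.0

    def __post_init__(self) -> None:
        for atom in ("carbon", "hydrogen", "oxygen", "nitrogen"):
            if getattr(self, atom) < 0:
                raise ValueError(f"{self.name}: negative {atom} count")
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be positive")
        if self._is_integer_formula() and abs(self.formula_mass - self.molar_mass) > 0.5:
            raise ValueError(
                f"{self.name}: molar_mass {self.molar_mass} disagrees with "
                f"formula mass {self.formula_mass:.3f} by more than 0.5 g/mol"
            )

    def _is_integer_formula(self) -> bool:
        return all(
            float(getattr(self, a)).is_integer()
            for a in ("carbon", "hydrogen", "oxygen", "nitrogen")
        )

    @property
    def formula_mass(self) -> float:
        """Molar mass recomputed from atomic composition (g/mol)."""
        return (
            self.carbon * _ATOMIC_MASS["C"]
            + self.hydrogen * _ATOMIC_MASS["H"]
            + self.oxygen * _ATOMIC_MASS["O"]
            + self.nitrogen * _ATOMIC_MASS["N"]
        )


def load_registry(path: str | Path | None = None) -> dict[str, Compound]:
    """Load a compound registry from YAML (``name: {carbon, ..., molar_mass}``).

    Without *path* the registry shipped with the package is used.
    """
    if path is None:
        text = resources.files("lignoferm.data").joinpath("compounds.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {name: Compound(name=name, **entry) for name, entry in raw.items()}


REGISTRY: dict[str, Compound] = load_registry()

ANHYDROHEXOSE_MASS = REGISTRY["anhydrohexose"].molar_mass  # 162.14 g/mol
ANHYDROPENTOSE_MASS = REGISTRY["anhydropentose"].molar_mass  # 132.11 g/mol

# polymer -> monosaccharide released on hydrolysis
HEXOSANS: Mapping[str, str] = {"glucan": "glucose", "galactan": "galactose", "mannan": "mannose"}
PENTOSANS: Mapping[str, str] = {"xylan": "xylose", "arabinan": "arabinose"}
_NON_CARBOHYDRATE = {"lignin_acid_soluble", "lignin_acid_insoluble", "ash", "lignin_ash"}


def get_compound(name: str, registry: Mapping[str, Compound] | None = None) -> Compound:
    reg = REGISTRY if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        raise UnknownCompoundError(name) from None


@dataclass(frozen=True)
class SugarEquivalents:
    """Monosaccharide molar concentrations (mM) released by full hydrolysis."""

    glucose: float = 0.0
    galactose: float = 0.0
    mannose: float = 0.0
    xylose: float = 0.0
    arabinose: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"negative {f.name} equivalent")

    @property
    def hexoses(self) -> float:
        """Total C6 sugars (mM)."""
        return self.glucose + self.galactose + self.mannose

    @property
    def pentoses(self) -> float:
        """Total C5 sugars (mM)."""
        return self.xylose + self.arabinose

    @property
    def total(self) -> float:
        return self.hexoses + self.pentoses

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def scaled(self, factor: float) -> "SugarEquivalents":
        return SugarEquivalents(**{k: v * factor for k, v in self.as_dict().items()})

    def __add__(self, other: "SugarEquivalents") -> "SugarEquivalents":
        a, b = self.as_dict(), other.as_dict()
        return SugarEquivalents(**{k: a[k] + b[k] for k in a})


@dataclass(frozen=True)
class BiomassComposition:
    """Mass-fraction description of a (pretreated) lignocellulosic substrate.

    ``fractions`` maps polymer names (glucan, xylan, galactan, arabinan,
    mannan) to dimensionless mass fractions of dry matter.  Lignin and ash
    fractions are carried for bookkeeping only; they do not contribute
    fermentable sugar.
    """

    fractions: Mapping[str, float]
    lignin_acid_soluble: float = 0.0
    lignin_acid_insoluble: float = 0.0
    ash: float = 0.0

    _SUM_TOLERANCE = 0.02

    def __post_init__(self) -> None:
        known = set(HEXOSANS) | set(PENTOSANS)
        for name, frac in self.fractions.items():
            if name not in known:
                raise CompositionError(f"unknown polymer {name!r}")
            if not 0.0 <= frac <= 1.0:
                raise CompositionError(f"fraction of {name} out of [0, 1]: {frac}")
        for name in ("lignin_acid_soluble", "lignin_acid_insoluble", "ash"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise CompositionError(f"{name} out of [0, 1]")
        total = (
            sum(self.fractions.values())
            + self.lignin_acid_soluble
            + self.lignin_acid_insoluble
            + self.ash
        )
        if total > 1.0 + self._SUM_TOLERANCE:
            raise CompositionError(f"mass fractions sum to {total:.3f} > 1")

    def fraction(self, polymer: str) -> float:
        return float(self.fractions.get(polymer, 0.0))


def molar_concentration(
    mass: float, compound: Compound | str, registry: Mapping[str, Compound] | None = None
) -> float:
    """Convert a mass concentration (g/l) to a molar one (mM).

    >>> round(molar_concentration(10.0, "glucose"), 2)
    55.51
    """
    if isinstance(compound, str):
        compound = get_compound(compound, registry)
    if mass < 0 or not math.isfinite(mass):
        raise ValueError(f"mass must be finite and non-negative, got {mass}")
    return mass / compound.molar_mass * 1000.0


def sugar_equivalents(composition: BiomassComposition, loading: float) -> SugarEquivalents:
    """Monosaccharide equivalents (mM) in *loading* g/l of dry substrate.

    Hexosans convert through the anhydrohexose mass (162.14 g/mol),
    pentosans through the anhydropentose mass (132.11 g/mol); each
    equivalent is ``loading x fraction / anhydro_mass x 1000``.
    """
    if loading < 0 or not math.isfinite(loading):
        raise ValueError(f"loading must be finite and non-negative, got {loading}")
    values: dict[str, float] = {}
    for polymer, sugar in HEXOSANS.items():
        values[sugar] = loading * composition.fraction(polymer) / ANHYDROHEXOSE_MASS * 1000.0
    for polymer, sugar in PENTOSANS.items():
        values[sugar] = loading * composition.fraction(polymer) / ANHYDROPENTOSE_MASS * 1000.0
    return SugarEquivalents(**values)


def consumed_equivalents_from_weight_loss(weight_loss: float) -> float:
    """Anhydroglucose equivalents (mM) in a measured substrate weight loss (g/l).

    Appropriate when the weight loss of an insoluble substrate can be
    attributed to cellulose consumption (washed substrates with no residual
    xylan).
    """
    if weight_loss < 0 or not math.isfinite(weight_loss):
        raise ValueError(f"weight loss must be finite and non-negative, got {weight_loss}")
    return weight_loss / ANHYDROHEXOSE_MASS * 1000.0


def read_composition_table(path: str | Path) -> dict[str, BiomassComposition]:
    """Read substrate compositions from a delimited table.

    Expected columns: ``substrate``, ``polymer`` and either ``fraction``
    (0-1) or ``percent`` (0-100, divided by 100 at parse time).  Lignin and
    ash rows are recognised by polymer name and stored on the side.
    """
    df = pd.read_csv(path)
    required = {"substrate", "polymer"}
    if not required.issubset(df.columns):
        raise CompositionError(f"composition table needs columns {sorted(required)}")
    if "fraction" in df.columns:
        values = df["fraction"].astype(float)
    elif "percent" in df.columns:
        values = df["percent"].astype(float) / 100.0
    else:
        raise CompositionError("composition table needs a 'fraction' or 'percent' column")

    out: dict[str, BiomassComposition] = {}
    for substrate, group in df.assign(_frac=values).groupby("substrate", sort=False):
        polymers: dict[str, float] = {}
        extras = {"lignin_acid_soluble": 0.0, "lignin_acid_insoluble": 0.0, "ash": 0.0}
        for _, row in group.iterrows():
            name = str(row["polymer"]).strip()
            if name in _NON_CARBOHYDRATE:
                key = "ash" if name in ("ash", "lignin_ash") else name
                extras[key] += float(row["_frac"])
            else:
                polymers[name] = polymers.get(name, 0.0) + float(row["_frac"])
        out[str(substrate)] = BiomassComposition(fractions=polymers, **extras)
    return out
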