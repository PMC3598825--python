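"""Product-yield stoichiometry for mixed-acid fermentations.

Anaerobic thermophiles ferment hexoses to at most 2 mol of C2/C3 organic
products (ethanol, acetate, lactate) per mol sugar, and pentoses to 1.67 mol
per mol — the pyruvate-equivalent ceiling of glycolysis and the pentose
phosphate route.  Comparing the measured organic product pool against that
theoretical capacity gives the fraction of fermentable carbohydrate actually
utilized, and the mole fractions within the pool characterise a strain's
product split (e.g. how ethanologenic a culture is).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .composition import SugarEquivalents
from .display import fmt

__all__ = [
    "ProductProfile",
    "YieldConstants",
    "ProductRatio",
    "UndefinedStatisticError",
    "product_capacity",
    "utilization_percent",
    "mole_percents",
    "ethanol_mole_percent",
    "normalized_ratio",
    "fold_change",
]


class UndefinedStatisticError(ValueError):
    """A ratio or percentage is requested with a zero denominator."""


@dataclass(frozen=True)
class ProductProfile:
    """End-point fermentation product concentrations (mM).

    Ethanol, acetate and lactate form the organic pool; CO2 and H2 are
    optional gas measurements used only by the recovery balances.
    """

    ethanol: float
    acetate: float
    lactate: float
    co2: float | None = None
    h2: float | None = None

    def __post_init__(self) -> None:
        for name in ("ethanol", "acetate", "lactate"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        for name in ("co2", "h2"):
            v = getattr(self, name)
            if v is not None and (v < 0 or not math.isfinite(v)):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    @property
    def total_organic(self) -> float:
        """Ethanol + acetate + lactate (mM)."""
        return self.ethanol + self.acetate + self.lactate

    def scaled(self, factor: float) -> "ProductProfile":
        return replace(
            self,
            ethanol=self.ethanol * factor,
            acetate=self.acetate * factor,
            lactate=self.lactate * factor,
            co2=None if self.co2 is None else self.co2 * factor,
            h2=None if self.h2 is None else self.h2 * factor,
        )


@dataclass(frozen=True)
class YieldConstants:
    """Theoretical organic-product yield per mol of sugar.

    2.0 mol per mol hexose and 1.67 mol per mol pentose (the rounded 5/3
    conventionally printed in fermentation balances; kept at 1.67 so that
    reported capacities reproduce published tables digit for digit).
    """

    hexose_factor: float = 2.0
    pentose_factor: float = 1.67

    def __post_init__(self) -> None:
        if self.hexose_factor <= 0 or self.pentose_factor <= 0:
            raise ValueError("yield factors must be positive")


def product_capacity(
    sugars: SugarEquivalents, constants: YieldConstants = YieldConstants()
) -> float:
    """Maximum ethanol+acetate+lactate (mM) formable from *sugars*."""
    return constants.hexose_factor * sugars.hexoses + constants.pentose_factor * sugars.pentoses


def utilization_percent(profile: ProductProfile, capacity: float) -> float:
    """Measured organic pool as a percentage of theoretical capacity."""
    if capacity <= 0:
        raise UndefinedStatisticError("utilization undefined for zero capacity")
    return profile.total_organic / capacity * 100.0


def mole_percents(profile: ProductProfile) -> tuple[float, float, float]:
    """(ethanol, acetate, lactate) mole percentages of the organic pool."""
    total = profile.total_organic
    if total <= 0:
        raise UndefinedStatisticError("mole fractions undefined for an empty product pool")
    return (
        profile.ethanol / total * 100.0,
        profile.acetate / total * 100.0,
        profile.lactate / total * 100.0,
    )


def ethanol_mole_percent(profile: ProductProfile) -> float:
    """Ethanol as mol% of ethanol+acetate+lactate."""
    return mole_percents(profile)[0]


@dataclass(frozen=True)
class ProductRatio:
    """Ethanol:acetate:lactate ratio normalized to its basis component.

    Normally the basis is ethanol and ``values`` is (1, acetate/ethanol,
    lactate/ethanol).  When ethanol is zero the ratio is re-based on the
    largest component instead and ``basis`` records which one.
    """

    values: tuple[float, float, float]
    basis: str = "ethanol"

    def __str__(self) -> str:  # "1 : 2.3 : 1.3", one decimal, half-up
        head, *rest = self.values
        parts = ["1" if head == 1.0 else fmt(head)] + [fmt(v) for v in rest]
        return " : ".join(parts)


def normalized_ratio(profile: ProductProfile) -> ProductRatio:
    """Ethanol:acetate:lactate normalized to ethanol = 1.

    Falls back to normalizing by the largest component (flagged via
    ``basis``) when no ethanol was formed.
    """
    if profile.ethanol > 0:
        e = profile.ethanol
        return ProductRatio((1.0, profile.acetate / e, profile.lactate / e))
    pool = {"ethanol": profile.ethanol, "acetate": profile.acetate, "lactate": profile.lactate}
    basis = max(pool, key=pool.get)  # type: ignore[arg-type]
    if pool[basis] <= 0:
        raise UndefinedStatisticError("ratio undefined for an empty product pool")
    d = pool[basis]
    return ProductRatio(
        (profile.ethanol / d, profile.acetate / d, profile.lactate / d), basis=basis
    )


def fold_change(test: ProductProfile, reference: ProductProfile, field: str = "ethanol") -> float:
    """Ratio of one product concentration between two cultures.

    Typically used for the ethanol increase of a cellulolytic/ethanologenic
    co-culture over the cellulolytic monoculture.
    """
    if field not in ("ethanol", "acetate", "lactate", "co2", "h2"):
        raise ValueError(f"unknown product field {field!r}")
    ref = getattr(reference, field)
    if ref is None or ref <= 0:
        raise UndefinedStatisticError(f"fold change undefined: reference {field} is zero")
    val = getattr(test, field)
    if val is None:
        raise UndefinedStatisticError(f"test profile lacks {field}")
    return val / ref
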