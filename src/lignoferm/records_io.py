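"""Reading, validating and summarizing fermentation experiment records.

One CSV row is one replicate of one condition (culture x substrate x
loading).  Concentrations are always mM; substrate loadings and cell dry
weight are g/l.  Expected header::

    id,strains,substrate,loading_g_l,ph_mode,substrate_final_g_l,
    ethanol_mM,acetate_mM,lactate_mM,co2_mM,h2_mM,cdw_g_l,replicate

``strains`` joins culture members with '+' (one name = monoculture, two =
dual co-culture).  Gas and cell columns may be left empty; summaries then
omit the recovery balances rather than treating them as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import balances
from .balances import CellBiomass, carbon_recovery, electron_recovery
from .composition import (
    SugarEquivalents,
    consumed_equivalents_from_weight_loss,
    get_compound,
    molar_concentration,
)
from .display import fmt
from .stoichiometry import (
    ProductProfile,
    UndefinedStatisticError,
    ethanol_mole_percent,
    normalized_ratio,
    utilization_percent,
)

__all__ = [
    "ExperimentRecord",
    "TimeCourse",
    "RecordValidationError",
    "PH_MODES",
    "SCHEMA_COLUMNS",
    "read_experiments",
    "write_experiments",
    "group_records",
    "consumed_equivalents_for",
    "summarize",
    "write_report",
]

PH_MODES = ("uncontrolled-flask", "buffered-flask", "ph-controlled-fermentor")

SCHEMA_COLUMNS = (
    "id",
    "strains",
    "substrate",
    "loading_g_l",
    "ph_mode",
    "substrate_final_g_l",
    "ethanol_mM",
    "acetate_mM",
    "lactate_mM",
    "co2_mM",
    "h2_mM",
    "cdw_g_l",
    "replicate",
)

# monosaccharides that may appear directly as defined-sugar substrates
_SOLUBLE_SUGARS = ("glucose", "galactose", "mannose", "xylose", "arabinose")


class RecordValidationError(ValueError):
    """One or more rows of an experiment file failed validation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class ExperimentRecord:
    """A single fermentation replicate: metadata, consumption and products."""

    id: str
    strains: tuple[str, ...]
    substrate: str
    loading: float  # g/l dry mass (initial)
    ph_mode: str
    profile: ProductProfile
    substrate_final: float | None = None  # g/l
    cells: CellBiomass | None = None
    replicate: int = 1
    consumed_equivalents: SugarEquivalents | None = None

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValueError(f"record {self.id}: culture must name at least one strain")
        if self.loading <= 0:
            raise ValueError(f"record {self.id}: loading must be positive")
        if self.ph_mode not in PH_MODES:
            raise ValueError(f"record {self.id}: unknown ph_mode {self.ph_mode!r}")
        if self.substrate_final is not None:
            if self.substrate_final < 0:
                raise ValueError(f"record {self.id}: negative final substrate")
            if self.substrate_final > self.loading * (1 + 1e-9):
                raise ValueError(
                    f"record {self.id}: final substrate {self.substrate_final} "
                    f"exceeds loading {self.loading}"
                )

    @property
    def is_coculture(self) -> bool:
        return len(self.strains) > 1

    @property
    def weight_loss(self) -> float | None:
        if self.substrate_final is None:
            return None
        return self.loading - self.substrate_final


@dataclass(frozen=True)
class TimeCourse:
    """Product concentrations sampled along a fermentation run."""

    times: np.ndarray  # h, strictly increasing
    ethanol: np.ndarray
    acetate: np.ndarray
    lactate: np.ndarray
    substrate: np.ndarray  # g/l remaining
    od600: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("ethanol", "acetate", "lactate", "substrate"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} series length differs from times")
        if self.od600 is not None and len(self.od600) != n:
            raise ValueError("od600 series length differs from times")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("ethanol", "acetate", "lactate", "substrate"):
            if np.any(np.asarray(getattr(self, name)) < -1e-12):
                raise ValueError(f"negative concentration in {name} series")

    def profile_at(self, index: int) -> ProductProfile:
        return ProductProfile(
            ethanol=float(self.ethanol[index]),
            acetate=float(self.acetate[index]),
            lactate=float(self.lactate[index]),
        )


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_experiments(path: str | Path) -> list[ExperimentRecord]:
    """Read and validate an experiment CSV; errors carry row numbers.

    All rows are checked before raising, so a single pass reports every
    problem in the file.
    """
    df = pd.read_csv(path)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError([f"missing column(s): {', '.join(missing)}"])

    records: list[ExperimentRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            profile = ProductProfile(
                ethanol=float(row["ethanol_mM"]),
                acetate=float(row["acetate_mM"]),
                lactate=float(row["lactate_mM"]),
                co2=_opt_float(row["co2_mM"]),
                h2=_opt_float(row["h2_mM"]),
            )
            cdw = _opt_float(row["cdw_g_l"])
            cells = None if cdw is None else CellBiomass.from_dry_weight(cdw)
            records.append(
                ExperimentRecord(
                    id=str(row["id"]),
                    strains=tuple(s.strip() for s in str(row["strains"]).split("+") if s.strip()),
                    substrate=str(row["substrate"]).strip(),
                    loading=float(row["loading_g_l"]),
                    ph_mode=str(row["ph_mode"]).strip(),
                    profile=profile,
                    substrate_final=_opt_float(row["substrate_final_g_l"]),
                    cells=cells,
                    replicate=int(row["replicate"]),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise RecordValidationError(errors)
    return records


def write_experiments(records: Iterable[ExperimentRecord], path: str | Path) -> None:
    """Write records back out in the standard CSV schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "strains": "+".join(r.strains),
                "substrate": r.substrate,
                "loading_g_l": r.loading,
                "ph_mode": r.ph_mode,
                "substrate_final_g_l": r.substrate_final,
                "ethanol_mM": r.profile.ethanol,
                "acetate_mM": r.profile.acetate,
                "lactate_mM": r.profile.lactate,
                "co2_mM": r.profile.co2,
                "h2_mM": r.profile.h2,
                "cdw_g_l": None if r.cells is None else r.cells.dry_weight,
                "replicate": r.replicate,
            }
        )
    pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS)).to_csv(path, index=False)


def group_records(
    records: Iterable[ExperimentRecord],
) -> dict[tuple[tuple[str, ...], str, float, str], list[ExperimentRecord]]:
    """Group replicates by (culture, substrate, loading, ph_mode)."""
    groups: dict[tuple[tuple[str, ...], str, float, str], list[ExperimentRecord]] = {}
    for r in records:
        groups.setdefault((r.strains, r.substrate, r.loading, r.ph_mode), []).append(r)
    return groups


def consumed_equivalents_for(record: ExperimentRecord) -> SugarEquivalents | None:
    """Consumed sugar equivalents for a record, if derivable.

    Explicitly attached equivalents win.  Otherwise, for a defined soluble
    sugar the weight difference converts through that sugar's molar mass;
    for polymeric substrates the weight loss is attributed to cellulose and
    converts through the anhydroglucose mass.
    """
    if record.consumed_equivalents is not None:
        return record.consumed_equivalents
    loss = record.weight_loss
    if loss is None:
        return None
    name = record.substrate.lower()
    if name in _SOLUBLE_SUGARS:
        return SugarEquivalents(**{name: molar_concentration(loss, get_compound(name))})
    return SugarEquivalents(glucose=consumed_equivalents_from_weight_loss(loss))


def _mean_sd(values: list[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return mean, sd


def summarize(
    records: Iterable[ExperimentRecord],
    capacities: Mapping[str, float] | None = None,
    initial_equivalents: Mapping[str, float] | None = None,
    gamma_biomass: float = balances.GAMMA_BIOMASS,
) -> pd.DataFrame:
    """Per-condition summary: products, ratio, ethanol mol%, recoveries.

    Statistics are computed per replicate and then aggregated as mean and
    sample standard deviation.  *capacities* maps substrate name to the
    theoretical organic-product capacity (mM) for the utilization column;
    *initial_equivalents* maps substrate name to initial glucose
    equivalents (mM) for the percent-of-substrate-consumed column.
    Balance columns stay empty (NaN) when a group lacks the gas or cell
    measurements they need.
    """
    rows = []
    for (strains, substrate, loading, ph_mode), group in sorted(
        group_records(records).items(), key=lambda kv: (kv[0][1], kv[0][0], kv[0][2])
    ):
        per = {
            "ethanol": [r.profile.ethanol for r in group],
            "acetate": [r.profile.acetate for r in group],
            "lactate": [r.profile.lactate for r in group],
            "total": [r.profile.total_organic for r in group],
        }
        row: dict[str, object] = {
            "culture": "+".join(strains),
            "substrate": substrate,
            "loading_g_l": loading,
            "ph_mode": ph_mode,
            "n": len(group),
        }
        for name, values in per.items():
            mean, sd = _mean_sd(values)
            row[f"{name}_mM"], row[f"{name}_mM_sd"] = mean, sd

        try:
            molpct = [ethanol_mole_percent(r.profile) for r in group]
            row["ethanol_mol_pct"], row["ethanol_mol_pct_sd"] = _mean_sd(molpct)
        except UndefinedStatisticError:
            row["ethanol_mol_pct"] = row["ethanol_mol_pct_sd"] = None

        try:
            ratios = [normalized_ratio(r.profile).values for r in group]
            mean_ratio = tuple(float(np.mean(col)) for col in zip(*ratios))
            row["ratio"] = f"1 : {fmt(mean_ratio[1])} : {fmt(mean_ratio[2])}"
        except UndefinedStatisticError:
            row["ratio"] = None

        capacity = (capacities or {}).get(substrate)
        if capacity:
            util = [utilization_percent(r.profile, capacity) for r in group]
            row["utilization_pct"], row["utilization_pct_sd"] = _mean_sd(util)

        consumed = [consumed_equivalents_for(r) for r in group]
        if all(c is not None and c.total > 0 for c in consumed):
            cons_mM = [c.total for c in consumed]
            row["consumed_equiv_mM"], row["consumed_equiv_mM_sd"] = _mean_sd(cons_mM)
            init = (initial_equivalents or {}).get(substrate)
            if init:
                pct = [c.total / init * 100.0 for c in consumed]
                row["substrate_consumed_pct"], row["substrate_consumed_pct_sd"] = _mean_sd(pct)
            if all(r.profile.co2 is not None and r.cells is not None for r in group):
                crec = [
                    carbon_recovery(c, r.profile, r.cells).recovery
                    for c, r in zip(consumed, group)
                ]
                row["carbon_recovery_pct"], row["carbon_recovery_pct_sd"] = _mean_sd(crec)
            if all(r.profile.h2 is not None and r.cells is not None for r in group):
                erec = [
                    electron_recovery(c, r.profile, r.cells, gamma_biomass=gamma_biomass).recovery
                    for c, r in zip(consumed, group)
                ]
                row["electron_recovery_pct"], row["electron_recovery_pct_sd"] = _mean_sd(erec)
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(rows: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a summary table as CSV or a markdown pipe-table.

    Column order is preserved as produced by :func:`summarize`; CSV output
    round-trips through :func:`pandas.read_csv` at full stored precision.
    """
    if rows is None or len(rows) == 0:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    if format == "csv":
        rows.to_csv(path, index=False)
    elif format in ("markdown", "markdown-table"):
        cols = list(rows.columns)
        lines = ["| " + " | ".join(cols) + " |", "|" + "|".join(["---"] * len(cols)) + "|"]
        for _, row in rows.iterrows():
            cells = []
            for c in cols:
                v = row[c]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    cells.append("")
                elif isinstance(v, float):
                    cells.append(fmt(v, 1))
                else:
                    cells.append(str(v))
            lines.append("| " + " | ".join(cells) + " |")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
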