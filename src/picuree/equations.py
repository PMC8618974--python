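"""The ten predictive REE equations/formulae, backed by a versioned registry.

Seven are banded linear forms (intercept + coefficients on weight/height/age
per sex and half-open age band), two are discrete lookup tables keyed on
weight or height, and one is the VCO2-proportional estimator restricted to
mechanically ventilated patients.

A record is any mapping with the cohort variable-dictionary keys; missing
required inputs yield a flagged ``not_applicable`` result rather than an
error, so whole-cohort evaluation never raises on partial records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .calorimetry import gas_constants
from .errors import ConfigurationError, DomainError

__all__ = [
    "EQUATION_IDS",
    "EquationResult",
    "LookupTable",
    "EquationRegistry",
    "load_registry",
    "mehta_ree",
    "talbot_lookup",
    "evaluate_equation",
    "evaluate_all",
]

LINEAR_IDS = (
    "harris_benedict",
    "harris_benedict_infants",
    "schofield_w",
    "schofield_wh",
    "oxford_w",
    "oxford_wh",
    "fao_who_unu",
)
LOOKUP_IDS = ("talbot_weight", "talbot_height")
EQUATION_IDS = LINEAR_IDS + LOOKUP_IDS + ("mehta",)

#: Inputs each equation needs beyond sex/age band matching.
REQUIRED_INPUTS = {
    "harris_benedict": ("weight", "height", "age"),
    "harris_benedict_infants": ("weight", "height"),
    "schofield_w": ("weight",),
    "schofield_wh": ("weight", "height"),
    "oxford_w": ("weight",),
    "oxford_wh": ("weight", "height"),
    "fao_who_unu": ("weight",),
    "talbot_weight": ("weight",),
    "talbot_height": ("height",),
    "mehta": ("vco2", "mechanically_ventilated"),
}


@dataclass(frozen=True)
class EquationResult:
    value: Optional[float]
    reason: str = "ok"  # ok | missing_input | no_band | not_ventilated | out_of_table

    @property
    def applicable(self) -> bool:
        return self.value is not None


NOT_APPLICABLE = EquationResult(None, "no_band")


@dataclass(frozen=True)
class Band:
    sex: str
    age_lo: float
    age_hi: float  # [lo, hi)
    intercept: float
    coef_weight: float
    coef_height: float
    coef_age: float
    citation: str


@dataclass(frozen=True)
class LookupTable:
    id: str
    abscissa: np.ndarray
    ree: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "abscissa", np.asarray(self.abscissa, dtype=float))
        object.__setattr__(self, "ree", np.asarray(self.ree, dtype=float))
        if not np.all(np.diff(self.abscissa) > 0):
            raise ConfigurationError(f"{self.id}: lookup abscissa must be strictly increasing")
        if np.any(self.ree <= 0):
            raise ConfigurationError(f"{self.id}: lookup REE values must be positive")


@dataclass(frozen=True)
class EquationRegistry:
    """All ten equation definitions plus gas constants, with provenance."""

    version: str
    bands: dict[str, tuple[Band, ...]]
    tables: dict[str, LookupTable]
    constants: dict

    def __post_init__(self):
        present = set(self.bands) | set(self.tables) | {"mehta"}
        missing = set(EQUATION_IDS) - present
        if missing:
            raise ConfigurationError(f"registry missing equations: {sorted(missing)}")
        if not self.version:
            raise ConfigurationError("registry version tag must be non-empty")

    @property
    def ids(self) -> tuple[str, ...]:
        return EQUATION_IDS

    def to_frame(self) -> pd.DataFrame:
        """Linear-band rows in the registry CSV schema (round-trip surface)."""
        rows = [
            {
                "id": eq_id,
                "sex": b.sex,
                "age_lo_years": b.age_lo,
                "age_hi_years": b.age_hi,
                "intercept": b.intercept,
                "coef_weight": b.coef_weight,
                "coef_height": b.coef_height,
                "coef_age": b.coef_age,
                "citation": b.citation,
            }
            for eq_id in LINEAR_IDS
            for b in self.bands[eq_id]
        ]
        return pd.DataFrame(rows)


def _bands_from_frame(df: pd.DataFrame) -> dict[str, tuple[Band, ...]]:
    bands: dict[str, list[Band]] = {}
    for row in df.itertuples(index=False):
        bands.setdefault(row.id, []).append(
            Band(
                sex=row.sex,
                age_lo=float(row.age_lo_years),
                age_hi=float(row.age_hi_years),
                intercept=float(row.intercept),
                coef_weight=float(row.coef_weight),
                coef_height=float(row.coef_height),
                coef_age=float(row.coef_age),
                citation=str(row.citation),
            )
        )
    for eq_id, bs in bands.items():
        by_sex: dict[str, list[Band]] = {}
        for b in bs:
            by_sex.setdefault(b.sex, []).append(b)
        for sex, group in by_sex.items():
            group = sorted(group, key=lambda b: b.age_lo)
            for a, b in zip(group, group[1:]):
                if b.age_lo < a.age_hi:
                    raise ConfigurationError(f"{eq_id}/{sex}: overlapping age bands")
    return {k: tuple(v) for k, v in bands.items()}


def load_registry(registry_csv=None, tables_csv=None) -> EquationRegistry:
    """Load the equation registry; defaults to the bundled transcriptions."""
    if registry_csv is None:
        with resources.as_file(
            resources.files("picuree.data").joinpath("equation_registry.csv")
        ) as p:
            reg_df = pd.read_csv(p)
    else:
        reg_df = pd.read_csv(Path(registry_csv))
    if tables_csv is None:
        with resources.as_file(
            resources.files("picuree.data").joinpath("talbot_tables.csv")
        ) as p:
            tab_df = pd.read_csv(p)
    else:
        tab_df = pd.read_csv(Path(tables_csv))
    tables = {}
    for tid, grp in tab_df.groupby("id"):
        grp = grp.sort_values("abscissa")
        tables[tid] = LookupTable(
            id=tid, abscissa=grp["abscissa"].to_numpy(), ree=grp["ree_kcal_day"].to_numpy()
        )
    constants = gas_constants()
    return EquationRegistry(
        version=str(constants["version"]),
        bands=_bands_from_frame(reg_df),
        tables=tables,
        constants=constants,
    )


def mehta_ree(vco2: float, k: Optional[float] = None) -> float:
    """VCO2-only REE (kcal/day): k * VCO2 [L/min] * 1440."""
    if vco2 < 0:
        raise DomainError(f"vco2 must be nonnegative, got {vco2}")
    if k is None:
        k = gas_constants()["mehta"]["kcal_per_l_co2"]
    return k * vco2 * 1440.0


def talbot_lookup(table: LookupTable, value: float, policy: str = "nearest") -> EquationResult:
    """Look up a basal-metabolism table at a weight/height value.

    ``nearest``: nearest abscissa, ties to the lower point (tables are
    discrete in the original).  ``linear``: interpolate between bracketing
    points, clamped outside the range.  ``strict``: out-of-range values are
    not applicable.
    """
    x = table.abscissa
    if policy == "strict" and (value < x[0] or value > x[-1]):
        return EquationResult(None, "out_of_table")
    if policy == "linear":
        return EquationResult(float(np.interp(value, x, table.ree)))
    if policy in ("nearest", "strict"):
        value_c = min(max(value, x[0]), x[-1])
        dist = np.abs(x - value_c)
        # ties to the lower abscissa: argmin returns the first minimum
        return EquationResult(float(table.ree[int(np.argmin(dist))]))
    raise ConfigurationError(f"unknown lookup policy {policy!r}")


def _record_sex(record) -> Optional[str]:
    male = record.get("male")
    if male is None or (isinstance(male, float) and math.isnan(male)):
        return None
    return "male" if male else "female"


def _get(record, key) -> Optional[float]:
    v = record.get(key)
    if v is None:
        return None
    v = float(v)
    return None if math.isnan(v) else v


def evaluate_equation(
    registry: EquationRegistry, eq_id: str, record, talbot_policy: str = "nearest"
) -> EquationResult:
    """Evaluate one equation on a patient record (mapping of cohort columns).

    Band selection uses half-open age intervals [lo, hi).  Missing inputs,
    out-of-band ages, and the ventilated-only restriction all produce a
    flagged non-applicable result.
    """
    if eq_id not in EQUATION_IDS:
        raise ConfigurationError(f"unknown equation id {eq_id!r}")

    if eq_id == "mehta":
        vent = _get(record, "mechanically_ventilated")
        if vent is None or not vent:
            return EquationResult(None, "not_ventilated")
        vco2 = _get(record, "vco2")
        if vco2 is None:
            return EquationResult(None, "missing_input")
        return EquationResult(mehta_ree(vco2, registry.constants["mehta"]["kcal_per_l_co2"]))

    if eq_id in LOOKUP_IDS:
        key = "weight" if eq_id == "talbot_weight" else "height"
        value = _get(record, key)
        if value is None:
            return EquationResult(None, "missing_input")
        return talbot_lookup(registry.tables[eq_id], value, talbot_policy)

    sex = _record_sex(record)
    age = _get(record, "age")
    if sex is None or age is None:
        return EquationResult(None, "missing_input")
    inputs = {}
    for key in REQUIRED_INPUTS[eq_id]:
        if key == "age":
            inputs["age"] = age
            continue
        v = _get(record, key)
        if v is None:
            return EquationResult(None, "missing_input")
        inputs[key] = v
    for band in registry.bands[eq_id]:
        if band.sex == sex and band.age_lo <= age < band.age_hi:
            value = (
                band.intercept
                + band.coef_weight * inputs.get("weight", 0.0)
                + band.coef_height * inputs.get("height", 0.0)
                + band.coef_age * (age if "age" in REQUIRED_INPUTS[eq_id] else 0.0)
            )
            return EquationResult(float(value))
    return EquationResult(None, "no_band")


def evaluate_all(registry: EquationRegistry, record, talbot_policy: str = "nearest"):
    """Evaluate every registry equation; one entry per id, never raises."""
    return {eq_id: evaluate_equation(registry, eq_id, record, talbot_policy) for eq_id in EQUATION_IDS}
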