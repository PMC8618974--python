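"""LMS growth z-scores and nutritional-status classification.

Z-scores come from the LMS (lambda-mu-sigma) parameterization against a
growth reference; classification applies the under-5 / 5-and-over WHO-style
cut-offs.  A synthetic fixture LMS table ships with the package (same CSV
schema as real reference tables, which can be dropped in).

Age-availability rules mirror reference-chart coverage: weight-for-length/
height z-scores exist only up to 5 years of age, weight-for-age only up to
10 years.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AvailabilityError, DataError, DomainError

__all__ = [
    "GrowthReference",
    "ZScore",
    "ZScoreSet",
    "NutritionalStatus",
    "load_growth_reference",
    "lms_zscore",
    "lms_inverse",
    "interpolate_lms",
    "compute_zscores",
    "classify_status",
    "bmi",
]

WFH_MAX_AGE_YEARS = 5.0
WFA_MAX_AGE_YEARS = 10.0

METRICS = ("weight_for_age", "height_for_age", "weight_for_length_height", "bmi_for_age")


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """LMS z-score: ((x/M)^L - 1)/(L*S) for L != 0, ln(x/M)/S for L == 0."""
    if x <= 0 or M <= 0:
        raise DomainError("measurement and median must be positive")
    if S <= 0:
        raise DomainError("S must be positive")
    if L == 0:
        return float(np.log(x / M) / S)
    return float(((x / M) ** L - 1.0) / (L * S))


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement at a given z: M*(1 + L*S*z)^(1/L), or M*exp(S*z) when L=0."""
    if L == 0:
        return float(M * np.exp(S * z))
    return float(M * (1.0 + L * S * z) ** (1.0 / L))


@dataclass(frozen=True)
class GrowthReference:
    """One metric/sex LMS table over an ordered grid (age months or height cm)."""

    metric: str
    sex: str
    grid: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        for name in ("grid", "L", "M", "S"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.grid) > 0):
            raise DataError(f"{self.metric}/{self.sex}: grid must be strictly increasing")
        if len({len(self.grid), len(self.L), len(self.M), len(self.S)}) != 1:
            raise DataError(f"{self.metric}/{self.sex}: LMS columns must match grid length")
        if np.any(self.M <= 0) or np.any(self.S <= 0):
            raise DataError(f"{self.metric}/{self.sex}: M and S must be positive")


def interpolate_lms(ref: GrowthReference, at: float) -> tuple[float, float, float]:
    """Piecewise-linear interpolation of (L, M, S) at an abscissa; exact at grid points."""
    if at < ref.grid[0] or at > ref.grid[-1]:
        raise AvailabilityError(
            f"{ref.metric}/{ref.sex}: abscissa {at} outside grid "
            f"[{ref.grid[0]}, {ref.grid[-1]}]"
        )
    return (
        float(np.interp(at, ref.grid, ref.L)),
        float(np.interp(at, ref.grid, ref.M)),
        float(np.interp(at, ref.grid, ref.S)),
    )


def load_growth_reference(path=None) -> dict[tuple[str, str], GrowthReference]:
    """Load LMS tables keyed by (metric, sex) from CSV.

    Default is the bundled synthetic fixture.  Schema: metric, sex,
    grid_value, L, M, S.
    """
    if path is None:
        with resources.as_file(
            resources.files("picuree.data").joinpath("growth_reference.csv")
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(Path(path))
    refs = {}
    for (metric, sex), grp in df.groupby(["metric", "sex"], sort=True):
        grp = grp.sort_values("grid_value")
        refs[(metric, sex)] = GrowthReference(
            metric=metric,
            sex=sex,
            grid=grp["grid_value"].to_numpy(),
            L=grp["L"].to_numpy(),
            M=grp["M"].to_numpy(),
            S=grp["S"].to_numpy(),
        )
    return refs


@dataclass(frozen=True)
class ZScore:
    value: Optional[float]
    reason: str = "available"  # available | age_over_5y | age_over_10y | out_of_reference

    @property
    def available(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class ZScoreSet:
    z_wfa: ZScore
    z_hfa: ZScore
    z_wfh: ZScore
    z_bmi: ZScore


def _try_z(refs, metric: str, sex: str, at: float, x: float) -> ZScore:
    ref = refs.get((metric, sex))
    if ref is None:
        return ZScore(None, "out_of_reference")
    try:
        L, M, S = interpolate_lms(ref, at)
    except AvailabilityError:
        return ZScore(None, "out_of_reference")
    return ZScore(lms_zscore(x, L, M, S))


def compute_zscores(
    age_years: float,
    sex: str,
    weight_kg: float,
    height_cm: float,
    refs: dict[tuple[str, str], GrowthReference],
) -> ZScoreSet:
    """Compute the four growth z-scores, honoring age-availability limits.

    WFH is attempted only for age <= 5 y, WFA only for age <= 10 y;
    unavailability is flagged with a reason, never raised.
    """
    months = age_years * 12.0
    if age_years > WFA_MAX_AGE_YEARS:
        z_wfa = ZScore(None, "age_over_10y")
    else:
        z_wfa = _try_z(refs, "weight_for_age", sex, months, weight_kg)
    z_hfa = _try_z(refs, "height_for_age", sex, months, height_cm)
    if age_years > WFH_MAX_AGE_YEARS:
        z_wfh = ZScore(None, "age_over_5y")
    else:
        z_wfh = _try_z(refs, "weight_for_length_height", sex, height_cm, weight_kg)
    z_bmi = _try_z(refs, "bmi_for_age", sex, months, bmi(weight_kg, height_cm))
    return ZScoreSet(z_wfa=z_wfa, z_hfa=z_hfa, z_wfh=z_wfh, z_bmi=z_bmi)


@dataclass(frozen=True)
class NutritionalStatus:
    stunting: Optional[bool]
    wasting: Optional[str]  # none | mild | moderate | severe
    weight_class: Optional[str]  # normal | overweight | obese

    @property
    def available(self) -> bool:
        return self.wasting is not None and self.weight_class is not None


def classify_status(age_years: float, z: ZScoreSet) -> NutritionalStatus:
    """Nutritional-status classes from z-scores.

    Stunting: height-for-age z < -2.  Wasting graded from the
    age-appropriate z (WFL/WFH under 5 y, BMI-for-age at 5 y and over) with
    strict thresholds -1/-2/-3 (z exactly at a threshold is the milder
    class).  Overweight: z > 2 (under 5) or BMI z > 1 (5 and over); obesity
    z > 3 / BMI z > 2, taking precedence over overweight.
    """
    stunting = None if not z.z_hfa.available else bool(z.z_hfa.value < -2)
    key = z.z_wfh if age_years < WFH_MAX_AGE_YEARS else z.z_bmi
    if not key.available:
        return NutritionalStatus(stunting=stunting, wasting=None, weight_class=None)
    v = key.value
    if v < -3:
        wasting = "severe"
    elif v < -2:
        wasting = "moderate"
    elif v < -1:
        wasting = "mild"
    else:
        wasting = "none"
    if age_years < WFH_MAX_AGE_YEARS:
        over_cut, obese_cut = 2.0, 3.0
    else:
        over_cut, obese_cut = 1.0, 2.0
    if v > obese_cut:
        weight_class = "obese"
    elif v > over_cut:
        weight_class = "overweight"
    else:
        weight_class = "normal"
    return NutritionalStatus(stunting=stunting, wasting=wasting, weight_class=weight_class)
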