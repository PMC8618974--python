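"""Synthetic PICU-like cohort and calorimetry-series generation.

Everything downstream is testable without any external data because this
module generates cohorts with known ground truth.  The generative model is
fully exposed in :class:`CohortSpec`:

* age log-normal (median/log-SD), truncated to the pediatric range;
* weight and height from the bundled LMS growth fixture at per-child
  (correlated) z draws; BMI derived;
* VO2 allometric in weight (``coef * weight**exponent * (1 + noise)``),
  RQ truncated-normal within plausibility bounds, VCO2 = RQ * VO2;
* vitals/labs normal with configurable moments;
* ground-truth REE either the exact Weir value of the record's gases
  (``weir_exact``) or a documented linear function of weight, sex, and
  body temperature plus noise (``covariate_driven``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import anthropometry as anthro
from . import schema
from .calorimetry import CalorimetrySeries, weir_ree
from .errors import ConfigurationError

__all__ = [
    "GasModel",
    "CovariateModel",
    "CohortSpec",
    "SyntheticPatient",
    "generate_cohort",
    "cohort_to_frame",
    "generate_breath_series",
    "inject_missingness",
    "simulate_cohort_frame",
]

#: Fields that may never be made missing (complete in the emulated study).
PROTECTED_FIELDS = frozenset(
    ["id", schema.TARGET_COLUMN]
    + schema.SEX_VARS
    + schema.ETHNICITY_VARS
    + schema.VENTILATION_VARS
    + schema.ANTHRO_VARS
    + schema.STATUS_VARS
    + schema.WASTING_VARS
    + schema.GAS_VARS
)

#: Default vitals/labs moments (mean, SD) in cohort-dictionary units.
DEFAULT_VITALS_LABS = {
    "heart_rate": (117.6, 30.3),
    "sbp": (103.5, 18.3),
    "dbp": (61.0, 14.9),
    "body_temperature": (36.6, 0.7),
    "sat_o2": (97.7, 2.7),
    "hemoglobin": (9.9, 1.8),
    "blood_glucose": (106.4, 37.3),
    "crp": (2.3, 1.0),  # log-normal: (median, log-SD)
}

DEFAULT_MISSINGNESS = {var: 0.03 for var in schema.FUNCTIONAL_VARS}


@dataclass(frozen=True)
class GasModel:
    allometric_coefficient: float = 0.0116  # L/min per kg^exponent
    allometric_exponent: float = 0.75
    vo2_noise_cv: float = 0.15
    rq_mean: float = 0.77  # mean of the *truncated* RQ distribution
    rq_sd: float = 0.12
    rq_bounds: tuple[float, float] = (0.67, 1.3)


@dataclass(frozen=True)
class CovariateModel:
    """Linear ground-truth REE for the covariate-driven mechanism.

    REE = weight_coef*weight + male_coef*male + temp_coef*(temp - temp_ref)
    + intercept + N(0, noise_sd); weight dominates by construction.
    """

    intercept: float = 0.0
    weight_coef: float = 55.0
    male_coef: float = 40.0
    temp_coef: float = 35.0
    temp_ref: float = 36.6
    noise_sd: float = 50.0


@dataclass(frozen=True)
class CohortSpec:
    n: int = 257
    seed: int = 0
    male_fraction: float = 0.564
    ethnicity_probs: tuple[float, float, float, float] = (0.7, 0.1, 0.1, 0.1)
    age_median_years: float = 2.4
    age_log_sd: float = 1.3
    age_range_years: tuple[float, float] = (0.05, 17.5)
    ventilated_fraction: float = 0.40
    gas_model: GasModel = GasModel()
    covariate_model: CovariateModel = CovariateModel()
    vitals_labs: dict = field(default_factory=lambda: dict(DEFAULT_VITALS_LABS))
    missingness_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    ree_mechanism: str = "weir_exact"  # weir_exact | covariate_driven
    growth_z_sd: float = 1.0
    growth_z_corr: float = 0.7  # weight-z vs height-z correlation

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigurationError("n must be nonnegative")
        for name in ("male_fraction", "ventilated_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        probs = self.ethnicity_probs
        if len(probs) != 4 or any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError("ethnicity_probs must be 4 proportions in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(f"ethnicity_probs must sum to 1, got {sum(probs)}")
        lo, hi = self.gas_model.rq_bounds
        if not lo < hi:
            raise ConfigurationError(f"rq_bounds low must be < high, got {self.gas_model.rq_bounds}")
        if self.gas_model.rq_sd <= 0:
            raise ConfigurationError("gas_model.rq_sd must be positive")
        if self.ree_mechanism not in ("weir_exact", "covariate_driven"):
            raise ConfigurationError(f"unknown ree_mechanism {self.ree_mechanism!r}")
        for var, rate in self.missingness_rates.items():
            if not (0 <= rate <= 1):
                raise ConfigurationError(f"missingness rate for {var} must be in [0, 1]")

    @classmethod
    def from_dict(cls, cfg: dict) -> "CohortSpec":
        cfg = dict(cfg)
        if "gas_model" in cfg:
            gm = dict(cfg["gas_model"])
            if "rq_bounds" in gm:
                gm["rq_bounds"] = tuple(gm["rq_bounds"])
            cfg["gas_model"] = GasModel(**gm)
        if "covariate_model" in cfg:
            cfg["covariate_model"] = CovariateModel(**cfg["covariate_model"])
        if "ethnicity_probs" in cfg:
            cfg["ethnicity_probs"] = tuple(cfg["ethnicity_probs"])
        if "age_range_years" in cfg:
            cfg["age_range_years"] = tuple(cfg["age_range_years"])
        try:
            spec = cls(**cfg)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        spec.validate()
        return spec


@dataclass(frozen=True)
class SyntheticPatient:
    record: dict
    true_ree: float
    true_steady_window: tuple[int, int]


def _truncnorm_loc_for_mean(target_mean: float, sd: float, bounds) -> float:
    """Location parameter so the truncated normal has the requested mean."""
    lo, hi = bounds

    def mean_err(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return float(optimize.brentq(mean_err, lo - 5 * sd, hi + 5 * sd))


def _draw_truncated_lognormal(rng, median, log_sd, lo, hi, size):
    out = np.empty(size)
    remaining = np.arange(size)
    mu = np.log(median)
    while remaining.size:
        draw = rng.lognormal(mu, log_sd, size=remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Generate ``spec.n`` synthetic patients; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    refs = anthro.load_growth_reference()
    gm = spec.gas_model
    rq_loc = _truncnorm_loc_for_mean(gm.rq_mean, gm.rq_sd, gm.rq_bounds)
    a_rq = (gm.rq_bounds[0] - rq_loc) / gm.rq_sd
    b_rq = (gm.rq_bounds[1] - rq_loc) / gm.rq_sd

    n = spec.n
    male = rng.random(n) < spec.male_fraction
    ethnicity = rng.choice(4, size=n, p=spec.ethnicity_probs)
    ventilated = rng.random(n) < spec.ventilated_fraction
    ages = _draw_truncated_lognormal(
        rng, spec.age_median_years, spec.age_log_sd, *spec.age_range_years, size=n
    )
    z_w = np.clip(rng.normal(0, spec.growth_z_sd, n), -2.5, 2.5)
    z_indep = rng.normal(0, spec.growth_z_sd, n)
    rho = spec.growth_z_corr
    z_h = np.clip(rho * z_w + np.sqrt(max(0.0, 1 - rho**2)) * z_indep, -2.5, 2.5)
    vo2_noise = np.clip(rng.normal(0, gm.vo2_noise_cv, n), -0.8, None)
    rq = stats.truncnorm.rvs(
        a_rq, b_rq, loc=rq_loc, scale=gm.rq_sd, size=n, random_state=rng
    )
    ree_noise = rng.normal(0, 1, n)
    window_starts = rng.integers(5, 16, size=n)

    patients = []
    for i in range(n):
        sex = "male" if male[i] else "female"
        months = ages[i] * 12.0
        L, M, S = anthro.interpolate_lms(refs[("weight_for_age", sex)], months)
        weight = anthro.lms_inverse(z_w[i], L, M, S)
        L, M, S = anthro.interpolate_lms(refs[("height_for_age", sex)], months)
        height = anthro.lms_inverse(z_h[i], L, M, S)
        bmi_val = anthro.bmi(weight, height)

        zset = anthro.compute_zscores(ages[i], sex, weight, height, refs)
        status = anthro.classify_status(ages[i], zset)

        vo2 = gm.allometric_coefficient * weight**gm.allometric_exponent * (1 + vo2_noise[i])
        vco2 = rq[i] * vo2

        record = {
            "id": i,
            "male": int(male[i]),
            "female": int(not male[i]),
            "caucasian": int(ethnicity[i] == 0),
            "asian": int(ethnicity[i] == 1),
            "south_american": int(ethnicity[i] == 2),
            "african": int(ethnicity[i] == 3),
            "mechanically_ventilated": int(ventilated[i]),
            "age": float(ages[i]),
            "weight": float(weight),
            "height": float(height),
            "bmi": float(bmi_val),
            "z_bmi": zset.z_bmi.value if zset.z_bmi.available else np.nan,
            "z_hfa": zset.z_hfa.value if zset.z_hfa.available else np.nan,
            "z_wfa": zset.z_wfa.value if zset.z_wfa.available else np.nan,
            "z_wfh": zset.z_wfh.value if zset.z_wfh.available else np.nan,
            "normal_weight": int(status.weight_class == "normal"),
            "overweight": int(status.weight_class == "overweight"),
            "obese": int(status.weight_class == "obese"),
            "stunting": int(bool(status.stunting)),
            "wasting_none": int(status.wasting == "none"),
            "wasting_mild": int(status.wasting == "mild"),
            "wasting_moderate": int(status.wasting == "moderate"),
            "wasting_severe": int(status.wasting == "severe"),
            "vo2": float(vo2),
            "vco2": float(vco2),
            "rq": float(rq[i]),
        }
        for var, params in spec.vitals_labs.items():
            mean, sd = params
            if var == "crp":
                record[var] = float(np.exp(np.log(mean) + sd * rng.standard_normal()))
            elif var == "sat_o2":
                record[var] = float(min(100.0, mean + sd * rng.standard_normal()))
            else:
                record[var] = float(mean + sd * rng.standard_normal())

        if spec.ree_mechanism == "weir_exact":
            true_ree = weir_ree(vo2, vco2)
        else:
            cm = spec.covariate_model
            temp = record.get("body_temperature", cm.temp_ref)
            true_ree = (
                cm.intercept
                + cm.weight_coef * weight
                + cm.male_coef * int(male[i])
                + cm.temp_coef * (temp - cm.temp_ref)
                + cm.noise_sd * ree_noise[i]
            )
        record[schema.TARGET_COLUMN] = float(true_ree)
        start = int(window_starts[i])
        patients.append(
            SyntheticPatient(
                record=record,
                true_ree=float(true_ree),
                true_steady_window=(start, start + 9),
            )
        )
    return patients


def cohort_to_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical column order."""
    if not patients:
        return pd.DataFrame(columns=schema.COHORT_COLUMNS)
    df = pd.DataFrame([p.record for p in patients])
    cols = [c for c in schema.COHORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]


def generate_breath_series(
    patient: SyntheticPatient,
    spec: CohortSpec,
    minutes: int = 30,
    within_noise: float = 0.01,
    rq_within_noise: float = 0.005,
    drift_rate: float = 0.11,
    rq_drift_rate: float = 0.06,
    ventilation_ratio: float = 27.0,
) -> CalorimetrySeries:
    """Minute series with a guaranteed steady window and drift outside it.

    Within ``patient.true_steady_window`` the per-minute multiplicative
    noise keeps RQ variation well under 5% and gas/ventilation variation
    under 10%; outside it, values drift multiplicatively per minute of
    distance from the window so that any window containing an outside
    minute violates at least one threshold (at the default rates).  Pass
    zero noise and drift rates to get a constant series.
    """
    rng = np.random.default_rng((spec.seed, int(patient.record["id"]), 7))
    start, end = patient.true_steady_window
    t = np.arange(minutes)
    dist = np.where(t < start, start - t, np.where(t > end, t - end, 0))

    base_vo2 = patient.record["vo2"]
    base_rq = patient.record["rq"]
    vo2 = base_vo2 * (1 + rng.uniform(-within_noise, within_noise, minutes))
    rq_series = base_rq * (1 + rng.uniform(-rq_within_noise, rq_within_noise, minutes))
    mv = ventilation_ratio * base_vo2 * (1 + rng.uniform(-within_noise, within_noise, minutes))

    vo2 = vo2 * (1 + drift_rate) ** dist
    rq_series = rq_series * (1 + rq_drift_rate) ** dist
    mv = mv * (1 + drift_rate) ** dist
    vco2 = rq_series * vo2
    return CalorimetrySeries(vo2=vo2, vco2=vco2, minute_ventilation=mv)


def inject_missingness(cohort: pd.DataFrame, rates: dict, seed: int) -> pd.DataFrame:
    """Make targeted cells missing, independently per cell at each rate.

    Gas and core anthropometric/demographic fields are protected; asking to
    remove them is a configuration error.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for var, rate in rates.items():
        if not (0 <= rate <= 1):
            raise ConfigurationError(f"missingness rate for {var} must be in [0, 1], got {rate}")
        if var in PROTECTED_FIELDS:
            raise ConfigurationError(f"field {var!r} is protected and cannot be made missing")
        if var not in out.columns:
            raise ConfigurationError(f"unknown variable {var!r} in missingness rates")
        mask = rng.random(len(out)) < rate
        out.loc[mask, var] = np.nan
    return out


def simulate_cohort_frame(spec: CohortSpec) -> pd.DataFrame:
    """generate_cohort + missingness injection, as one cohort table."""
    df = cohort_to_frame(generate_cohort(spec))
    if len(df) and spec.missingness_rates:
        df = inject_missingness(df, spec.missingness_rates, seed=spec.seed + 1)
    return df


def replace_spec(spec: CohortSpec, **kwargs) -> CohortSpec:
    """Convenience wrapper around :func:`dataclasses.replace` with validation."""
    new = replace(spec, **kwargs)
    new.validate()
    return new
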