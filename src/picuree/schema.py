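"""Cohort variable dictionary and candidate-pool definitions.

One row per patient; snake_case columns, units fixed package-wide
(weight kg, height cm, age years, gases L/min, REE kcal/day).
"""

from __future__ import annotations

from .errors import ConfigurationError

# Indicator pairs/groups are one-hot encoded so that each variable is a
# standalone model input (male and female are two separate candidates).
SEX_VARS = ["male", "female"]
ETHNICITY_VARS = ["caucasian", "asian", "south_american", "african"]
VENTILATION_VARS = ["mechanically_ventilated"]
ANTHRO_VARS = ["age", "weight", "height", "bmi", "z_bmi", "z_hfa"]
STATUS_VARS = ["normal_weight", "overweight", "obese", "stunting"]
WASTING_VARS = ["wasting_none", "wasting_mild", "wasting_moderate", "wasting_severe"]
GAS_VARS = ["vo2", "vco2", "rq"]

#: 24-variable baseline candidate pool.
DS1_POOL = (
    SEX_VARS
    + ETHNICITY_VARS
    + VENTILATION_VARS
    + ANTHRO_VARS
    + STATUS_VARS
    + WASTING_VARS
    + GAS_VARS
)

#: The 8 "functional" (vitals + labs) inputs added by the extended pool.
FUNCTIONAL_VARS = [
    "heart_rate",
    "sbp",
    "dbp",
    "sat_o2",
    "body_temperature",
    "crp",
    "hemoglobin",
    "blood_glucose",
]

#: 32-variable extended candidate pool.
DS2_POOL = DS1_POOL + FUNCTIONAL_VARS

TARGET_COLUMN = "measured_ree"

#: Age-gated z-scores: may legitimately be missing, never model inputs.
AGE_GATED_Z_VARS = ["z_wfa", "z_wfh"]

#: Full cohort CSV column order.
COHORT_COLUMNS = (
    ["id"]
    + SEX_VARS
    + ETHNICITY_VARS
    + VENTILATION_VARS
    + ANTHRO_VARS
    + AGE_GATED_Z_VARS
    + STATUS_VARS
    + WASTING_VARS
    + GAS_VARS
    + FUNCTIONAL_VARS
    + [TARGET_COLUMN]
)

GAS_MODES = {
    "all": GAS_VARS,
    "none": [],
    "vo2_only": ["vo2"],
    "vco2_only": ["vco2"],
    "rq_only": ["rq"],
}

#: Pool sizes fixed by the study design (variant, gas_mode) -> expected count.
EXPECTED_POOL_SIZES = {
    ("ds1", "all"): 24,
    ("ds1", "none"): 21,
    ("ds1", "vo2_only"): 22,
    ("ds1", "vco2_only"): 22,
    ("ds1", "rq_only"): 22,
    ("ds2", "all"): 32,
    ("ds2", "none"): 29,
    ("ds2", "vco2_only"): 30,
}


def candidate_pool(variant: str, gas_mode: str) -> list[str]:
    """Return the candidate-variable pool for a dataset variant and gas mode.

    ``variant`` is ``ds1`` (24 baseline variables) or ``ds2`` (adds the 8
    functional variables); ``gas_mode`` keeps the stated subset of
    ``vo2``/``vco2``/``rq``.
    """
    if variant not in ("ds1", "ds2"):
        raise ConfigurationError(f"dataset_variant must be 'ds1' or 'ds2', got {variant!r}")
    if gas_mode not in GAS_MODES:
        raise ConfigurationError(
            f"gas_mode must be one of {sorted(GAS_MODES)}, got {gas_mode!r}"
        )
    base = DS1_POOL if variant == "ds1" else DS2_POOL
    keep_gas = set(GAS_MODES[gas_mode])
    pool = [v for v in base if v not in GAS_VARS or v in keep_gas]
    expected = EXPECTED_POOL_SIZES.get((variant, gas_mode))
    if expected is not None and len(pool) != expected:
        raise ConfigurationError(
            f"candidate pool for ({variant}, {gas_mode}) has {len(pool)} variables, "
            f"expected {expected}"
        )
    return pool
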