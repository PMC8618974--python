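"""Comparison statistics, variable screening, and experiment orchestration.

Per-method fit metrics follow the study conventions:

* MAE and the mean relative error (per-record |pred-true|/true, averaged);
* two accuracy percentages, ``accuracy_abs = 100*(1 - MAE/mean(true))`` and
  ``accuracy_rel = 100*(1 - mean relative error)``;
* R^2 as the squared Pearson correlation;
* a two-sample F statistic oriented var(true)/var(pred) with a two-tailed
  p-value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import schema
from .ann import MLPSpec, reversal_blind_predict
from .equations import EQUATION_IDS, evaluate_equation, load_registry
from .errors import ConfigurationError, DataError, DomainError
from .twist import GAConfig, run_twist

__all__ = [
    "FitMetrics",
    "accuracy_from_mae",
    "accuracy_from_mre",
    "f_two_sample",
    "compute_metrics",
    "correlation_profile",
    "export_fit_curve",
    "drop_incomplete_variables",
    "ExperimentConfig",
    "run_experiment",
]

#: Columns excluded from modelling regardless of completeness.
DEFAULT_FORCED_EXCLUSIONS = (
    "length_of_stay",
    "diagnosis",
    "comorbidities",
    "current_therapy",
    "current_nutrition",
    "gestational_age",
    "birth_weight",
)

SIGNIFICANCE_LEVEL = 0.001  # multiple-testing-aware flagging threshold


def accuracy_from_mae(mae: float, mean_true: float) -> float:
    """Absolute-error accuracy percentage: 100*(1 - MAE/mean(true))."""
    if mean_true <= 0:
        raise DomainError("mean of true values must be positive")
    return 100.0 * (1.0 - mae / mean_true)


def accuracy_from_mre(mre: float) -> float:
    """Relative-error accuracy percentage: 100*(1 - mean relative error)."""
    return 100.0 * (1.0 - mre)


def f_two_sample(sd_true: float, n_true: int, sd_pred: float, n_pred: int):
    """Two-sample variance-ratio test oriented var(true)/var(pred).

    Returns ``(f, p)`` with a two-tailed p-value under
    F(n_true-1, n_pred-1).
    """
    if sd_true <= 0 or sd_pred <= 0:
        raise DomainError("standard deviations must be positive")
    if n_true < 2 or n_pred < 2:
        raise DomainError("both samples need n >= 2")
    f = (sd_true / sd_pred) ** 2
    dist = stats.f(n_true - 1, n_pred - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


@dataclass(frozen=True)
class FitMetrics:
    n: int
    mean_true: float
    sd_true: float
    mean_pred: float
    sd_pred: float
    mae: float
    mre: float
    accuracy_abs: float
    accuracy_rel: float
    r2: float
    f_statistic: Optional[float]
    f_pvalue: Optional[float]
    f_significant: Optional[bool]

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(true, pred, subgroup=None) -> FitMetrics:
    """Full fit-metric suite for one prediction method.

    ``subgroup`` optionally restricts both sequences (e.g. ventilated-only
    or infant-only rows).  Sample SDs use the n-1 denominator; a
    zero-variance prediction leaves the F test undefined (flagged None).
    """
    true = np.asarray(true, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if true.shape != pred.shape:
        raise DataError("true and pred must have equal length")
    if subgroup is not None:
        mask = np.asarray(subgroup, dtype=bool).ravel()
        true, pred = true[mask], pred[mask]
    if true.size < 2:
        raise DataError("metrics require at least 2 records")
    if np.isnan(true).any() or np.isnan(pred).any():
        raise DataError("NaN values in metric inputs")
    n = int(true.size)
    mean_true, sd_true = float(true.mean()), float(true.std(ddof=1))
    mean_pred, sd_pred = float(pred.mean()), float(pred.std(ddof=1))
    mae = float(np.abs(pred - true).mean())
    mre = float((np.abs(pred - true) / true).mean())
    if sd_true > 0 and sd_pred > 0:
        r2 = float(stats.pearsonr(true, pred).statistic ** 2)
        f_stat, f_p = f_two_sample(sd_true, n, sd_pred, n)
        f_sig = f_p < SIGNIFICANCE_LEVEL
    else:
        r2, f_stat, f_p, f_sig = float("nan"), None, None, None
    return FitMetrics(
        n=n,
        mean_true=mean_true,
        sd_true=sd_true,
        mean_pred=mean_pred,
        sd_pred=sd_pred,
        mae=mae,
        mre=mre,
        accuracy_abs=accuracy_from_mae(mae, mean_true),
        accuracy_rel=accuracy_from_mre(mre),
        r2=r2,
        f_statistic=f_stat,
        f_pvalue=f_p,
        f_significant=f_sig,
    )


def correlation_profile(table: pd.DataFrame, target: str, candidates=None) -> pd.DataFrame:
    """Pearson r of each candidate variable with the target, sorted descending."""
    if candidates is None:
        candidates = [c for c in table.columns if c != target and c != "id"]
    y = table[target].to_numpy(dtype=float)
    rows = []
    for var in candidates:
        x = table[var].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            rows.append({"variable": var, "pearson_r": np.nan, "n": int(ok.sum())})
        else:
            r = stats.pearsonr(x[ok], y[ok]).statistic
            rows.append({"variable": var, "pearson_r": float(r), "n": int(ok.sum())})
    df = pd.DataFrame(rows)
    return df.sort_values("pearson_r", ascending=False, na_position="last").reset_index(
        drop=True
    )


def export_fit_curve(true, pred, degree: int = 5) -> pd.DataFrame:
    """Rank-ordered true/predicted values plus a polynomial tendency line.

    Records are sorted by true value ascending; the tendency line is the
    degree-``degree`` least-squares polynomial of predicted value against
    rank.
    """
    true = np.asarray(true, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if true.size < degree + 1:
        raise DataError(f"fit curve requires at least {degree + 1} points")
    order = np.argsort(true, kind="stable")
    rank = np.arange(true.size)
    sorted_pred = pred[order]
    coeffs = np.polynomial.polynomial.polyfit(rank, sorted_pred, degree)
    trend = np.polynomial.polynomial.polyval(rank, coeffs)
    return pd.DataFrame(
        {"rank": rank, "true": true[order], "predicted": sorted_pred, "tendency": trend}
    )


def drop_incomplete_variables(
    table: pd.DataFrame, forced_exclusions=DEFAULT_FORCED_EXCLUSIONS
):
    """Remove every column with >=1 missing cell plus forced exclusions.

    Returns ``(reduced table, screening report)``; the report lists each
    removed column with its reason and missing count.
    """
    report = []
    drop = []
    for col in table.columns:
        n_missing = int(table[col].isna().sum())
        if col in forced_exclusions:
            drop.append(col)
            report.append(
                {"variable": col, "reason": "forced_exclusion", "n_missing": n_missing}
            )
        elif n_missing > 0:
            drop.append(col)
            report.append(
                {"variable": col, "reason": "missing_data", "n_missing": n_missing}
            )
    return table.drop(columns=drop), pd.DataFrame(
        report, columns=["variable", "reason", "n_missing"]
    )


@dataclass(frozen=True)
class ExperimentConfig:
    dataset_variant: str = "ds1"  # ds1 | ds2
    gas_mode: str = "all"  # all | none | vo2_only | vco2_only | rq_only
    ga: GAConfig = GAConfig()
    mlp: MLPSpec = MLPSpec()
    talbot_policy: str = "nearest"
    registry_path: Optional[str] = None
    tables_path: Optional[str] = None

    def pool(self) -> list[str]:
        return schema.candidate_pool(self.dataset_variant, self.gas_mode)


def _metrics_or_none(true, pred, subgroup=None):
    try:
        return compute_metrics(true, pred, subgroup).to_dict()
    except DataError:
        return None


def run_experiment(config: ExperimentConfig, cohort: pd.DataFrame) -> dict:
    """Full pipeline on one cohort: screening, selection, ANN, all equations.

    The cohort is restricted to rows complete for the variant's candidate
    pool; columns with residual missingness are screened out, the
    evolutionary selector picks features and a split, the MLP produces one
    blind prediction per record, and the metric suite is computed for the
    ANN (averaged over halves and pooled) and for every registry equation
    (restricted to each equation's applicable subgroup).  Deterministic for
    fixed config seeds.
    """
    pool = config.pool()
    target = schema.TARGET_COLUMN
    needed = pool + [target]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise DataError(f"cohort lacks required columns: {missing_cols}")

    complete = cohort.dropna(subset=needed).reset_index(drop=True)
    screened, screening_report = drop_incomplete_variables(complete[needed])
    candidates = [c for c in pool if c in screened.columns]
    if len(candidates) != len(pool):
        raise ConfigurationError(
            f"candidate pool reduced from {len(pool)} to {len(candidates)} by screening"
        )

    selection = run_twist(complete, target, candidates, config.ga, config.mlp)
    features = selection.selected_features
    blind = reversal_blind_predict(
        complete[features].to_numpy(dtype=float),
        complete[target].to_numpy(dtype=float),
        selection.split_plan,
        config.mlp,
    )
    true = complete[target].to_numpy(dtype=float)
    pred = blind["predicted_ree_kcal_day"].to_numpy()
    fold_a = (blind["fold"] == "A->B").to_numpy()

    ann_pooled = compute_metrics(true, pred).to_dict()
    half_metrics = [
        compute_metrics(true, pred, subgroup=fold_mask).to_dict()
        for fold_mask in (fold_a, ~fold_a)
    ]
    numeric_keys = [
        k for k, v in half_metrics[0].items() if isinstance(v, (int, float)) and v is not None
    ]
    ann_averaged = {
        k: float(np.mean([m[k] for m in half_metrics]))
        if all(m[k] is not None for m in half_metrics)
        else None
        for k in numeric_keys
    }

    registry = load_registry(config.registry_path, config.tables_path)
    records = complete.to_dict("records")
    equation_metrics = {}
    equation_predictions = {}
    for eq_id in EQUATION_IDS:
        results = [
            evaluate_equation(registry, eq_id, rec, config.talbot_policy) for rec in records
        ]
        values = np.array(
            [r.value if r.applicable else np.nan for r in results], dtype=float
        )
        applicable = ~np.isnan(values)
        equation_predictions[eq_id] = values
        if applicable.sum() >= 2:
            equation_metrics[eq_id] = compute_metrics(
                true[applicable], values[applicable]
            ).to_dict()
            equation_metrics[eq_id]["n_applicable"] = int(applicable.sum())
        else:
            equation_metrics[eq_id] = None

    profile = correlation_profile(complete, target, candidates)
    curve = export_fit_curve(true, pred)

    return {
        "config": {
            "dataset_variant": config.dataset_variant,
            "gas_mode": config.gas_mode,
            "pool_size": len(pool),
            "ga_seed": config.ga.seed,
            "mlp_seed": config.mlp.seed,
            "ga": asdict(config.ga),
            "mlp": asdict(config.mlp),
        },
        "n_records": int(len(complete)),
        "screening": screening_report.to_dict("records"),
        "selected_features": features,
        "split_plan": [int(v) for v in selection.split_plan],
        "fitness_trajectory": selection.fitness_trajectory,
        "ann_metrics": {"pooled": ann_pooled, "averaged_halves": ann_averaged},
        "equation_metrics": equation_metrics,
        "correlation_profile": profile.to_dict("records"),
        "fit_curve": curve.to_dict("records"),
    }


def _json_default(obj):
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True, default=_json_default)
        fh.write("\n")
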