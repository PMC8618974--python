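import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from picuree import schema
from picuree.ann import MLPSpec
from picuree.cohort import CohortSpec, simulate_cohort_frame
from picuree.errors import ConfigurationError, DataError, DomainError
from picuree.evaluation import (
    ExperimentConfig,
    accuracy_from_mae,
    accuracy_from_mre,
    compute_metrics,
    correlation_profile,
    drop_incomplete_variables,
    export_fit_curve,
    f_two_sample,
    report_to_json,
    run_experiment,
)
from picuree.twist import GAConfig


class TestCandidatePools:
    @pytest.mark.parametrize(
        "variant,mode,size",
        [
            ("ds1", "all", 24),
            ("ds1", "none", 21),
            ("ds1", "vo2_only", 22),
            ("ds1", "vco2_only", 22),
            ("ds1", "rq_only", 22),
            ("ds2", "all", 32),
            ("ds2", "none", 29),
            ("ds2", "vco2_only", 30),
        ],
    )
    def test_sizes(self, variant, mode, size):
        assert len(schema.candidate_pool(variant, mode)) == size

    def test_ds1_pool_contents(self):
        pool = set(schema.candidate_pool("ds1", "all"))
        assert {"male", "female", "vo2", "vco2", "rq", "z_bmi", "z_hfa"} <= pool
        assert "z_wfa" not in pool and "z_wfh" not in pool
        assert "heart_rate" not in pool

    def test_bad_variant(self):
        with pytest.raises(ConfigurationError):
            schema.candidate_pool("ds3", "all")


class TestFTwoSample:
    def test_equal_sds(self):
        f, p = f_two_sample(10.0, 50, 10.0, 50)
        assert f == 1.0 and p == pytest.approx(1.0)

    def test_published_harris_benedict_row(self):
        f, p = f_two_sample(325.7, 257, 260.2, 257)
        assert round(f, 3) == 1.567
        assert p < 0.001

    def test_published_mehta_row(self):
        f, _ = f_two_sample(301.9, 102, 257.0, 102)
        assert round(f, 3) == 1.380

    def test_two_tailed_symmetry(self):
        f1, p1 = f_two_sample(10.0, 30, 20.0, 30)
        f2, p2 = f_two_sample(20.0, 30, 10.0, 30)
        assert f1 == pytest.approx(1 / f2)
        assert p1 == pytest.approx(p2)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(DomainError):
            f_two_sample(0.0, 10, 1.0, 10)


class TestComputeMetrics:
    def test_identity_prediction(self, rng):
        y = rng.normal(600, 300, 100) + 1000
        m = compute_metrics(y, y)
        assert m.mae == 0.0 and m.accuracy_abs == 100.0
        assert m.r2 == pytest.approx(1.0)
        assert m.f_statistic == pytest.approx(1.0)

    def test_accuracy_identity_from_published_row(self):
        assert round(accuracy_from_mae(244.2, 623.3), 1) == 60.8
        assert round(accuracy_from_mre(0.058), 1) == 94.2

    def test_metric_identities(self, rng):
        y = rng.normal(600, 300, 200) + 1000
        pred = y + rng.normal(0, 50, 200)
        m = compute_metrics(y, pred)
        assert m.accuracy_abs == pytest.approx(100 * (1 - m.mae / m.mean_true), abs=1e-9)
        assert m.accuracy_rel == pytest.approx(100 * (1 - m.mre), abs=1e-9)
        assert m.f_statistic == pytest.approx((m.sd_true / m.sd_pred) ** 2, abs=1e-9)
        assert m.sd_true == pytest.approx(np.std(y, ddof=1))
        assert m.r2 == pytest.approx(stats.pearsonr(y, pred).statistic ** 2)

    def test_subgroup_restriction(self, rng):
        y = rng.normal(600, 100, 50) + 500
        pred = y * 1.1
        mask = np.zeros(50, bool)
        mask[:20] = True
        m = compute_metrics(y, pred, subgroup=mask)
        assert m.n == 20
        assert m.mean_true == pytest.approx(y[:20].mean())

    def test_zero_variance_pred_flagged(self):
        m = compute_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m.f_statistic is None and m.f_pvalue is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            compute_metrics([1.0, 2.0], [1.0])


class TestCorrelationProfile:
    def test_identical_variable_r1(self, rng):
        y = rng.normal(size=100)
        df = pd.DataFrame({"same": y, "noise": rng.normal(size=100), "target": y})
        prof = correlation_profile(df, "target", ["same", "noise"])
        assert prof.iloc[0]["variable"] == "same"
        assert prof.iloc[0]["pearson_r"] == pytest.approx(1.0)

    def test_independent_variable_small_r(self, rng):
        y = rng.normal(size=1000)
        df = pd.DataFrame({"indep": rng.normal(size=1000), "target": y})
        prof = correlation_profile(df, "target", ["indep"])
        assert abs(prof.iloc[0]["pearson_r"]) < 0.1

    def test_gases_top_ranked_on_weir_cohort(self, cohort_frame):
        prof = correlation_profile(
            cohort_frame, "measured_ree", schema.candidate_pool("ds1", "all")
        )
        assert set(prof.head(2)["variable"]) == {"vo2", "vco2"}

    def test_constant_variable_undefined(self):
        df = pd.DataFrame({"const": np.ones(10), "target": np.arange(10.0)})
        prof = correlation_profile(df, "target", ["const"])
        assert np.isnan(prof.iloc[0]["pearson_r"])


class TestFitCurve:
    def test_identity_curve(self, rng):
        y = np.sort(rng.normal(600, 300, 50))
        out = export_fit_curve(y, y)
        assert np.all(np.diff(out["true"]) >= 0)
        resid = out["predicted"] - out["tendency"]
        # tendency is a least-squares fit of the sorted curve
        assert np.abs(resid).mean() < np.abs(y).mean()

    def test_constant_prediction_constant_polynomial(self, rng):
        y = rng.normal(size=30)
        pred = np.full(30, 7.0)
        out = export_fit_curve(y, pred)
        np.testing.assert_allclose(out["tendency"], 7.0, atol=1e-9)

    def test_exact_interpolation_six_points(self, rng):
        y = np.arange(6.0)
        pred = rng.normal(size=6)
        out = export_fit_curve(y, pred, degree=5)
        np.testing.assert_allclose(out["tendency"], out["predicted"], atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            export_fit_curve(np.arange(4.0), np.arange(4.0), degree=5)


class TestScreening:
    def test_no_missing_only_forced(self, small_cohort_frame):
        df = small_cohort_frame[schema.DS1_POOL + ["measured_ree"]]
        out, report = drop_incomplete_variables(df)
        assert list(out.columns) == list(df.columns)
        assert report.empty

    def test_single_missing_cell_drops_column(self, small_cohort_frame):
        df = small_cohort_frame[schema.DS2_POOL].copy()
        df.loc[df.index[0], "crp"] = np.nan
        out, report = drop_incomplete_variables(df)
        assert "crp" not in out.columns
        row = report[report["variable"] == "crp"].iloc[0]
        assert row["reason"] == "missing_data" and row["n_missing"] == 1

    def test_forced_exclusions_reported(self):
        df = pd.DataFrame({"length_of_stay": [1.0, 2.0], "weight": [10.0, 12.0]})
        out, report = drop_incomplete_variables(df)
        assert list(out.columns) == ["weight"]
        assert report.iloc[0]["reason"] == "forced_exclusion"

    def test_complete_case_ds2_pool_survives(self):
        df = simulate_cohort_frame(CohortSpec(seed=11))
        complete = df.dropna(subset=schema.DS2_POOL)
        out, _ = drop_incomplete_variables(complete[schema.DS2_POOL])
        assert len(out.columns) == 32


def tiny_experiment(variant="ds1", gas_mode="all", seed=0):
    return ExperimentConfig(
        dataset_variant=variant,
        gas_mode=gas_mode,
        ga=GAConfig(population_size=8, generations=3, seed=seed),
        mlp=MLPSpec(seed=seed, max_epochs=120),
    )


@pytest.fixture(scope="module")
def report(cohort_frame):
    return run_experiment(tiny_experiment(), cohort_frame)


class TestRunExperiment:
    def test_pool_size_recorded(self, report):
        assert report["config"]["pool_size"] == 24

    def test_metric_identities_in_report(self, report):
        for metrics in [report["ann_metrics"]["pooled"]] + [
            m for m in report["equation_metrics"].values() if m
        ]:
            assert metrics["accuracy_abs"] == pytest.approx(
                100 * (1 - metrics["mae"] / metrics["mean_true"]), abs=1e-9
            )
            assert metrics["accuracy_rel"] == pytest.approx(
                100 * (1 - metrics["mre"]), abs=1e-9
            )
            if metrics["f_statistic"] is not None:
                assert metrics["f_statistic"] == pytest.approx(
                    (metrics["sd_true"] / metrics["sd_pred"]) ** 2, abs=1e-9
                )

    def test_mehta_on_ventilated_subgroup(self, report, cohort_frame):
        n_vent = int(cohort_frame["mechanically_ventilated"].sum())
        assert report["equation_metrics"]["mehta"]["n_applicable"] == n_vent

    def test_equation_metrics_independent_of_seed(self, cohort_frame, report):
        other = run_experiment(tiny_experiment(seed=9), cohort_frame)
        for eq_id, metrics in report["equation_metrics"].items():
            if metrics is None:
                assert other["equation_metrics"][eq_id] is None
                continue
            assert metrics["mae"] == other["equation_metrics"][eq_id]["mae"]

    def test_deterministic_reports(self, cohort_frame, tmp_path, report):
        again = run_experiment(tiny_experiment(), cohort_frame)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        report_to_json(report, p1)
        report_to_json(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_ds2_complete_cases(self):
        df = simulate_cohort_frame(CohortSpec(seed=13))
        rep = run_experiment(tiny_experiment(variant="ds2", gas_mode="vco2_only"), df)
        assert rep["config"]["pool_size"] == 30
        assert rep["n_records"] <= len(df)

    def test_missing_column_rejected(self, cohort_frame):
        with pytest.raises(DataError):
            run_experiment(tiny_experiment(), cohort_frame.drop(columns=["vo2"]))
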