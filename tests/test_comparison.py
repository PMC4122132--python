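import numpy as np
import pandas as pd
import pytest
from scipy import stats

from insertmetrics import (
    CohortConfig,
    MetricConfig,
    ValidationError,
    build_cohort_table,
    compare_to_reference,
    order_effect_screen,
    run_study,
    simulate_cohort,
    summarize,
)


def _table(values_by_technique, metric="peak_n", orders=None):
    rows = []
    i = 0
    for tech, vals in values_by_technique.items():
        for j, v in enumerate(vals):
            rows.append(
                {
                    "specimen_id": f"S{i}",
                    "technique": tech,
                    "insertion_order": orders[i] if orders else j % 3 + 1,
                    metric: v,
                }
            )
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def small_cohort_table():
    cohort = simulate_cohort(
        CohortConfig(n_per_technique={"forceps": 4, "hifocus_tool": 3, "motorized": 3},
                     master_seed=42)
    )
    return build_cohort_table(cohort, MetricConfig())


class TestSummarize:
    def test_closed_form(self):
        out = summarize(_table({"forceps": [1.0, 2.0, 3.0]}))
        row = out.iloc[0]
        assert (row["mean"], row["sd"], row["n"]) == (2.0, 1.0, 3)

    def test_single_value_sd_undefined(self):
        out = summarize(_table({"forceps": [5.0]}))
        assert out.iloc[0]["mean"] == 5.0
        assert np.isnan(out.iloc[0]["sd"])
        assert out.iloc[0]["n"] == 1

    def test_matches_loop_oracle(self, small_cohort_table):
        out = summarize(small_cohort_table)
        for _, row in out.iterrows():
            vals = small_cohort_table.loc[
                small_cohort_table["technique"] == row["technique"], row["metric"]
            ].tolist()
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert row["mean"] == pytest.approx(mean)
            assert row["sd"] == pytest.approx(sd)
            assert row["n"] == len(vals)


class TestCompareToReference:
    def test_identical_groups_p_one(self):
        table = _table({"forceps": [0.2] * 4, "motorized": [0.2] * 4})
        out = compare_to_reference(table)
        assert out["p_value"].iloc[0] == 1.0

    def test_perfect_separation_p_zero(self):
        table = _table({"forceps": [0.0] * 4, "motorized": [1.0] * 4})
        out = compare_to_reference(table)
        assert out["p_value"].iloc[0] == 0.0

    def test_equals_squared_t_test(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 8)
        table = _table({"forceps": list(a), "motorized": list(b)})
        p_anova = compare_to_reference(table)["p_value"].iloc[0]
        p_t = stats.ttest_ind(a, b).pvalue  # two-group ANOVA F = t²
        assert p_anova == pytest.approx(p_t, rel=1e-12)

    def test_missing_reference_rejected(self, small_cohort_table):
        with pytest.raises(ValidationError):
            compare_to_reference(small_cohort_table, reference="robotic")

    def test_p_invariant_to_relabeling_and_rescaling(self, small_cohort_table):
        base = compare_to_reference(small_cohort_table)
        relabeled = small_cohort_table.copy()
        relabeled["specimen_id"] = [f"X{i}" for i in range(len(relabeled))]
        rescaled = relabeled.copy()
        rescaled["peak_n"] = rescaled["peak_n"] * 1000.0
        out = compare_to_reference(rescaled)
        np.testing.assert_allclose(out["p_value"], base["p_value"], rtol=1e-9)

    def test_detects_motorized_count_contrasts(self):
        """At the study group sizes the motorized archetype differs from
        forceps in excursion and sudden-rise counts in most replicates."""
        hits_th, hits_g = 0, 0
        n_rep = 40
        for rep in range(n_rep):
            cohort = simulate_cohort(CohortConfig(master_seed=1000 + rep))
            table = build_cohort_table(cohort)
            pvals = compare_to_reference(table).set_index(["metric", "technique"])
            hits_th += pvals.loc[("over_threshold_n", "motorized"), "p_value"] < 0.05
            hits_g += pvals.loc[("sudden_rise_n", "motorized"), "p_value"] < 0.05
        assert hits_th > n_rep / 2
        assert hits_g > n_rep / 2


class TestOrderScreen:
    def test_injected_attenuation_excludes_order_3(self):
        cohort = simulate_cohort(CohortConfig(master_seed=5, order_effects={3: 0.5}))
        table = build_cohort_table(cohort)
        result = order_effect_screen(table)
        assert result.excluded_orders == [3]
        assert not (result.filtered["insertion_order"] == 3).any()
        assert len(result.filtered) == len(table) - (table["insertion_order"] == 3).sum()

    def test_single_order_skips_with_notice(self):
        table = _table({"forceps": [0.2, 0.25, 0.22]}, orders=[1, 1, 1])
        result = order_effect_screen(table)
        assert result.excluded_orders == []
        assert result.omnibus_p is None
        assert any("skipped" in n for n in result.notices)
        pd.testing.assert_frame_equal(result.filtered, table)

    def test_detail_reports_per_technique_contrasts(self):
        cohort = simulate_cohort(CohortConfig(master_seed=6))
        table = build_cohort_table(cohort)
        result = order_effect_screen(table)
        assert {"technique", "insertion_order", "p_value"} <= set(result.detail.columns)
        assert result.detail["p_value"].between(0, 1).all()

    def test_invalid_alpha_rejected(self, small_cohort_table):
        with pytest.raises(ValidationError):
            order_effect_screen(small_cohort_table, alpha=1.5)


class TestBuildCohortTable:
    def test_duplicate_specimen_order_rejected(self):
        cohort = simulate_cohort(
            CohortConfig(n_per_technique={"forceps": 2}, master_seed=0)
        )
        for rec in cohort:
            rec.specimen_id, rec.insertion_order = "same", 1
        with pytest.raises(ValidationError, match="duplicate"):
            build_cohort_table(cohort)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            build_cohort_table([])


class TestRunStudy:
    CONFIG = {
        "simulate": {
            "n_per_technique": {"forceps": 10, "hifocus_tool": 8, "motorized": 8},
            "master_seed": 11,
        },
        "compare": {"reference": "forceps"},
    }

    def test_summary_layout_and_artifacts(self, tmp_path):
        report = run_study(self.CONFIG, out_dir=tmp_path)
        assert len(report.summary) == 15  # 5 metrics x 3 techniques
        assert set(report.summary["technique"]) == {"forceps", "hifocus_tool", "motorized"}
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "summary.csv").exists()
        assert (tmp_path / "report.txt").exists()
        # reference rows carry no P value; contrasts do
        ref = report.summary[report.summary["technique"] == "forceps"]
        assert ref["p_value"].isna().all()
        rest = report.summary[report.summary["technique"] != "forceps"]
        assert rest["p_value"].between(0, 1).all()

    def test_group_sizes_match_filtered_table(self, tmp_path):
        report = run_study(self.CONFIG, out_dir=tmp_path)
        counts = report.screen.filtered.groupby("technique").size()
        for _, row in report.summary.iterrows():
            assert row["n"] == counts[row["technique"]]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            run_study({"inputs": {"files": []}})

    def test_deterministic_artifacts(self, tmp_path):
        run_study(self.CONFIG, out_dir=tmp_path / "a")
        run_study(self.CONFIG, out_dir=tmp_path / "b")
        for name in ("metrics.csv", "summary.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
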