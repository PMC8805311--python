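"""Cohort orchestration, statistics (with exact-enumeration oracle) and fixture."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rtsegeval.cohort import (
    EvalConfig,
    cases_to_frame,
    correlation_report,
    dvh_differences,
    evaluate_case,
    evaluate_cohort,
    ingest_printed_tables,
    pearson_r,
    plan_consistency_check,
    summarize_cohort,
    wilcoxon_signed_rank,
)
from rtsegeval.phantom import PerturbationParams, generate_cohort

from test_phantom import COMPACT, IDENTITY


def wilcoxon_exact_oracle(diffs):
    """Two-sided exact p by full enumeration of all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean_w = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_six_positive_differences_exact_p(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        assert res.p_value == pytest.approx(2 / 64)
        assert res.significant

    def test_antisymmetric_differences_not_significant(self):
        res = wilcoxon_signed_rank([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        assert res.p_value > 0.9
        assert not res.significant

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_full_enumeration_for_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        d = np.round(rng.normal(0.3, 1.0, n), 3)
        d = d[d != 0]
        if len(d) < 5:
            return
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-10)

    def test_zero_differences_dropped(self):
        with_zeros = [0.0, 0.0, 1.0, 2.0, 0.5, 3.0, 1.5, 2.5]
        res = wilcoxon_signed_rank(with_zeros)
        assert res.n_effective == 6
        assert res.p_value == pytest.approx(2 / 64)

    def test_all_zero_gives_no_evidence(self):
        res = wilcoxon_signed_rank([0.0] * 8)
        assert res.p_value == 1.0 and not res.significant

    def test_fewer_than_five_pairs_warns(self):
        with pytest.warns(UserWarning, match="non-zero pairs"):
            res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert np.isnan(res.p_value)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_p_value_from_t_distribution(self, rng):
        from scipy import stats

        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        res = pearson_r(x, y)
        t = res.r * np.sqrt((20 - 2) / (1 - res.r**2))
        p = 2 * stats.t.sf(abs(t), df=18)
        assert res.p_value == pytest.approx(p, rel=1e-6)

    def test_constant_input_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            res = pearson_r(np.ones(5), np.arange(5.0))
        assert np.isnan(res.r)


class TestPlanConsistency:
    def test_identical_sets_all_pass(self):
        a = {"prostate_D98": 72.0, "rectum_V50": 3.0}
        rep = plan_consistency_check(a, dict(a))
        assert rep["within_tolerance"].all()

    def test_five_percent_deviation_flagged(self):
        a = {"p1": 100.0, "p2": 50.0}
        b = {"p1": 105.0, "p2": 50.2}
        rep = plan_consistency_check(a, b)
        assert not rep.loc["p1", "within_tolerance"]
        assert rep.loc["p2", "within_tolerance"]

    def test_mismatched_parameter_lists_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            plan_consistency_check({"a": 1.0}, {"b": 1.0})


class TestEvaluateCase:
    @pytest.fixture(scope="class")
    def identity_case(self):
        case = generate_cohort(
            1, spec=COMPACT, params=IDENTITY, seed=4, crop_size=(80, 80, 80)
        )[0]
        return evaluate_case(
            case.gt_masks, case.pred_masks, case.dose_ref, case.dose_test,
            EvalConfig(), case.case_id
        )

    def test_identity_case_degenerate_metrics(self, identity_case):
        cm = identity_case
        assert all(v == 1.0 for v in cm.dsc.values())
        assert all(v == 0.0 for v in cm.hd_avg.values())
        assert all(v == 0.0 for v in cm.hd95.values())
        assert cm.gamma_pass_pct == 100.0
        assert cm.ci_ref == cm.ci_test
        assert all(v == 0.0 for v in dvh_differences(cm).values())

    def test_dvh_parameters_present_for_all_configured_structures(self, identity_case):
        keys = set(identity_case.dvh_ref)
        assert {"prostate_D98", "prostate_D2", "prostate_V95%",
                "ctv_D98", "ctv_D2", "ctv_V95%",
                "rectum_V50", "rectum_V65", "rectum_V70",
                "bladder_V60", "bladder_V65", "bladder_V70"} == keys

    def test_missing_structure_flagged_not_dropped(self):
        case = generate_cohort(
            1, spec=COMPACT, params=IDENTITY, seed=4, crop_size=(80, 80, 80)
        )[0]
        pred = dict(case.pred_masks)
        del pred["rectum"]
        cm = evaluate_case(case.gt_masks, pred, case.dose_ref, case.dose_test)
        assert cm.flagged and cm.missing == ["rectum"]
        assert np.isnan(cm.dsc["rectum"])
        assert cm.dsc["prostate"] == 1.0


class TestCohortTables:
    def test_summary_mean_sd_and_order_invariance(self):
        df = pd.DataFrame(
            {"dsc_prostate": [0.8, 0.9, 1.0], "gamma_pct": [70.0, 80.0, 90.0]}
        )
        s = summarize_cohort(df)
        assert s.loc["mean", "dsc_prostate"] == pytest.approx(0.9)
        assert s.loc["sd", "gamma_pct"] == pytest.approx(10.0)  # ddof=1
        shuffled = summarize_cohort(df.iloc[[2, 0, 1]])
        pd.testing.assert_frame_equal(s, shuffled)

    def test_single_repeated_case_sd_zero(self):
        df = pd.DataFrame({"dsc_prostate": [0.9, 0.9, 0.9]})
        assert summarize_cohort(df).loc["sd", "dsc_prostate"] == 0.0

    def test_fixture_loads_eleven_patients_with_spot_values(self):
        df = ingest_printed_tables()
        assert len(df) == 11
        assert df.loc["Pat82", "dsc_prostate"] == 0.92
        assert df.loc["Pat59", "gamma_pct"] == 71
        assert df.loc["Pat32", "hd95_rectum"] == 14.9

    def test_malformed_fixture_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("patient,dsc_prostate\nPatX,0.9\n")
        with pytest.raises(ValueError, match="missing columns"):
            ingest_printed_tables(p)

    def test_correlation_report_families_and_range(self):
        df = ingest_printed_tables()
        rep = correlation_report(df)
        assert "dsc_prostate vs gamma_pct" in rep.index
        assert "mean_dsc vs gamma_pct" in rep.index
        valid = rep["r"].dropna()
        assert ((valid >= -1) & (valid <= 1)).all()

    def test_correlation_on_constant_columns_reported_as_nan(self):
        df = pd.DataFrame(
            {
                "dsc_prostate": [0.9, 0.9, 0.9],
                "dsc_bladder": [0.9, 0.9, 0.9],
                "dsc_rectum": [0.9, 0.9, 0.9],
                "gamma_pct": [100.0, 100.0, 100.0],
            }
        )
        rep = correlation_report(df)
        assert rep["r"].isna().all()


class TestEndToEndFrame:
    def test_cases_to_frame_holds_all_metric_columns(self):
        cases = generate_cohort(
            2,
            spec=COMPACT,
            params=PerturbationParams(max_translation_mm=(2, 2, 2),
                                      max_angles_deg=(3, 3, 3), deform_sigma=1.0),
            seed=8,
            crop_size=(80, 80, 80),
        )
        frame = cases_to_frame(evaluate_cohort(cases))
        for col in ("dsc_prostate", "hdavg_rectum", "hd95_bladder",
                    "ref_prostate_D98", "test_prostate_D98",
                    "diff_ctv_V95%", "ci_manual", "ci_unet", "gamma_pct"):
            assert col in frame.columns
        assert len(frame) == 2
        assert not frame["flagged"].any()
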