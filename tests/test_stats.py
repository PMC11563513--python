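"""Clustered association statistics: GEE, group comparisons, categorization."""

import numpy as np
import pandas as pd
import pytest

from octava import (
    CohortSimParams,
    categorize_adherence,
    categorize_severity,
    fit_gee_change_on_usage,
    fit_gee_crosssectional,
    generate_cohort,
    longitudinal_group_comparison,
    preprocess,
    thickness_comparisons,
)
from octava.config import GEEConfig
from octava.stats import DEFAULT_COVARIATES


@pytest.fixture(scope="module")
def cohort500():
    params = CohortSimParams(
        n_participants=500,
        within_participant_corr=0.5,
        effect_sizes={"svd_outcome": {"foveal_vd": 0.40}},
        with_followup=False,
        seed=11,
    )
    return generate_cohort(params)[0]


class TestPreprocess:
    def test_wmh_log_icv(self):
        t = pd.DataFrame({"wmh_volume_ml": [1.0], "icv_ml": [1000.0]})
        out = preprocess(t)
        assert out["wmh_log_icv"].iloc[0] == pytest.approx(np.log(0.001))

    def test_pvs_percent_of_roi(self):
        t = pd.DataFrame({"pvs_bg_volume_ml": [2.0], "bg_roi_volume_ml": [100.0]})
        out = preprocess(t)
        assert out["pvs_bg_volume_pct"].iloc[0] == pytest.approx(2.0)

    def test_nonpositive_wmh_raises_with_row(self):
        t = pd.DataFrame({"wmh_volume_ml": [1.0, -0.1], "icv_ml": [1000.0, 1000.0]})
        with pytest.raises(ValueError, match="rows"):
            preprocess(t)


class TestCategorization:
    @pytest.mark.parametrize(
        "pahi,label",
        [(20, "moderate"), (31, "severe"), (30, "moderate"), (7, "mild"), (2, "none/mild-subthreshold")],
    )
    def test_severity_bins(self, pahi, label):
        assert categorize_severity([pahi]).iloc[0] == label

    def test_severity_negative_raises(self):
        with pytest.raises(ValueError):
            categorize_severity([-1.0])

    def test_adherence_mean_definition(self):
        out = categorize_adherence([6.7, 3.9, 4.0])
        assert list(out["adherence_mean"]) == ["optimal", "sub_optimal", "optimal"]

    def test_adherence_nightly_definition(self):
        out = categorize_adherence([5.0, 5.0], [79.0, 80.0])
        assert list(out["adherence_nightly"]) == ["sub_optimal", "optimal"]

    def test_missing_usage_missing_label(self):
        out = categorize_adherence([np.nan])
        assert out["adherence_mean"].iloc[0] is None


class TestGEECrossSectional:
    def test_recovers_true_standardized_beta(self, cohort500):
        r = fit_gee_crosssectional(cohort500, "svd_outcome", "foveal_vd")
        assert r.standardized_beta == pytest.approx(0.40, abs=0.07)
        assert r.ci_low <= r.standardized_beta <= r.ci_high
        assert r.n_participants == 500
        assert r.n_eyes == 1000

    def test_single_eye_matches_ols(self):
        params = CohortSimParams(
            n_participants=200,
            eyes_per_participant=1,
            effect_sizes={"o": {"foveal_vd": 0.3}},
            with_followup=False,
            seed=12,
        )
        table, _ = generate_cohort(params)
        r = fit_gee_crosssectional(table, "o", "foveal_vd", covariates=["age", "bmi"])
        import statsmodels.api as sm

        z = lambda c: (c - c.mean()) / c.std(ddof=0)
        exog = sm.add_constant(
            pd.DataFrame({c: z(table[c].astype(float)) for c in ["foveal_vd", "age", "bmi"]})
        )
        ols = sm.OLS(z(table["o"]), exog).fit()
        assert r.standardized_beta == pytest.approx(ols.params["foveal_vd"], abs=1e-6)

    def test_standardization_scale_invariance(self, cohort500):
        t2 = cohort500.copy()
        t2["foveal_vd"] = t2["foveal_vd"] * 1000.0
        r1 = fit_gee_crosssectional(cohort500, "svd_outcome", "foveal_vd")
        r2 = fit_gee_crosssectional(t2, "svd_outcome", "foveal_vd")
        assert r1.standardized_beta == pytest.approx(r2.standardized_beta, abs=1e-8)

    def test_exclusion_bookkeeping(self, cohort500):
        t = cohort500.copy()
        t.loc[t.index[:37], "sbp"] = np.nan
        r = fit_gee_crosssectional(t, "svd_outcome", "foveal_vd")
        assert r.n_eyes + r.n_excluded == len(t)
        assert r.n_excluded == 37

    def test_too_few_clusters_raises(self):
        params = CohortSimParams(n_participants=5, effect_sizes={"o": {"foveal_vd": 0.0}}, with_followup=False, seed=13)
        table, _ = generate_cohort(params)
        with pytest.raises(ValueError, match="clusters"):
            fit_gee_crosssectional(table, "o", "foveal_vd")

    def test_independence_structure_option(self, cohort500):
        cfg = GEEConfig(working_correlation="independence")
        r = fit_gee_crosssectional(cohort500, "svd_outcome", "foveal_vd", config=cfg)
        assert r.working_correlation == "independence"
        assert r.standardized_beta == pytest.approx(0.40, abs=0.07)


class TestLongitudinal:
    def test_identical_groups_p_one(self):
        # identical non-normal change distributions in both adherence groups
        rows = []
        vals = np.concatenate([np.linspace(0, 1, 9) ** 3, [5.0]])
        for i in range(20):
            usage = 6.0 if i < 10 else 2.0
            v = vals[i % 10]
            rows.append(dict(participant_id=f"P{i}", eye="OD", visit="baseline",
                             x=0.0, cpap_usage_hr_per_night=usage))
            rows.append(dict(participant_id=f"P{i}", eye="OD", visit="followup",
                             x=v, cpap_usage_hr_per_night=usage))
        t = pd.DataFrame(rows)
        res = longitudinal_group_comparison(t, "x", "OD")
        assert res.test_used == "mann-whitney"
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(0)
        detected = 0
        for rep in range(50):
            rows = []
            for i in range(40):
                optimal = i < 20
                delta = rng.normal(2.0 if optimal else 0.0, 1.0)
                usage = 6.0 if optimal else 2.0
                rows.append(dict(participant_id=f"P{i}", eye="OD", visit="baseline",
                                 x=0.0, cpap_usage_hr_per_night=usage))
                rows.append(dict(participant_id=f"P{i}", eye="OD", visit="followup",
                                 x=delta, cpap_usage_hr_per_night=usage))
            res = longitudinal_group_comparison(pd.DataFrame(rows), "x", "OD")
            detected += res.p_value < 0.01
        assert detected >= 47  # >= 95% power at this separation

    def test_degenerate_shared_value(self):
        rows = []
        for i in range(10):
            usage = 6.0 if i < 5 else 2.0
            rows.append(dict(participant_id=f"P{i}", eye="OD", visit="baseline",
                             x=1.0, cpap_usage_hr_per_night=usage))
            rows.append(dict(participant_id=f"P{i}", eye="OD", visit="followup",
                             x=1.0, cpap_usage_hr_per_night=usage))
        res = longitudinal_group_comparison(pd.DataFrame(rows), "x", "OD")
        assert res.p_value is None and "degenerate" in res.note

    def test_insufficient_data_returns_none(self):
        t = pd.DataFrame(
            [dict(participant_id="P0", eye="OD", visit="baseline", x=0.0, cpap_usage_hr_per_night=5.0)]
        )
        assert longitudinal_group_comparison(t, "x", "OD") is None


class TestGEEChangeOnUsage:
    def test_recovery(self):
        params = CohortSimParams(
            n_participants=500,
            change_effect_sizes={"foveal_vd": 0.3},
            within_participant_corr=0.5,
            seed=14,
        )
        table, _ = generate_cohort(params)
        r = fit_gee_change_on_usage(table, "foveal_vd")
        assert r.standardized_beta == pytest.approx(0.3, abs=0.07)

    def test_constant_usage_raises(self):
        params = CohortSimParams(n_participants=30, seed=15)
        table, _ = generate_cohort(params)
        table["cpap_usage_hr_per_night"] = 5.0
        with pytest.raises(ValueError, match="zero variance"):
            fit_gee_change_on_usage(table, "foveal_vd")

    def test_no_followup_raises(self):
        params = CohortSimParams(n_participants=30, with_followup=False, seed=16)
        table, _ = generate_cohort(params)
        with pytest.raises(ValueError):
            fit_gee_change_on_usage(table, "foveal_vd")


class TestThickness:
    def test_full_result_set_on_simulated_cohort(self):
        table, _ = generate_cohort(CohortSimParams(n_participants=60, seed=17))
        results = thickness_comparisons(table)
        assert len(results) > 0
        kinds = {r.test_used for r in results}
        assert "paired-t" in kinds
        for r in results:
            if r.p_value is not None:
                assert 0.0 <= r.p_value <= 1.0

    def test_identical_pre_post_degenerate(self):
        rows = []
        for i in range(12):
            for visit in ("baseline", "followup"):
                rows.append(dict(participant_id=f"P{i}", eye="OD", visit=visit,
                                 mac_foveal_um=270.0, pahi=40.0,
                                 cpap_usage_hr_per_night=6.0 if i < 6 else 2.0))
        res = thickness_comparisons(pd.DataFrame(rows), regions=["mac_foveal_um"])
        paired = [r for r in res if r.test_used == "paired-t"]
        assert paired and all(r.p_value is None for r in paired)

    def test_paired_shift_detected(self):
        rng = np.random.default_rng(1)
        detected = 0
        for rep in range(30):
            rows = []
            for i in range(16):
                pre = rng.normal(8.5, 0.3)
                post = pre + 0.05 + rng.normal(0, 0.03)
                for visit, v in (("baseline", pre), ("followup", post)):
                    rows.append(dict(participant_id=f"P{i}", eye="OD", visit=visit,
                                     macular_volume_mm3=v, pahi=40.0,
                                     cpap_usage_hr_per_night=6.0))
            res = thickness_comparisons(pd.DataFrame(rows), regions=["macular_volume_mm3"])
            paired = [r for r in res if r.test_used == "paired-t"]
            assert paired
            detected += paired[0].p_value < 0.01
        assert detected >= 27  # ~90% power


def test_pvalues_reported_unadjusted(cohort500):
    # two phenotypes tested against the same outcome: p-values come from
    # the individual fits, no multiplicity correction applied
    r1 = fit_gee_crosssectional(cohort500, "svd_outcome", "foveal_vd")
    r2 = fit_gee_crosssectional(cohort500, "svd_outcome", "parafoveal_vd")
    assert r1.p_value != r2.p_value
    assert 0 <= r1.p_value <= 1 and 0 <= r2.p_value <= 1
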