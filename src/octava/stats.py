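"""Clustered association analyses for a two-eye ophthalmic cohort.

Cross-sectional associations between eye-level retinal phenotypes and
participant-level outcomes use generalized estimating equations (GEE)
with an identity link, exchangeable working correlation and robust
(sandwich) standard errors, clustering fellow eyes within participant.
Outcome and continuous predictors are z-scored on the analysis sample so
the reported coefficients are standardized βs; binary covariates stay
0/1.  Longitudinal analyses compare per-eye phenotype changes between
CPAP-adherence groups (t-test when both groups pass a Shapiro–Wilk
normality gate at α = 0.05, Mann-Whitney U otherwise) and regress change
on average CPAP usage in the same GEE framework.  P-values are reported
unadjusted for multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .config import GEEConfig

__all__ = [
    "GEEResult",
    "GroupComparisonResult",
    "DEFAULT_COVARIATES",
    "preprocess",
    "categorize_severity",
    "categorize_adherence",
    "fit_gee_crosssectional",
    "longitudinal_group_comparison",
    "fit_gee_change_on_usage",
    "thickness_comparisons",
]

DEFAULT_COVARIATES = [
    "age",
    "sex_female",
    "sbp",
    "bmi",
    "diabetes",
    "hypercholesterolemia",
    "smoker",
    "image_quality",
]

THICKNESS_REGIONS = [
    "mac_foveal_um",
    "mac_superior_um",
    "mac_nasal_um",
    "mac_inferior_um",
    "mac_temporal_um",
    "macular_volume_mm3",
]


@dataclass
class GEEResult:
    outcome: str
    phenotype: str
    standardized_beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_eyes: int
    n_participants: int
    n_excluded: int
    working_correlation: str

    def __post_init__(self) -> None:
        assert self.ci_low <= self.standardized_beta <= self.ci_high


@dataclass
class GroupComparisonResult:
    variable: str
    eye: str | None
    group_labels: tuple[str, str]
    test_used: str              # "t-test", "mann-whitney", "paired-t"
    statistic: float | None
    p_value: float | None
    n_groups: tuple[int, int]
    group_means: tuple[float, float]
    note: str = ""


def preprocess(table: pd.DataFrame) -> pd.DataFrame:
    """Derived analysis columns: log WMH fraction of intracranial volume,
    PVS volumes as % of their region of interest; ordinal brain scores are
    kept numeric.  Raises on non-positive WMH/ICV, naming the offending
    rows."""
    out = table.copy()
    if {"wmh_volume_ml", "icv_ml"} <= set(out.columns):
        bad = out.index[(out["wmh_volume_ml"] <= 0) | (out["icv_ml"] <= 0)]
        if len(bad):
            raise ValueError(f"non-positive WMH or ICV volume in rows {list(bad[:5])}")
        out["wmh_log_icv"] = np.log(out["wmh_volume_ml"] / out["icv_ml"])
    for tissue in ("bg", "cso"):
        vol, roi = f"pvs_{tissue}_volume_ml", f"{tissue}_roi_volume_ml"
        if {vol, roi} <= set(out.columns):
            out[f"pvs_{tissue}_volume_pct"] = 100.0 * out[vol] / out[roi]
    return out


def categorize_severity(pahi) -> pd.Series:
    """OSA severity from the apnea-hypopnea index: mild 5–14, moderate
    15–30, severe > 30 events/hour; values below 5 are flagged as
    subthreshold."""
    s = pd.Series(np.atleast_1d(np.asarray(pahi, dtype=float)))
    if (s < 0).any():
        raise ValueError("pAHI must be >= 0")
    lab = pd.Series(
        np.select(
            [s < 5, s < 15, s <= 30, s > 30],
            ["none/mild-subthreshold", "mild", "moderate", "severe"],
            default="",
        ),
        index=s.index,
    )
    return lab


def categorize_adherence(
    mean_usage_hr, pct_nights_over_4hr=None
) -> pd.DataFrame:
    """CPAP adherence under both definitions in circulation:

    * ``mean``: optimal when mean usage ≥ 4 hr/night;
    * ``nightly``: optimal when usage reached ≥ 4 hr on ≥ 80 % of nights.

    Returns a DataFrame with both labelings; missing usage → missing label.
    """
    usage = pd.Series(np.atleast_1d(np.asarray(mean_usage_hr, dtype=float)))
    if (usage.dropna() < 0).any():
        raise ValueError("usage must be >= 0")
    mean_lab = pd.Series(
        np.where(usage.isna(), None, np.where(usage >= 4.0, "optimal", "sub_optimal")),
        index=usage.index,
    )
    if pct_nights_over_4hr is None:
        nightly_lab = pd.Series([None] * len(usage), index=usage.index)
    else:
        pct = pd.Series(np.atleast_1d(np.asarray(pct_nights_over_4hr, dtype=float)))
        nightly_lab = pd.Series(
            np.where(pct.isna(), None, np.where(pct >= 80.0, "optimal", "sub_optimal")),
            index=usage.index,
        )
    return pd.DataFrame({"adherence_mean": mean_lab, "adherence_nightly": nightly_lab})


def _is_binary(col: pd.Series) -> bool:
    vals = pd.unique(col.dropna())
    return len(vals) <= 2


def _zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    if sd == 0:
        raise ValueError(f"zero-variance column {col.name!r}")
    return (col - col.mean()) / sd


def _fit_gee(
    data: pd.DataFrame,
    endog_col: str,
    predictor: str,
    covariates: list[str],
    config: GEEConfig,
    outcome_name: str,
    phenotype_name: str,
    n_input_rows: int,
) -> GEEResult:
    cols = [endog_col, predictor, *covariates, "participant_id"]
    d = data[cols].dropna().copy()
    n_used = len(d)
    groups = d["participant_id"]
    if groups.nunique() < config.min_clusters:
        raise ValueError(
            f"only {groups.nunique()} clusters after exclusions "
            f"(minimum {config.min_clusters})"
        )
    endog = _zscore(d[endog_col].astype(float))
    exog = pd.DataFrame(index=d.index)
    for c in [predictor, *covariates]:
        col = d[c].astype(float)
        exog[c] = col if _is_binary(col) else _zscore(col)
    exog = sm.add_constant(exog)
    cov_struct = (
        sm.cov_struct.Exchangeable()
        if config.working_correlation == "exchangeable"
        else sm.cov_struct.Independence()
    )
    model = sm.GEE(endog, exog, groups=groups, family=sm.families.Gaussian(), cov_struct=cov_struct)
    try:
        res = model.fit()
    except Exception as e:  # pragma: no cover - Gaussian GEE rarely fails
        raise RuntimeError(f"GEE did not converge for {outcome_name}~{phenotype_name}: {e}") from e
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(f"GEE produced non-finite estimates for {outcome_name}~{phenotype_name}")
    ci = res.conf_int().loc[predictor]
    if not (np.isfinite(ci).all() and np.isfinite(res.pvalues[predictor])):
        raise RuntimeError(
            f"GEE inference undefined for {outcome_name}~{phenotype_name} "
            "(non-finite robust standard error)"
        )
    return GEEResult(
        outcome=outcome_name,
        phenotype=phenotype_name,
        standardized_beta=float(res.params[predictor]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(res.pvalues[predictor]),
        n_eyes=n_used,
        n_participants=int(groups.nunique()),
        n_excluded=n_input_rows - n_used,
        working_correlation=config.working_correlation,
    )


def fit_gee_crosssectional(
    table: pd.DataFrame,
    outcome: str,
    phenotype: str,
    covariates: list[str] | None = None,
    config: GEEConfig | None = None,
) -> GEEResult:
    """Standardized association between one outcome and one retinal
    phenotype at baseline, both eyes clustered by participant."""
    cfg = config or GEEConfig()
    covs = DEFAULT_COVARIATES if covariates is None else covariates
    base = table[table["visit"] == "baseline"] if "visit" in table.columns else table
    return _fit_gee(base, outcome, phenotype, covs, cfg, outcome, phenotype, len(base))


def _per_eye_change(table: pd.DataFrame, column: str, eye: str) -> pd.DataFrame:
    d = table[table["eye"] == eye]
    wide = d.pivot_table(index="participant_id", columns="visit", values=column, aggfunc="first")
    if "followup" not in wide.columns or "baseline" not in wide.columns:
        return pd.DataFrame(columns=["participant_id", "change"])
    out = (wide["followup"] - wide["baseline"]).dropna().rename("change").reset_index()
    return out


def _choose_test(g1: np.ndarray, g2: np.ndarray) -> str:
    """t-test iff both groups pass Shapiro-Wilk at α = 0.05; a
    zero-variance group counts as non-normal."""
    for g in (g1, g2):
        if np.ptp(g) == 0:
            return "mann-whitney"
        if sps.shapiro(g).pvalue <= 0.05:
            return "mann-whitney"
    return "t-test"


def longitudinal_group_comparison(
    table: pd.DataFrame,
    phenotype: str,
    eye: str,
    config: GEEConfig | None = None,
) -> GroupComparisonResult | None:
    """Compare follow-up − baseline change of one phenotype between optimal
    and sub-optimal CPAP adherence, independently for one eye.  Returns
    None when either group has fewer than 3 changes."""
    cfg = config or GEEConfig()
    change = _per_eye_change(table, phenotype, eye)
    usage = table.groupby("participant_id")["cpap_usage_hr_per_night"].first()
    pct = (
        table.groupby("participant_id")["pct_nights_over_4hr"].first()
        if "pct_nights_over_4hr" in table.columns
        else None
    )
    adherence = categorize_adherence(usage.values, None if pct is None else pct.values)
    col = "adherence_mean" if cfg.adherence_definition == "mean" else "adherence_nightly"
    labels = pd.Series(adherence[col].values, index=usage.index)
    change["adherence"] = change["participant_id"].map(labels)
    g_opt = change.loc[change["adherence"] == "optimal", "change"].to_numpy(float)
    g_sub = change.loc[change["adherence"] == "sub_optimal", "change"].to_numpy(float)
    if len(g_opt) < 3 or len(g_sub) < 3:
        return None
    if np.ptp(g_opt) == 0 and np.ptp(g_sub) == 0 and g_opt[0] == g_sub[0]:
        return GroupComparisonResult(
            variable=phenotype, eye=eye, group_labels=("optimal", "sub_optimal"),
            test_used="none", statistic=None, p_value=None,
            n_groups=(len(g_opt), len(g_sub)),
            group_means=(float(g_opt.mean()), float(g_sub.mean())),
            note="degenerate: identical constant changes in both groups",
        )
    test = _choose_test(g_opt, g_sub)
    if test == "t-test":
        stat, p = sps.ttest_ind(g_opt, g_sub)
    else:
        stat, p = sps.mannwhitneyu(g_opt, g_sub, alternative="two-sided")
    return GroupComparisonResult(
        variable=phenotype, eye=eye, group_labels=("optimal", "sub_optimal"),
        test_used=test, statistic=float(stat), p_value=float(p),
        n_groups=(len(g_opt), len(g_sub)),
        group_means=(float(g_opt.mean()), float(g_sub.mean())),
    )


def fit_gee_change_on_usage(
    table: pd.DataFrame,
    phenotype: str,
    covariates: list[str] | None = None,
    config: GEEConfig | None = None,
) -> GEEResult:
    """Δphenotype (follow-up − baseline, per eye) regressed on average CPAP
    usage, clustered by participant, standardized coefficients."""
    cfg = config or GEEConfig()
    covs = DEFAULT_COVARIATES if covariates is None else covariates
    pieces = []
    for eye in sorted(table["eye"].unique()):
        ch = _per_eye_change(table, phenotype, eye)
        ch["eye"] = eye
        pieces.append(ch)
    change = pd.concat(pieces, ignore_index=True)
    if change.empty:
        raise ValueError("no participants with both visits")
    base = table[table["visit"] == "baseline"].drop_duplicates(["participant_id", "eye"])
    merged = change.merge(
        base[["participant_id", "eye", "cpap_usage_hr_per_night", *covs]],
        on=["participant_id", "eye"],
        how="left",
    )
    if merged["cpap_usage_hr_per_night"].std(ddof=0) == 0:
        raise ValueError("CPAP usage has zero variance across the cohort")
    return _fit_gee(
        merged,
        "change",
        "cpap_usage_hr_per_night",
        covs,
        cfg,
        f"delta_{phenotype}",
        "cpap_usage_hr_per_night",
        len(merged),
    )


def thickness_comparisons(
    table: pd.DataFrame,
    regions: list[str] | None = None,
    config: GEEConfig | None = None,
) -> list[GroupComparisonResult]:
    """Device-thickness analyses: baseline moderate-vs-severe comparison per
    macular region (test chosen by the normality gate), then pre/post
    paired t-tests per region within each OSA-severity × adherence group.
    Cells with fewer than 3 participants are skipped."""
    cfg = config or GEEConfig()
    regs = [r for r in (regions or THICKNESS_REGIONS) if r in table.columns]
    results: list[GroupComparisonResult] = []
    severity = categorize_severity(
        table.groupby("participant_id")["pahi"].first().values
    )
    sev = pd.Series(
        severity.values, index=table.groupby("participant_id")["pahi"].first().index
    )
    usage = table.groupby("participant_id")["cpap_usage_hr_per_night"].first()
    pct = (
        table.groupby("participant_id")["pct_nights_over_4hr"].first()
        if "pct_nights_over_4hr" in table.columns
        else None
    )
    adher = categorize_adherence(usage.values, None if pct is None else pct.values)
    col = "adherence_mean" if cfg.adherence_definition == "mean" else "adherence_nightly"
    adh = pd.Series(adher[col].values, index=usage.index)

    base = table[table["visit"] == "baseline"]
    for region in regs:
        # cross-sectional: moderate vs severe at baseline (eyes pooled per participant)
        per_part = base.groupby("participant_id")[region].mean()
        g_mod = per_part[sev.reindex(per_part.index) == "moderate"].dropna().to_numpy(float)
        g_sev = per_part[sev.reindex(per_part.index) == "severe"].dropna().to_numpy(float)
        if len(g_mod) >= 3 and len(g_sev) >= 3:
            test = _choose_test(g_mod, g_sev)
            if test == "t-test":
                stat, p = sps.ttest_ind(g_mod, g_sev)
            else:
                stat, p = sps.mannwhitneyu(g_mod, g_sev, alternative="two-sided")
            results.append(
                GroupComparisonResult(
                    variable=region, eye=None, group_labels=("moderate", "severe"),
                    test_used=test, statistic=float(stat), p_value=float(p),
                    n_groups=(len(g_mod), len(g_sev)),
                    group_means=(float(g_mod.mean()), float(g_sev.mean())),
                )
            )
        # longitudinal paired t-tests within severity × adherence
        for sev_group in ("moderate", "severe"):
            for adh_group in ("optimal", "sub_optimal"):
                ids = sev.index[(sev == sev_group) & (adh.reindex(sev.index) == adh_group)]
                sub = table[table["participant_id"].isin(ids)]
                wide = sub.pivot_table(
                    index="participant_id", columns="visit", values=region, aggfunc="mean"
                )
                if not {"baseline", "followup"} <= set(wide.columns):
                    continue
                paired = wide.dropna()
                if len(paired) < 3:
                    continue
                pre = paired["baseline"].to_numpy(float)
                post = paired["followup"].to_numpy(float)
                diff = post - pre
                if np.ptp(diff) == 0:
                    note = "zero-variance paired differences"
                    stat_v, p_v = None, None
                else:
                    t = sps.ttest_rel(post, pre)
                    stat_v, p_v, note = float(t.statistic), float(t.pvalue), ""
                results.append(
                    GroupComparisonResult(
                        variable=region, eye=None,
                        group_labels=(f"{sev_group}/{adh_group}", "pre-vs-post"),
                        test_used="paired-t", statistic=stat_v, p_value=p_v,
                        n_groups=(len(paired), len(paired)),
                        group_means=(float(pre.mean()), float(post.mean())),
                        note=note,
                    )
                )
    return results
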