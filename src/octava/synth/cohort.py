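"""Two-eye cohort simulator with known standardized effect sizes.

Emulates the study design the association analyses expect: each
participant contributes up to two eyes per visit (baseline / follow-up),
phenotypes are correlated between fellow eyes through a participant
random intercept, and configurable outcomes are built as

    outcome = Σ_j β_j · z(phenotype_j) + b_i + ε,    b_i ⊥ ε

with Var(b_i) + Var(ε) scaled so the configured standardized β is the
true marginal coefficient and ``within_participant_corr`` is the ICC of
the residual between fellow eyes.  Follow-up changes can be tied to CPAP
usage with the same standardized-coefficient convention.  Covariate and
phenotype marginals are plausible for a middle-aged sleep-apnoea cohort;
they are documented defaults, not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSimParams", "generate_cohort"]

# phenotype panel: (mean, sd, lower clip, upper clip)
_PHENOTYPES: dict[str, tuple[float, float, float | None, float | None]] = {
    "parafoveal_vd": (0.36, 0.030, 0.0, 1.0),
    "foveal_vd": (0.20, 0.040, 0.0, 1.0),
    "branching_points": (120.0, 20.0, 0.0, None),
    "faz_area_mm2": (0.28, 0.080, 0.02, None),
    "tortuosity_large": (1.12, 0.030, 1.0, None),
    "tortuosity_small": (1.15, 0.030, 1.0, None),
    "radius_large_um": (13.5, 1.2, 5.0, None),
    "radius_small_um": (7.5, 0.8, 2.0, None),
    "ks_score": (0.25, 0.080, 0.0, 1.0),
    "symmetry_ratio": (0.78, 0.060, 0.05, 1.0),
    "bifurcation_distance_large_um": (180.0, 30.0, 20.0, None),
    "bifurcation_distance_small_um": (120.0, 25.0, 20.0, None),
    "prnfl_thickness_um": (97.0, 9.0, 40.0, None),
    "mac_foveal_um": (270.0, 20.0, 150.0, None),
    "mac_superior_um": (335.0, 18.0, 200.0, None),
    "mac_nasal_um": (332.0, 18.0, 200.0, None),
    "mac_inferior_um": (330.0, 18.0, 200.0, None),
    "mac_temporal_um": (320.0, 18.0, 200.0, None),
    "macular_volume_mm3": (8.5, 0.40, 5.0, None),
}


@dataclass(frozen=True)
class CohortSimParams:
    n_participants: int = 500
    eyes_per_participant: int = 2
    # outcome column -> {phenotype column: standardized beta}
    effect_sizes: dict[str, dict[str, float]] = field(default_factory=dict)
    # phenotype column -> standardized beta of follow-up change on CPAP usage
    change_effect_sizes: dict[str, float] = field(default_factory=dict)
    within_participant_corr: float = 0.5
    missing_followup_fraction: float = 0.0
    missing_eye_fraction: float = 0.0
    with_followup: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.eyes_per_participant not in (1, 2):
            raise ValueError("eyes_per_participant must be 1 or 2")
        if not (0 <= self.within_participant_corr < 1):
            raise ValueError("within_participant_corr must be in [0, 1)")
        for frac in (self.missing_followup_fraction, self.missing_eye_fraction):
            if not (0 <= frac < 1):
                raise ValueError("missing fractions must be in [0, 1)")
        for eff in self.effect_sizes.values():
            for b in eff.values():
                if not np.isfinite(b):
                    raise ValueError("effect sizes must be finite")


def _clustered_z(rng: np.random.Generator, n_part: int, n_eyes: int, rho: float) -> np.ndarray:
    """(n_part, n_eyes) unit-variance draws with between-eye correlation rho."""
    zp = rng.standard_normal((n_part, 1))
    ze = rng.standard_normal((n_part, n_eyes))
    return np.sqrt(rho) * zp + np.sqrt(1.0 - rho) * ze


def generate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-format cohort table (one row per eye-visit).

    Returns the table and a dict of the true effects used, for test
    oracles.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    n_eyes = params.eyes_per_participant
    rho = params.within_participant_corr
    eyes = ["OD", "OS"][:n_eyes]

    # participant-level covariates
    part = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age": rng.normal(50.1, 9.1, n).clip(25, 80),
            "sex_female": rng.binomial(1, 0.33, n),
            "sbp": rng.normal(135.0, 15.0, n).clip(90, 210),
            "bmi": rng.normal(34.8, 6.1, n).clip(18, 60),
            "diabetes": rng.binomial(1, 0.09, n),
            "hypercholesterolemia": rng.binomial(1, 0.28, n),
            "smoker": rng.binomial(1, 0.186, n),
            "pahi": rng.normal(53.7, 24.7, n).clip(15.1, 140.0),
            "spo2_mean": rng.normal(92.9, 2.0, n).clip(80, 100),
            "spo2_nadir": rng.normal(75.7, 9.3, n).clip(50, 95),
            "icv_ml": rng.normal(1476.0, 161.0, n).clip(1000, 2000),
            "bg_roi_volume_ml": rng.normal(55.0, 6.0, n).clip(35, 80),
            "cso_roi_volume_ml": rng.normal(400.0, 40.0, n).clip(250, 550),
            "fazekas": np.clip(np.round(rng.normal(1.8, 1.0, n)), 0, 6),
            "deep_atrophy": np.clip(np.round(rng.normal(1.3, 0.8, n)), 0, 6),
            "superficial_atrophy": np.clip(np.round(rng.normal(1.3, 0.8, n)), 0, 6),
            "pvs_bg_count": np.round(rng.normal(130.0, 40.0, n).clip(20, 400)),
            "pvs_cso_count": np.round(rng.normal(600.0, 180.0, n).clip(100, 1500)),
        }
    )
    part["wmh_volume_ml"] = np.exp(rng.normal(0.0, 0.7, n)).clip(0.05, 30.0)
    part["pvs_bg_volume_ml"] = rng.normal(2.0, 0.6, n).clip(0.3, None) / 100.0 * part["bg_roi_volume_ml"]
    part["pvs_cso_volume_ml"] = rng.normal(3.1, 1.2, n).clip(0.4, None) / 100.0 * part["cso_roi_volume_ml"]

    # CPAP usage: mixture so both adherence classes are populated
    optimal = rng.random(n) < 0.55
    usage = np.where(
        optimal, rng.normal(6.7, 0.9, n), rng.normal(3.0, 1.3, n)
    ).clip(0.0, 12.0)
    part["cpap_usage_hr_per_night"] = usage
    part["pct_nights_over_4hr"] = (80.0 + 8.0 * (usage - 4.0) + rng.normal(0, 8, n)).clip(0, 100)
    part["days_of_treatment"] = rng.normal(135.0, 40.0, n).clip(30, 300)

    # eye-level image quality and phenotype latents
    quality = _clustered_z(rng, n, n_eyes, rho)
    latents = {name: _clustered_z(rng, n, n_eyes, rho) for name in _PHENOTYPES}

    rows = []
    for j, eye in enumerate(eyes):
        df = part.copy()
        df["eye"] = eye
        df["visit"] = "baseline"
        df["image_quality"] = np.clip(8.0 + quality[:, j], 4.0, 10.0)
        for name, (mu, sd, lo, hi) in _PHENOTYPES.items():
            df[name] = np.clip(mu + sd * latents[name][:, j], lo, hi)
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)

    # configured outcomes: standardized-β construction on the latent scale
    z_usage = (usage - usage.mean()) / usage.std()
    for outcome, betas in params.effect_sizes.items():
        resvar = max(1.0 - sum(b**2 for b in betas.values()), 0.04)
        noise = _clustered_z(rng, n, n_eyes, rho) * np.sqrt(resvar)
        vals = noise.copy()
        for phen, beta in betas.items():
            if phen not in latents:
                raise KeyError(f"unknown phenotype {phen!r} in effect_sizes")
            vals = vals + beta * latents[phen]
        for j, eye in enumerate(eyes):
            table.loc[table["eye"] == eye, outcome] = vals[:, j]

    # follow-up visit with usage-linked change
    if params.with_followup:
        has_fup = rng.random(n) >= params.missing_followup_fraction
        keep = np.flatnonzero(has_fup)
        change_noise = {
            name: _clustered_z(rng, len(keep), n_eyes, rho) for name in _PHENOTYPES
        }
        fup_rows = []
        for j, eye in enumerate(eyes):
            base = table[(table["eye"] == eye) & (table["visit"] == "baseline")].iloc[keep].copy()
            base["visit"] = "followup"
            for name, (mu, sd, lo, hi) in _PHENOTYPES.items():
                gamma = params.change_effect_sizes.get(name, 0.0)
                dz = gamma * z_usage[keep] + np.sqrt(max(1 - gamma**2, 0.04)) * change_noise[name][:, j]
                base[name] = np.clip(base[name] + 0.5 * sd * dz, lo, hi)
            fup_rows.append(base)
        table = pd.concat([table] + fup_rows, ignore_index=True)

    # optionally drop the second eye for a subset of participants
    if n_eyes == 2 and params.missing_eye_fraction > 0:
        drop_eye = rng.random(n) < params.missing_eye_fraction
        dropped = {f"P{i:04d}" for i in np.flatnonzero(drop_eye)}
        table = table[~((table["participant_id"].isin(dropped)) & (table["eye"] == "OS"))]
        table = table.reset_index(drop=True)

    table = table.sort_values(["participant_id", "visit", "eye"]).reset_index(drop=True)
    truth = {
        "effect_sizes": params.effect_sizes,
        "change_effect_sizes": params.change_effect_sizes,
        "within_participant_corr": rho,
    }
    return table, truth
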