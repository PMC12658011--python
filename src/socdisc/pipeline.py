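"""End-to-end orchestration: raw choices → discounting metrics → inference.

Stage order: exclusions → income recoding → indifference profiles →
per-participant hyperbolic fits (logk) and AUC → pooled model comparison →
group/continuous regressions (the logk/AUC multiverse pair) → subscale
regression → mediation (dichotomous and continuous) → moderation and
age-moderation → reliability → cross-validation and propensity-matching
robustness. Every output table carries the configuration hash; timestamps
are isolated to the run log so result bundles are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import synthetic, task, models, stats, mediation, reliability
from .errors import ConfigError, DataError

COVARIATES = ["age", "gender_male", "income", "fluid_intelligence"]

STAGES = ("generate", "fit", "analyze", "report")


@dataclass
class RunConfig:
    """Single configuration object driving the whole pipeline."""

    cohort: synthetic.CohortConfig | None = None
    participants_csv: str | None = None
    choices_csv: str | None = None
    v0_mode: str = "free"
    v0_value: float = 85.0
    k_floor: float = models.K_FLOOR
    use_aicc: bool = False
    mediation_method: str = "quasi_bayesian"
    mediation_sims: int = 1000
    matching_caliper: float = 0.2
    cv_folds: int = 10
    seed: int = 20240817
    output_dir: str = "socdisc_output"
    stop_after: str = "report"
    make_figure: bool = True

    def __post_init__(self) -> None:
        file_input = self.participants_csv is not None and self.choices_csv is not None
        if self.cohort is None and not file_input:
            self.cohort = synthetic.CohortConfig(seed=self.seed)
        if self.cohort is not None and file_input:
            raise ConfigError("provide either a synthetic cohort config or input CSVs, not both")
        if self.stop_after not in STAGES:
            raise ConfigError(f"stop_after must be one of {STAGES}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort is not None:
            cfg.cohort = synthetic.CohortConfig(**cohort)
        return cfg


def run_config_hash(config: RunConfig) -> str:
    fields = dataclasses.asdict(config)
    # Presentation-only settings do not alter results, so they stay out of
    # the hash: identical analyses hash identically wherever they are written.
    for skip in ("output_dir", "make_figure", "stop_after"):
        fields.pop(skip, None)
    payload = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Input readers

REQUIRED_CHOICE_COLUMNS = ["participant_id", "social_distance", "trial_index", "selfish_amount", "choice"]


def read_choices(path: str) -> dict[str, list[task.ChoiceBlock]]:
    """Validated choice blocks per participant from long-format CSV."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"choices file missing column(s) {missing}")
    bad_label = df[~df["choice"].isin(["selfish", "generous"])]
    if len(bad_label):
        row = bad_label.index[0]
        raise DataError(f"row {row}: choice label {bad_label['choice'].iloc[0]!r} not in {{selfish, generous}}")
    bad_dist = df[~df["social_distance"].isin(task.SOCIAL_DISTANCES)]
    if len(bad_dist):
        row = bad_dist.index[0]
        raise DataError(f"row {row}: social distance {bad_dist['social_distance'].iloc[0]} not canonical")
    dup = df.duplicated(subset=["participant_id", "social_distance", "trial_index"])
    if dup.any():
        raise DataError(f"row {int(np.where(dup)[0][0])}: duplicate (participant, distance, trial)")

    blocks: dict[str, list[task.ChoiceBlock]] = {}
    for (pid, dist), grp in df.groupby(["participant_id", "social_distance"], sort=True):
        if len(grp) != 9:
            raise DataError(f"participant {pid} block N={dist} has {len(grp)} trials, expected 9")
        grp = grp.sort_values("trial_index")
        blocks.setdefault(str(pid), []).append(
            task.ChoiceBlock(social_distance=int(dist), choices=tuple(grp["choice"]))
        )
    return blocks


def read_participants(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "participant_id" not in df.columns:
        raise DataError("participants file missing column 'participant_id'")
    return df


# ---------------------------------------------------------------------------
# Stage helpers

def _apply_exclusions(df: pd.DataFrame, log: list[str]) -> pd.DataFrame:
    bad = df[(df["attention_failures"] < 0) | (df["attention_failures"] > 4)]
    if len(bad):
        raise DataError(f"attention_failures outside 0-4 for {list(bad['participant_id'])}")
    excluded = df[df["attention_failures"] >= 2]
    for _, row in excluded.iterrows():
        log.append(
            f"excluded {row['participant_id']}: failed {row['attention_failures']} of 4 attention checks"
        )
    log.append(f"exclusions: {len(excluded)} of {len(df)} participants removed")
    return df[df["attention_failures"] < 2].reset_index(drop=True)


def _recode_income(df: pd.DataFrame, log: list[str]) -> pd.DataFrame:
    df = df.copy()
    income = df["income_bracket"].astype(str)
    known = pd.to_numeric(income[income != "dont_know"], errors="raise")
    if known.empty:
        raise DataError("cannot recode income: no known brackets")
    mean_bracket = int(math.floor(known.mean() + 0.5))
    n_recode = int((income == "dont_know").sum())
    df["income"] = np.where(income == "dont_know", mean_bracket, pd.to_numeric(income, errors="coerce"))
    df["income"] = df["income"].astype(float)
    log.append(f"income recode: {n_recode} 'don't know' set to mean bracket {mean_bracket}")
    return df


def _profiles_frame(blocks_by_pid: dict[str, list[task.ChoiceBlock]], pids: list[str]) -> tuple[pd.DataFrame, dict[str, task.IndifferenceProfile]]:
    rows = []
    profiles = {}
    for pid in pids:
        if pid not in blocks_by_pid:
            raise DataError(f"participant {pid} has no choice data")
        profile = task.build_profile(blocks_by_pid[pid])
        profiles[pid] = profile
        for n, ip, v, flag in zip(
            profile.social_distances, profile.indifference_points, profile.forgone_v, profile.violations
        ):
            rows.append(
                {
                    "participant_id": pid,
                    "social_distance": n,
                    "indifference_point": ip,
                    "v": v,
                    "violation_flag": int(flag),
                }
            )
    return pd.DataFrame(rows), profiles


def _fits_frame(profiles: dict[str, task.IndifferenceProfile], options: models.FitOptions) -> pd.DataFrame:
    rows = []
    for pid, profile in profiles.items():
        fit = models.fit_participant(profile, "hyperbolic", options)
        auc = models.compute_auc(profile)
        rows.append(
            {
                "participant_id": pid,
                "family": fit.family,
                "V0": fit.v0,
                "k": fit.k,
                "logk": fit.logk,
                "rss": fit.rss,
                "aic": fit.aic,
                "converged": int(fit.converged),
                "k_floored": int(fit.k_floored),
                "degenerate": int(fit.degenerate),
                "auc": auc.auc,
                "n_violations": profile.n_violations,
            }
        )
    return pd.DataFrame(rows)


def _regression_table(result: stats.RegressionResult) -> pd.DataFrame:
    rows = []
    for t in result.terms:
        rows.append(
            {
                "Variable": t.name,
                "b": t.b,
                "se": t.se,
                "CI_low": t.ci_low,
                "CI_high": t.ci_high,
                "Std_B": t.std_b,
                "Std_se": t.std_se,
                "Std_CI_low": t.std_ci_low,
                "Std_CI_high": t.std_ci_high,
                "p": t.p,
            }
        )
    return pd.DataFrame(rows)


def _regression_text(title: str, result: stats.RegressionResult) -> str:
    lines = [title, "Variable\tb (se)\tCI\tStd. B (se)\tStd. CI\tp"]
    for t in result.terms:
        lines.append(
            f"{t.name}\t{t.b:.2f} ({t.se:.2f})\t{t.ci_low:.2f}–{t.ci_high:.2f}\t"
            f"{t.std_b:.2f} ({t.std_se:.2f})\t{t.std_ci_low:.2f}–{t.std_ci_high:.2f}\t{t.p:.3g}"
        )
    lines.append(
        f"F({result.df1:.0f},{result.df2:.0f}) = {result.f_stat:.2f}, p = {result.f_p:.3g}, "
        f"Adjusted R^2 = {result.adj_r2:.2f}"
    )
    return "\n".join(lines)


def _effect_dict(e: mediation.EffectSummary) -> dict:
    return {"point": e.point, "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p}


def _mediation_dict(res: mediation.MediationResult) -> dict:
    return {
        "acme": _effect_dict(res.acme),
        "ade": _effect_dict(res.ade),
        "total": _effect_dict(res.total),
        "prop_mediated": _effect_dict(res.prop_mediated),
        "sims": res.sims,
        "seed": res.seed,
        "method": res.method,
        "treatment_contrast": res.treatment_contrast,
        "assumptions": "linear models, no treatment-mediator interaction; sims/CI method are package defaults (unreported in the source analyses)",
    }


def plot_discounting_curves(analysis: pd.DataFrame, profiles_df: pd.DataFrame, path: str) -> None:
    """Mean v-vs-N curve per group with fitted hyperbolic overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    merged = profiles_df.merge(analysis[["participant_id", "group"]], on="participant_id")
    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(1, 100, 200)
    for group, color in (("control", "tab:blue"), ("high", "tab:red")):
        sub = merged[merged["group"] == group]
        if sub.empty:
            continue
        means = sub.groupby("social_distance")["v"].mean()
        sems = sub.groupby("social_distance")["v"].sem()
        ax.errorbar(means.index, means.values, yerr=sems.values, fmt="o", color=color, label=group)
        gk = float(np.exp(analysis.loc[analysis["group"] == group, "logk"].median()))
        ax.plot(grid, task.MAX_FORGONE / (1 + gk * grid), color=color, alpha=0.6)
    ax.set_xlabel("Social distance (N)")
    ax.set_ylabel("Amount willing to forgo, v ($)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Orchestration

def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the in-memory result bundle."""
    t0 = time.time()
    cfg_hash = run_config_hash(config)
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    log: list[str] = [f"config_hash={cfg_hash}", f"seed={config.seed}"]
    bundle: dict = {"config_hash": cfg_hash, "seed": config.seed}

    def write_csv(df: pd.DataFrame, name: str) -> None:
        with open(os.path.join(outdir, name), "w", newline="") as fh:
            fh.write(f"# socdisc config_hash={cfg_hash} seed={config.seed}\n")
            df.to_csv(fh, index=False)

    def write_json(obj: dict, name: str) -> None:
        obj = {"config_hash": cfg_hash, **obj}
        with open(os.path.join(outdir, name), "w") as fh:
            json.dump(obj, fh, indent=2, default=float)
            fh.write("\n")

    # --- input stage -------------------------------------------------------
    if config.cohort is not None:
        records = synthetic.generate_cohort(config.cohort)
        participants = synthetic.participants_frame(records)
        choices_df = synthetic.choices_frame(records)
        write_csv(participants, "participants.csv")
        write_csv(choices_df, "choices.csv")
        blocks_by_pid = {r.id: r.choice_blocks for r in records}
        log.append(f"generated synthetic cohort: n={len(records)}")
    else:
        participants = read_participants(config.participants_csv)
        blocks_by_pid = read_choices(config.choices_csv)
        log.append(f"read cohort from files: n={len(participants)}")
    if config.stop_after == "generate":
        _finish(outdir, log, t0)
        return bundle

    # --- cleaning ----------------------------------------------------------
    participants = _apply_exclusions(participants, log)
    participants = _recode_income(participants, log)
    participants["group_high"] = (participants["group"] == "high").astype(int)
    participants["gender_male"] = (participants["gender"] == "male").astype(int)

    # --- discounting -------------------------------------------------------
    pids = list(participants["participant_id"].astype(str))
    profiles_df, profiles = _profiles_frame(blocks_by_pid, pids)
    options = models.FitOptions(
        v0_mode=config.v0_mode, v0_value=config.v0_value, k_floor=config.k_floor, use_aicc=config.use_aicc
    )
    fits_df = _fits_frame(profiles, options)
    write_csv(profiles_df, "profiles.csv")
    write_csv(fits_df, "fits.csv")
    log.append(f"profiles with monotonicity violations: {int((fits_df['n_violations'] > 0).sum())}")
    log.append(f"fits with k at floor: {int(fits_df['k_floored'].sum())}")

    pooled = {
        fam: models.fit_pooled(list(profiles.values()), fam, options) for fam in models.FAMILIES
    }
    comparison = models.compare_models({fam: f.aic for fam, f in pooled.items()})
    write_json(
        {
            "aic": comparison.aic,
            "delta_aic": comparison.delta_aic,
            "akaike_weight": comparison.akaike_weight,
            "best_family": comparison.best_family,
        },
        "model_comparison.json",
    )
    bundle["model_comparison"] = comparison
    bundle["fits"] = fits_df
    bundle["profiles"] = profiles_df
    if config.stop_after == "fit":
        _finish(outdir, log, t0)
        return bundle

    # --- joined analysis table --------------------------------------------
    analysis = participants.merge(fits_df[["participant_id", "logk", "auc"]], on="participant_id")
    bundle["analysis"] = analysis
    n_high = int(analysis["group_high"].sum())
    n_control = int(len(analysis) - n_high)
    group_ok = n_high > 1 and n_control > 1
    if not group_ok:
        log.append("NOTICE: a group is (nearly) empty; group-based analyses skipped, continuous analyses run")

    # --- descriptives (Table 1 layout) -------------------------------------
    if group_ok:
        ctrl = analysis[analysis["group_high"] == 0]
        high = analysis[analysis["group_high"] == 1]
        rows = []
        for var in ("tripm_total", "stab_total", "age", "fluid_intelligence", "logk", "auc"):
            cmp_res = stats.welch_test(ctrl[var], high[var])
            rows.append(
                {
                    "variable": var,
                    "control_mean": ctrl[var].mean(),
                    "control_sd": ctrl[var].std(ddof=1),
                    "high_mean": high[var].mean(),
                    "high_sd": high[var].std(ddof=1),
                    "t": cmp_res.statistic,
                    "df": cmp_res.df,
                    "p": cmp_res.p,
                    "cohens_d": cmp_res.cohens_d,
                    "d_ci_low": cmp_res.d_ci_low,
                    "d_ci_high": cmp_res.d_ci_high,
                }
            )
        gender_table = pd.crosstab(analysis["gender"], analysis["group_high"])
        chi = stats.chi_squared_test(gender_table.to_numpy())
        table1 = pd.DataFrame(rows)
        write_csv(table1, "table1.csv")
        bundle["table1"] = table1
        bundle["gender_chi2"] = chi

    # --- regressions: the logk/AUC multiverse pair always together ---------
    regressions: dict[str, stats.RegressionResult] = {}
    if group_ok:
        regressions["group_logk"] = stats.fit_ols(analysis, "logk", ["group_high"], COVARIATES)
        regressions["group_auc"] = stats.fit_ols(analysis, "auc", ["group_high"], COVARIATES)
    regressions["tripm_logk"] = stats.fit_ols(analysis, "logk", ["tripm_total"], COVARIATES)
    regressions["tripm_auc"] = stats.fit_ols(analysis, "auc", ["tripm_total"], COVARIATES)
    regressions["subscales_logk"] = stats.fit_ols(
        analysis, "logk", ["tripm_boldness", "tripm_meanness", "tripm_disinhibition"], COVARIATES
    )
    name_map = {
        "group_logk": "table3",
        "tripm_logk": "table4",
        "group_auc": "table3_auc",
        "tripm_auc": "table4_auc",
        "subscales_logk": "table_subscales",
    }
    text_blocks = []
    for key, res in regressions.items():
        write_csv(_regression_table(res), f"{name_map[key]}.csv")
        text_blocks.append(_regression_text(f"[{name_map[key]}] {key}", res))
    bundle["regressions"] = regressions

    # --- criminal-history odds ratios ---------------------------------------
    if group_ok and analysis["committed_crime"].nunique() == 2:
        bundle["crime_or"] = stats.fit_logistic_or(analysis, "committed_crime", "group_high", COVARIATES)
        bundle["crime_or_unadjusted"] = stats.fit_logistic_or(analysis, "committed_crime", "group_high")
        log.append(f"crime OR (adjusted): {bundle['crime_or'].or_value:.2f}")

    # --- mediation ----------------------------------------------------------
    med_out: dict = {}
    if group_ok:
        med_out["dichotomous"] = _mediation_dict(
            mediation.mediate(
                analysis, "stab_total", "group_high", "logk", COVARIATES,
                sims=config.mediation_sims, seed=config.seed + 1, method=config.mediation_method,
            )
        )
    med_out["continuous"] = _mediation_dict(
        mediation.mediate(
            analysis, "stab_total", "tripm_total", "logk", COVARIATES,
            sims=config.mediation_sims, seed=config.seed + 2, method=config.mediation_method,
            treatment_contrast=2 * float(analysis["tripm_total"].std(ddof=1)),
        )
    )
    write_json(med_out, "mediation.json")
    bundle["mediation"] = med_out

    # --- moderation ---------------------------------------------------------
    moderations: dict[str, stats.RegressionResult] = {}
    if group_ok:
        moderations["stab_logk_x_group"] = stats.fit_moderation(
            analysis, "stab_total", "logk", "group_high", COVARIATES
        )
        moderations["logk_age_x_group"] = stats.fit_moderation(
            analysis, "logk", "group_high", "age", ["gender_male", "income", "fluid_intelligence"]
        )
    moderations["stab_logk_x_tripm"] = stats.fit_moderation(
        analysis, "stab_total", "logk", "tripm_total", COVARIATES
    )
    moderations["logk_age_x_tripm"] = stats.fit_moderation(
        analysis, "logk", "tripm_total", "age", ["gender_male", "income", "fluid_intelligence"]
    )
    for key, res in moderations.items():
        write_csv(_regression_table(res), f"moderation_{key}.csv")
    bundle["moderations"] = moderations

    # --- reliability --------------------------------------------------------
    alpha = reliability.cronbach_alpha(
        analysis[["tripm_boldness", "tripm_meanness", "tripm_disinhibition"]].to_numpy()
    )
    rel_out = {
        "tripm_component_alpha": {
            "value": alpha.value, "n_units": alpha.n_units, "n_items": alpha.n_items_or_raters,
            "note": "internal consistency across the three subscale components (item-level data are not modeled)",
        }
    }
    if group_ok:
        # Synthetic two-rater screening-interview scores for a high-group
        # subsample, emulating the double-rated follow-up interviews.
        high = analysis[analysis["group_high"] == 1]
        sub = high.head(min(44, len(high)))
        rng = np.random.default_rng(config.seed + 3)
        latent = sub["tripm_total"].to_numpy() * 24.0 / 174.0
        ratings = latent[:, None] + rng.normal(0, 2.0, size=(len(sub), 2))
        icc = reliability.icc_oneway(ratings)
        rel_out["interview_icc1"] = {
            "value": icc.value, "ci_low": icc.ci_low, "ci_high": icc.ci_high,
            "n_targets": icc.n_units, "n_raters": icc.n_items_or_raters,
            "note": "synthetic rater emulation (one-way random effects, single rater, absolute)",
        }
    write_json(rel_out, "reliability.json")
    bundle["reliability"] = rel_out

    # --- robustness ---------------------------------------------------------
    robust: dict = {}
    if group_ok:
        cv = reliability.kfold_cv(
            analysis, "logk", ["group_high"] + COVARIATES, k=min(config.cv_folds, len(analysis)),
            seed=config.seed + 4,
        )
        write_csv(cv.fold_coefs.assign(oof_r2=cv.oof_r2), "cv.csv")
        robust["cv"] = cv
        match = reliability.propensity_match(
            analysis, "group_high", COVARIATES, caliper=config.matching_caliper
        )
        pairs_df = pd.DataFrame(match.matched_pairs, columns=["treated_id", "control_id"])
        write_csv(pairs_df, "matching.csv")
        smd_df = pd.DataFrame(
            {"covariate": list(match.smd_before), "smd_before": list(match.smd_before.values()),
             "smd_after": list(match.smd_after.values())}
        )
        write_csv(smd_df, "matching_smd.csv")
        robust["match"] = match
        matched_ids = set(pairs_df["treated_id"]) | set(pairs_df["control_id"])
        matched = analysis[analysis["participant_id"].astype(str).isin(matched_ids)]
        if len(matched) > 10:
            robust["matched_group_logk"] = stats.fit_ols(matched, "logk", ["group_high"], COVARIATES)
            write_csv(_regression_table(robust["matched_group_logk"]), "table3_matched.csv")
        log.append(
            f"matching: {len(pairs_df)} pairs, {len(match.unmatched_treated)} treated unmatched"
        )
    bundle["robustness"] = robust
    if config.stop_after == "analyze":
        _finish(outdir, log, t0)
        return bundle

    # --- report -------------------------------------------------------------
    if config.make_figure:
        plot_discounting_curves(analysis, profiles_df, os.path.join(outdir, "discounting_curves.png"))
    summary = _summary_text(cfg_hash, config, analysis, comparison, regressions, med_out, group_ok, log)
    with open(os.path.join(outdir, "summary.txt"), "w") as fh:
        fh.write(summary)
    with open(os.path.join(outdir, "tables.txt"), "w") as fh:
        fh.write("\n\n".join(text_blocks) + "\n")
    bundle["summary"] = summary
    _finish(outdir, log, t0)
    return bundle


def _summary_text(cfg_hash, config, analysis, comparison, regressions, med_out, group_ok, log) -> str:
    lines = [
        "socdisc pipeline summary",
        f"config_hash: {cfg_hash}",
        f"seed: {config.seed}",
        f"n analyzed: {len(analysis)} (high: {int(analysis['group_high'].sum())}, "
        f"control: {int((1 - analysis['group_high']).sum())})",
        f"social distances: {', '.join(str(n) for n in task.SOCIAL_DISTANCES)}",
        f"best-fitting family (pooled AIC): {comparison.best_family}",
        "Akaike weights: "
        + ", ".join(f"{fam}={w:.3f}" for fam, w in comparison.akaike_weight.items()),
        "sign conventions: higher logk = steeper discounting; higher AUC = more generosity",
    ]
    if group_ok and "group_logk" in regressions:
        t = regressions["group_logk"].term("group_high")
        lines.append(f"group -> logk: b={t.b:.3f} (se {t.se:.3f}), Std. B={t.std_b:.3f}, p={t.p:.3g}")
    else:
        lines.append("group-based analyses skipped (a group is empty); continuous analyses reported")
    t = regressions["tripm_logk"].term("tripm_total")
    lines.append(f"TriPM -> logk: b={t.b:.4f}, Std. B={t.std_b:.3f}, p={t.p:.3g}")
    if "dichotomous" in med_out:
        acme = med_out["dichotomous"]["acme"]
        lines.append(
            f"mediation (group -> logk -> STAB): ACME={acme['point']:.3f} "
            f"[{acme['ci_low']:.3f}, {acme['ci_high']:.3f}], p={acme['p']:.3g}"
        )
    lines.append("")
    lines.extend(log)
    return "\n".join(lines) + "\n"


def _finish(outdir: str, log: list[str], t0: float) -> None:
    # The run log is the only artifact carrying wall-clock timestamps.
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write(f"finished {stamp} after {time.time() - t0:.1f}s\n")
        fh.write("\n".join(log) + "\n")
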