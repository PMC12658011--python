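"""Synthetic cohort generator emulating the study's statistical structure.

Generates a two-group cohort (controls vs. high-psychopathy) with:

* group-separated TriPM totals and correlated Boldness/Meanness/
  Disinhibition subscales that sum exactly to the total,
* a latent per-participant hyperbolic discount rate (logk) whose group
  difference has standardized magnitude ≈ 0.9,
* an antisocial-behavior (STAB) outcome built from group and latent logk
  plus Gaussian noise, embedding a nonzero indirect group→logk→STAB path,
* demographic covariates (age, gender, ordinal income with a "don't know"
  category, fluid intelligence), attention-check failures, and a binary
  lifetime-crime flag,
* binary task choices produced from the latent discount rate via a softmax
  (logistic-in-dollars) response rule; temperature 0 reproduces the
  deterministic threshold logic of the task.

Default moments mirror the study population the analysis is designed for;
they are deliberately fixed so every downstream stage is testable without
any external download.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.special import expit

from .errors import ConfigError, DataError
from .task import (
    MAX_FORGONE,
    SOCIAL_DISTANCES,
    ChoiceBlock,
    TrialSchedule,
    build_trial_schedule,
)

GROUPS = ("control", "high")

#: TriPM 95th-percentile cutoffs by gender used for group assignment.
DEFAULT_CUTOFFS: dict[str, float] = {"male": 105.0, "female": 91.0, "other": 91.0}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; pair-valued fields are ordered (control, high)."""

    n_control: int = 427
    n_high: int = 288
    tripm_mean_by_group: tuple[float, float] = (55.86, 122.25)
    tripm_sd_by_group: tuple[float, float] = (19.90, 16.92)
    logk_mean_by_group: tuple[float, float] = (-4.0, -2.5)
    logk_sd: float = 1.65
    #: STAB = intercept + group_effect·[high] + logk_effect·logk + N(0, noise_sd)
    stab_coefs: tuple[float, float, float, float] = (62.8, 35.0, 1.0, 18.0)
    age_mean_by_group: tuple[float, float] = (40.21, 31.50)
    age_sd_by_group: tuple[float, float] = (11.59, 8.92)
    age_range: tuple[int, int] = (18, 79)
    gender_probs: tuple[float, float, float] = (0.44, 0.52, 0.04)  # male, female, other
    income_probs: tuple[float, ...] = (0.13, 0.25, 0.20, 0.13, 0.08, 0.04, 0.05, 0.09)
    income_dont_know_prob: float = 0.03
    fluid_mean_by_group: tuple[float, float] = (5.57, 5.16)
    fluid_sd: float = 2.0
    attention_fail_probs: tuple[float, ...] = (0.955, 0.028, 0.010, 0.004, 0.003)
    #: P(committed any crime) = logistic(intercept + effect·[high])
    crime_logit_coefs: tuple[float, float] = (-0.336, 2.160)
    subscale_resid_sd: float = 6.0
    subscale_corr: float = 0.3
    choice_temperature: float = 2.0
    seed: int = 20240817

    def validate(self) -> None:
        if self.n_control <= 0:
            raise ConfigError("n_control must be > 0")
        if self.n_high <= 0:
            raise ConfigError("n_high must be > 0")
        for name in ("tripm_mean_by_group", "tripm_sd_by_group", "logk_mean_by_group",
                     "age_mean_by_group", "age_sd_by_group", "fluid_mean_by_group"):
            if len(getattr(self, name)) != 2:
                raise ConfigError(f"{name} must have exactly two entries (control, high)")
        for name in ("tripm_sd_by_group", "age_sd_by_group"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ConfigError(f"{name} entries must be > 0")
        if self.logk_sd <= 0:
            raise ConfigError("logk_sd must be > 0")
        if self.stab_coefs[3] <= 0:
            raise ConfigError("stab_coefs noise sd must be > 0")
        if self.fluid_sd <= 0:
            raise ConfigError("fluid_sd must be > 0")
        if self.choice_temperature < 0:
            raise ConfigError("choice_temperature must be >= 0")
        if len(self.income_probs) != 8:
            raise ConfigError("income_probs must list 8 bracket probabilities")
        for name in ("gender_probs", "income_probs", "attention_fail_probs"):
            p = getattr(self, name)
            if any(x < 0 for x in p):
                raise ConfigError(f"{name} must be nonnegative")
        if not 0 <= self.income_dont_know_prob < 1:
            raise ConfigError("income_dont_know_prob must be in [0, 1)")
        if not -1 < self.subscale_corr < 1:
            raise ConfigError("subscale_corr must be in (-1, 1)")


def config_hash(config: CohortConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ParticipantRecord:
    id: str
    group: str
    tripm_total: float
    tripm_boldness: float
    tripm_meanness: float
    tripm_disinhibition: float
    stab_total: float
    age: int
    gender: str
    income_bracket: int | None  # None encodes "don't know"
    fluid_intelligence: int
    attention_failures: int
    committed_crime: int
    latent_logk: float | None = None  # synthetic cohorts only
    choice_blocks: list[ChoiceBlock] = field(default_factory=list)


def simulate_choices(
    latent_logk: float,
    schedule: TrialSchedule | None = None,
    temperature: float = 0.0,
    seed: int = 0,
) -> list[ChoiceBlock]:
    """Binary choices from a latent hyperbolic discount rate.

    The generous option is worth v_N = 80/(1 + kN) at distance N; on a trial
    forgoing ``a`` dollars, P(generous) = logistic((v_N − a)/temperature).
    Temperature 0 is the deterministic threshold rule (generous iff a ≤ v_N).
    """
    schedule = schedule or build_trial_schedule()
    if temperature < 0:
        raise ConfigError("temperature must be >= 0")
    rng = np.random.default_rng(seed)
    k = math.exp(latent_logk)
    forgone = np.asarray(schedule.forgone_amounts(), dtype=float)
    blocks = []
    for n in schedule.social_distances:
        v_n = MAX_FORGONE / (1.0 + k * n)
        if temperature == 0:
            generous = forgone <= v_n
        else:
            generous = rng.random(len(forgone)) < expit((v_n - forgone) / temperature)
        blocks.append(
            ChoiceBlock(
                social_distance=n,
                choices=tuple("generous" if g else "selfish" for g in generous),
            )
        )
    return blocks


def assign_group(
    tripm_total: float,
    gender: str,
    cutoffs: dict[str, float] | None = None,
) -> str:
    """High-psychopathy iff the TriPM total meets the gender-specific cutoff."""
    cutoffs = cutoffs if cutoffs is not None else DEFAULT_CUTOFFS
    if gender not in cutoffs:
        raise ConfigError(f"no TriPM cutoff configured for gender {gender!r}")
    return "high" if tripm_total >= cutoffs[gender] else "control"


def apply_exclusions(
    records: list[ParticipantRecord],
) -> tuple[list[ParticipantRecord], list[tuple[ParticipantRecord, str]]]:
    """Drop participants failing two or more of the four attention checks."""
    retained, excluded = [], []
    for rec in records:
        if not 0 <= rec.attention_failures <= 4:
            raise DataError(f"participant {rec.id}: attention_failures {rec.attention_failures} outside 0-4")
        if rec.attention_failures >= 2:
            excluded.append((rec, f"failed {rec.attention_failures} of 4 attention checks"))
        else:
            retained.append(rec)
    return retained, excluded


def recode_income(records: list[ParticipantRecord]) -> list[ParticipantRecord]:
    """Replace "don't know" income with the full-sample mean bracket.

    The mean of the known ordinal codes is rounded half-up to the nearest
    bracket; all other participants are returned unchanged.
    """
    known = [r.income_bracket for r in records if r.income_bracket is not None]
    if not known:
        raise DataError("cannot recode income: no participant reported a known bracket")
    mean_bracket = int(math.floor(sum(known) / len(known) + 0.5))
    return [
        replace(r, income_bracket=mean_bracket) if r.income_bracket is None else r
        for r in records
    ]


def _draw_subscales(rng: np.random.Generator, totals: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    """Three correlated subscale scores per participant, summing to the total."""
    m = len(totals)
    rho, sd = cfg.subscale_corr, cfg.subscale_resid_sd
    cov = sd**2 * (np.full((3, 3), rho) + np.eye(3) * (1 - rho))
    resid = rng.multivariate_normal(np.zeros(3), cov, size=m)
    resid -= resid.mean(axis=1, keepdims=True)  # sum-zero so subscales add to total
    return totals[:, None] / 3.0 + resid


def generate_cohort(config: CohortConfig | None = None) -> list[ParticipantRecord]:
    """Draw a full cohort; reproducible given (config, seed)."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    schedule = build_trial_schedule()

    gender_probs = np.asarray(config.gender_probs, dtype=float)
    gender_probs = gender_probs / gender_probs.sum()
    income_probs = np.asarray(config.income_probs, dtype=float)
    income_probs = income_probs / income_probs.sum()
    att_probs = np.asarray(config.attention_fail_probs, dtype=float)
    att_probs = att_probs / att_probs.sum()

    records: list[ParticipantRecord] = []
    counter = 0
    for gi, (group, n_group) in enumerate(zip(GROUPS, (config.n_control, config.n_high))):
        tripm = rng.normal(config.tripm_mean_by_group[gi], config.tripm_sd_by_group[gi], n_group)
        tripm = np.clip(tripm, 0.0, 174.0)  # 58 items scored 0-3
        subscales = _draw_subscales(rng, tripm, config)
        logk = rng.normal(config.logk_mean_by_group[gi], config.logk_sd, n_group)
        b0, b_group, b_logk, noise_sd = config.stab_coefs
        stab = b0 + b_group * (group == "high") + b_logk * logk + rng.normal(0, noise_sd, n_group)
        age = np.clip(
            np.rint(rng.normal(config.age_mean_by_group[gi], config.age_sd_by_group[gi], n_group)),
            *config.age_range,
        ).astype(int)
        gender = rng.choice(["male", "female", "other"], size=n_group, p=gender_probs)
        fluid = np.clip(
            np.rint(rng.normal(config.fluid_mean_by_group[gi], config.fluid_sd, n_group)), 0, 13
        ).astype(int)
        dont_know = rng.random(n_group) < config.income_dont_know_prob
        income = rng.choice(np.arange(1, 9), size=n_group, p=income_probs)
        attention = rng.choice(np.arange(len(att_probs)), size=n_group, p=att_probs)
        c0, c_group = config.crime_logit_coefs
        crime = (rng.random(n_group) < expit(c0 + c_group * (group == "high"))).astype(int)
        choice_seeds = rng.integers(0, 2**31 - 1, size=n_group)

        for i in range(n_group):
            counter += 1
            records.append(
                ParticipantRecord(
                    id=f"P{counter:04d}",
                    group=group,
                    tripm_total=float(tripm[i]),
                    tripm_boldness=float(subscales[i, 0]),
                    tripm_meanness=float(subscales[i, 1]),
                    tripm_disinhibition=float(subscales[i, 2]),
                    stab_total=float(stab[i]),
                    age=int(age[i]),
                    gender=str(gender[i]),
                    income_bracket=None if dont_know[i] else int(income[i]),
                    fluid_intelligence=int(fluid[i]),
                    attention_failures=int(attention[i]),
                    committed_crime=int(crime[i]),
                    latent_logk=float(logk[i]),
                    choice_blocks=simulate_choices(
                        float(logk[i]), schedule, config.choice_temperature, int(choice_seeds[i])
                    ),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Tabular emitters

def participants_frame(records: list[ParticipantRecord]):
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.id,
                "group": r.group,
                "tripm_total": round(r.tripm_total, 6),
                "tripm_boldness": round(r.tripm_boldness, 6),
                "tripm_meanness": round(r.tripm_meanness, 6),
                "tripm_disinhibition": round(r.tripm_disinhibition, 6),
                "stab_total": round(r.stab_total, 6),
                "age": r.age,
                "gender": r.gender,
                "income_bracket": "dont_know" if r.income_bracket is None else r.income_bracket,
                "fluid_intelligence": r.fluid_intelligence,
                "attention_failures": r.attention_failures,
                "committed_crime": r.committed_crime,
                "latent_logk": "" if r.latent_logk is None else round(r.latent_logk, 6),
            }
        )
    return pd.DataFrame(rows)


def choices_frame(records: list[ParticipantRecord]):
    import pandas as pd

    schedule = build_trial_schedule()
    rows = []
    for r in records:
        for block in r.choice_blocks:
            for trial, choice in enumerate(block.choices):
                rows.append(
                    {
                        "participant_id": r.id,
                        "social_distance": block.social_distance,
                        "trial_index": trial,
                        "selfish_amount": schedule.selfish_amounts[trial],
                        "choice": choice,
                    }
                )
    return pd.DataFrame(rows)


def _write_with_header(df, path, header_comment: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def write_cohort_csvs(records: list[ParticipantRecord], config: CohortConfig, outdir) -> dict[str, str]:
    """Write participants.csv and choices.csv with config-hash headers."""
    import os

    os.makedirs(outdir, exist_ok=True)
    tag = f"socdisc synthetic cohort config_hash={config_hash(config)} seed={config.seed}"
    paths = {}
    for name, df in (("participants", participants_frame(records)), ("choices", choices_frame(records))):
        path = os.path.join(outdir, f"{name}.csv")
        _write_with_header(df, path, tag)
        paths[name] = path
    return paths
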