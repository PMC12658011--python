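"""Reliability statistics and robustness procedures.

Cronbach's alpha for internal consistency, the one-way random-effects
single-rater absolute-agreement intraclass correlation ICC(1,1) for
inter-rater reliability, deterministic k-fold cross-validation of a
regression specification, and greedy 1:1 nearest-neighbor propensity-score
matching on the logit propensity with a caliper in logit-PS SD units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import ModelError, StatisticError, UsageError


@dataclass(frozen=True)
class ReliabilityResult:
    statistic: str  # alpha | icc1
    value: float
    ci_low: float | None
    ci_high: float | None
    n_units: int
    n_items_or_raters: int


@dataclass(frozen=True)
class MatchResult:
    matched_pairs: list[tuple[str, str]]
    caliper_sd_units: float
    caliper_logit: float
    unmatched_treated: list[str]
    smd_before: dict[str, float]
    smd_after: dict[str, float]


@dataclass(frozen=True)
class CvResult:
    fold_coefs: pd.DataFrame  # one row per fold, one column per term
    oof_r2: float
    in_sample_adj_r2: float
    k: int
    seed: int


def cronbach_alpha(items) -> ReliabilityResult:
    """α = (m/(m−1))·(1 − Σ item variances / variance of the item sum)."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise StatisticError("cronbach_alpha needs >= 3 units and >= 2 items")
    if np.isnan(X).any():
        raise StatisticError("cronbach_alpha requires complete data")
    m = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise StatisticError("cronbach_alpha undefined: zero total-score variance")
    alpha = (m / (m - 1)) * (1 - X.var(axis=0, ddof=1).sum() / total_var)
    return ReliabilityResult("alpha", float(alpha), None, None, X.shape[0], m)


def icc_oneway(ratings, alpha: float = 0.05) -> ReliabilityResult:
    """ICC(1,1): single-rater, absolute agreement, one-way random effects.

    ICC = (MSB − MSW)/(MSB + (k−1)·MSW) from the one-way ANOVA of the
    target × rater table, with the standard F-distribution 95% CI.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise StatisticError("icc_oneway needs >= 2 targets and >= 2 raters")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((X - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    if msb == 0 and msw == 0:
        raise StatisticError("icc_oneway undefined: no variance between or within targets")
    icc = (msb - msw) / (msb + (k - 1) * msw)

    ci_low = ci_high = None
    if msw > 0:
        f_obs = msb / msw
        df1, df2 = n - 1, n * (k - 1)
        f_l = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        ci_low = (f_l - 1) / (f_l + k - 1)
        ci_high = (f_u - 1) / (f_u + k - 1)
    return ReliabilityResult("icc1", float(icc), ci_low, ci_high, n, k)


def kfold_cv(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    k: int = 10,
    seed: int = 0,
) -> CvResult:
    """Deterministic k-fold CV of an OLS spec; pooled out-of-fold R²."""
    n = len(data)
    if not 2 <= k <= n:
        raise UsageError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    sub = data[[outcome] + predictors].astype(float).reset_index(drop=True)
    y = sub[outcome].to_numpy()
    X = sm.add_constant(sub[predictors].to_numpy())
    full_fit = sm.OLS(y, X).fit()

    preds = np.empty(n)
    rows = []
    for fold in folds:
        train = np.setdiff1d(order, fold)
        fit = sm.OLS(y[train], X[train]).fit()
        preds[fold] = X[fold] @ fit.params
        rows.append(fit.params)
    oof_r2 = 1 - np.sum((y - preds) ** 2) / np.sum((y - y.mean()) ** 2)
    coefs = pd.DataFrame(rows, columns=["(Intercept)"] + predictors)
    return CvResult(coefs, float(oof_r2), float(full_fit.rsquared_adj), k, seed)


def _smd(x_t: np.ndarray, x_c: np.ndarray) -> float:
    denom = math.sqrt((x_t.var(ddof=1) + x_c.var(ddof=1)) / 2)
    if denom == 0:
        return 0.0
    return (x_t.mean() - x_c.mean()) / denom


def propensity_match(
    data: pd.DataFrame,
    treatment: str,
    covariates: list[str],
    caliper: float = 0.2,
    id_col: str = "participant_id",
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor match on the logit propensity score.

    Treated units are matched hardest-first (descending propensity,
    deterministic id tie-break) to the nearest unused control within
    ``caliper`` × SD(logit PS). Standardized mean differences are reported
    before (full sample) and after (matched pairs) for every covariate.
    """
    t = data[treatment].astype(int).to_numpy()
    if t.sum() == 0 or t.sum() == len(t):
        raise ModelError("propensity_match requires both treatment classes")
    X = sm.add_constant(data[covariates].astype(float).to_numpy())
    ps = sm.Logit(t, X).fit(disp=0).predict(X)
    ps = np.clip(ps, 1e-12, 1 - 1e-12)
    logit_ps = np.log(ps / (1 - ps))
    caliper_logit = caliper * logit_ps.std(ddof=1)

    ids = data[id_col].astype(str).to_numpy()
    treated_idx = np.where(t == 1)[0]
    control_idx = np.where(t == 0)[0]
    # Hardest-to-match (highest PS) treated first; ties broken by id.
    treated_order = sorted(treated_idx, key=lambda i: (-logit_ps[i], ids[i]))

    available = {int(i) for i in control_idx}
    pairs: list[tuple[str, str]] = []
    pair_idx: list[tuple[int, int]] = []
    unmatched = []
    for ti in treated_order:
        best_ci, best_dist = None, None
        for ci in available:
            dist = abs(logit_ps[ti] - logit_ps[ci])
            if dist > caliper_logit:
                continue
            if best_dist is None or dist < best_dist or (dist == best_dist and ids[ci] < ids[best_ci]):
                best_ci, best_dist = ci, dist
        if best_ci is None:
            unmatched.append(ids[ti])
        else:
            available.remove(best_ci)
            pairs.append((ids[ti], ids[best_ci]))
            pair_idx.append((ti, best_ci))

    smd_before, smd_after = {}, {}
    for cov in covariates:
        col = data[cov].astype(float).to_numpy()
        smd_before[cov] = _smd(col[treated_idx], col[control_idx])
        if pair_idx:
            mt = np.array([p[0] for p in pair_idx])
            mc = np.array([p[1] for p in pair_idx])
            smd_after[cov] = _smd(col[mt], col[mc])
        else:
            smd_after[cov] = float("nan")
    return MatchResult(
        matched_pairs=pairs,
        caliper_sd_units=caliper,
        caliper_logit=float(caliper_logit),
        unmatched_treated=unmatched,
        smd_before=smd_before,
        smd_after=smd_after,
    )
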