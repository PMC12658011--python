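"""Group and continuous inference: Welch tests, chi-squared, OLS with
standardized coefficients, moderation, logistic odds ratios, Bonferroni.

Conventions follow the analysis design: two-tailed tests throughout;
Cohen's d from the pooled SD with a normal-approximation CI; "Std. B" means
every variable in the model — outcome, continuous predictors and binary
indicators alike — is z-scored before fitting; gender enters as a male
indicator with female/other as the reference; income is ordinal numeric.
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
class GroupComparison:
    statistic_kind: str  # welch_t | chi_squared
    statistic: float
    df: float
    p: float
    cohens_d: float | None = None
    d_ci_low: float | None = None
    d_ci_high: float | None = None


@dataclass(frozen=True)
class RegressionTerm:
    name: str
    b: float
    se: float
    ci_low: float
    ci_high: float
    std_b: float
    std_se: float
    std_ci_low: float
    std_ci_high: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    terms: list[RegressionTerm]
    f_stat: float
    df1: float
    df2: float
    f_p: float
    adj_r2: float
    n: int

    def term(self, name: str) -> RegressionTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    adjusted_for: tuple[str, ...]


def welch_test(x, y) -> GroupComparison:
    """Welch two-sample t-test with pooled-SD Cohen's d and normal CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatisticError("welch_test requires n >= 2 per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise StatisticError("welch_test undefined: zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=False)
    n1, n2 = len(x), len(y)
    pooled_sd = math.sqrt(((n1 - 1) * vx + (n2 - 1) * vy) / (n1 + n2 - 2))
    d = (x.mean() - y.mean()) / pooled_sd
    se_d = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    z = sps.norm.ppf(0.975)
    return GroupComparison(
        statistic_kind="welch_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        cohens_d=d,
        d_ci_low=d - z * se_d,
        d_ci_high=d + z * se_d,
    )


def chi_squared_test(table) -> GroupComparison:
    """Pearson chi-squared test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise StatisticError("chi_squared_test expects a 2-D contingency table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatisticError("chi_squared_test undefined: zero marginal")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return GroupComparison(statistic_kind="chi_squared", statistic=float(stat), df=float(dof), p=float(p))


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ModelError(f"cannot standardize constant column(s): {list(zero.index)}")
    return (df - df.mean()) / sd


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ModelError(f"design matrix is rank deficient among terms {list(X.columns)}")


def _ols(y: pd.Series, X: pd.DataFrame):
    return sm.OLS(np.asarray(y, dtype=float), sm.add_constant(X.to_numpy(dtype=float))).fit()


def fit_ols(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    covariates: list[str] | None = None,
    interactions: list[tuple[str, str]] | None = None,
) -> RegressionResult:
    """OLS with unstandardized and fully standardized coefficients.

    ``interactions`` adds product terms; in the standardized model the
    product is formed from the z-scored factors (and is not re-scored), the
    usual moderation convention.
    """
    covariates = covariates or []
    interactions = interactions or []
    cols = list(dict.fromkeys(predictors + covariates))
    sub = data[[outcome] + cols].astype(float)
    if sub.isna().any().any():
        raise ModelError("fit_ols requires complete cases")
    n = len(sub)

    def with_products(frame: pd.DataFrame) -> pd.DataFrame:
        frame = frame.copy()
        for a, b in interactions:
            frame[f"{a}:{b}"] = frame[a] * frame[b]
        return frame

    X_raw = with_products(sub[cols])
    p_terms = X_raw.shape[1]
    if n <= p_terms + 1:
        raise ModelError("fit_ols requires n > number of parameters")
    _check_rank(X_raw)
    raw = _ols(sub[outcome], X_raw)

    zsub = _zscore(sub)
    X_std = with_products(zsub[cols])
    std = _ols(zsub[outcome], X_std)

    ci_raw = raw.conf_int()
    ci_std = std.conf_int()
    terms = []
    names = ["(Intercept)"] + list(X_raw.columns)
    for i, name in enumerate(names):
        terms.append(
            RegressionTerm(
                name=name,
                b=float(raw.params[i]),
                se=float(raw.bse[i]),
                ci_low=float(ci_raw[i][0]),
                ci_high=float(ci_raw[i][1]),
                std_b=float(std.params[i]),
                std_se=float(std.bse[i]),
                std_ci_low=float(ci_std[i][0]),
                std_ci_high=float(ci_std[i][1]),
                p=float(raw.pvalues[i]),
            )
        )
    return RegressionResult(
        terms=terms,
        f_stat=float(raw.fvalue),
        df1=float(raw.df_model),
        df2=float(raw.df_resid),
        f_p=float(raw.f_pvalue),
        adj_r2=float(raw.rsquared_adj),
        n=n,
    )


def fit_moderation(
    data: pd.DataFrame,
    outcome: str,
    focal: str,
    moderator: str,
    covariates: list[str] | None = None,
) -> RegressionResult:
    """OLS with a focal × moderator product term (reported with CI and p)."""
    return fit_ols(
        data,
        outcome,
        predictors=[focal, moderator],
        covariates=covariates,
        interactions=[(focal, moderator)],
    )


def fit_logistic_or(
    data: pd.DataFrame,
    outcome: str,
    group: str,
    covariates: list[str] | None = None,
) -> OddsRatioResult:
    """Odds ratio for ``group`` from an ML logistic regression with Wald CI."""
    covariates = covariates or []
    cols = [group] + covariates
    sub = data[[outcome] + cols].astype(float)
    y = sub[outcome]
    if y.nunique() < 2:
        raise ModelError("logistic outcome must contain both classes")
    _check_rank(sub[cols])
    X = sm.add_constant(sub[cols].to_numpy(dtype=float))
    try:
        fit = sm.Logit(np.asarray(y), X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise ModelError(f"logistic fit failed ({exc}); consider penalized estimation") from exc
    if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
        raise ModelError("near-complete separation: group SE diverges; consider penalized estimation")
    beta, se = float(fit.params[1]), float(fit.bse[1])
    z = sps.norm.ppf(0.975)
    return OddsRatioResult(
        or_value=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p=float(fit.pvalues[1]),
        adjusted_for=tuple(covariates),
    )


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test alpha controlling the familywise rate over m comparisons."""
    if m < 1:
        raise UsageError("m must be >= 1")
    if not 0 < family_alpha < 1:
        raise UsageError("family_alpha must be in (0, 1)")
    return family_alpha / m
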