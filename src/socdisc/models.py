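"""Discounting models: hyperbolic/exponential/linear fits, AIC, logk, AUC.

The core model is hyperbolic decay of the amount willing to forgo with
social distance,

    v(N) = V0 / (1 + k·N),

with V0 the undiscounted value and k > 0 the discount rate; steeper k means
faster devaluation of more distant others. Exponential (V0·exp(−kN)) and
linear (max(V0 − kN, 0)) alternatives are fit to the same observations and
compared by AIC with Akaike weights. Per-participant summaries are logk
(natural log of the hyperbolic k) and the model-agnostic normalized
trapezoidal area under the v-vs-N curve (AUC in [0, 1]; higher = more
generous).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError, FitError, UsageError
from .task import MAX_FORGONE, IndifferenceProfile

FAMILIES = ("hyperbolic", "exponential", "linear")

#: Smallest representable discount rate; non-discounters are floored here so
#: logk stays finite.
K_FLOOR = 1e-6

#: Upper bound on k; flat-zero profiles pin the estimate here.
K_CEIL = 1e4

#: Residual sums of squares below this are treated as an exact fit when
#: forming the Gaussian profile log-likelihood (keeps AIC finite).
RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class FitOptions:
    """Fitting configuration.

    v0_mode: "free" estimates V0 jointly with k (bounded in (0, 160]);
    "fixed" pins V0 at ``v0_value``. ``use_aicc`` switches the information
    criterion to the small-sample corrected AICc.
    """

    v0_mode: str = "free"
    v0_value: float = 85.0
    k_floor: float = K_FLOOR
    k_ceil: float = K_CEIL
    use_aicc: bool = False
    n_starts: int = 5

    def __post_init__(self) -> None:
        if self.v0_mode not in ("free", "fixed"):
            raise UsageError(f"v0_mode must be 'free' or 'fixed', got {self.v0_mode!r}")
        if self.k_floor <= 0 or self.k_ceil <= self.k_floor:
            raise UsageError("require 0 < k_floor < k_ceil")


@dataclass(frozen=True)
class DiscountFit:
    family: str
    v0: float
    k: float
    logk: float
    rss: float
    n_obs: int
    aic: float
    converged: bool
    k_floored: bool
    degenerate: bool = False


@dataclass(frozen=True)
class ModelComparison:
    aic: dict[str, float]
    delta_aic: dict[str, float]
    akaike_weight: dict[str, float]
    best_family: str


@dataclass(frozen=True)
class AucResult:
    auc: float
    x_span: float
    y_max: float


def model_value(family: str, v0: float, k: float, n) -> np.ndarray | float:
    """Discounted value v at social distance(s) N under one model family."""
    n = np.asarray(n, dtype=float)
    if family == "hyperbolic":
        out = v0 / (1.0 + k * n)
    elif family == "exponential":
        out = v0 * np.exp(-k * n)
    elif family == "linear":
        out = np.maximum(v0 - k * n, 0.0)
    else:
        raise UsageError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    return out if out.ndim else float(out)


def _aic(rss: float, n: int, n_params: int, use_aicc: bool) -> float:
    # Gaussian profile likelihood with shared additive constants dropped;
    # valid for comparing families on identical observations.
    rss = max(rss, RSS_FLOOR)
    aic = n * math.log(rss / n) + 2 * n_params
    if use_aicc:
        denom = n - n_params - 1
        if denom > 0:
            aic += 2 * n_params * (n_params + 1) / denom
        else:
            aic = math.inf
    return aic


def _fit_family(n: np.ndarray, v: np.ndarray, family: str, options: FitOptions) -> DiscountFit:
    free_v0 = options.v0_mode == "free"
    # Linear slope lives on the dollars-per-distance scale, not the rate scale.
    if family == "linear":
        k_lo, k_hi = 0.0, 2.0 * MAX_FORGONE
        k_starts = np.linspace(0.05, 2.0, options.n_starts)
    else:
        k_lo, k_hi = options.k_floor, options.k_ceil
        k_starts = np.logspace(-4, 0, options.n_starts)

    def residuals(theta: np.ndarray) -> np.ndarray:
        if free_v0:
            v0, k = theta
        else:
            v0, k = options.v0_value, theta[0]
        return model_value(family, v0, k, n) - v

    best = None
    for k0 in k_starts:
        if free_v0:
            x0 = np.array([max(min(v.max(), 160.0), 1.0), k0])
            bounds = ([1e-6, k_lo], [160.0, k_hi])
        else:
            x0 = np.array([k0])
            bounds = ([k_lo], [k_hi])
        try:
            sol = least_squares(residuals, x0, bounds=bounds, method="trf")
        except Exception:  # pragma: no cover - solver failures fold into multistart
            continue
        rss = float(np.sum(sol.fun**2))
        k_hat = float(sol.x[1] if free_v0 else sol.x[0])
        v0_hat = float(sol.x[0]) if free_v0 else options.v0_value
        cand = (rss, k_hat, v0_hat, bool(sol.success))
        if best is None or cand[0] < best[0] - 1e-10 or (abs(cand[0] - best[0]) <= 1e-10 and cand[1] < best[1]):
            best = cand
    if best is None:
        raise FitError(f"{family} fit failed to converge from all {options.n_starts} starts")

    rss, k_hat, v0_hat, success = best
    n_params = 2 if free_v0 else 1
    k_floored = family != "linear" and k_hat <= options.k_floor * (1 + 1e-9)
    if k_floored:
        k_hat = options.k_floor
    degenerate = bool(np.all(v == 0.0))
    logk = math.log(k_hat) if k_hat > 0 else -math.inf
    return DiscountFit(
        family=family,
        v0=v0_hat,
        k=k_hat,
        logk=logk,
        rss=rss,
        n_obs=len(v),
        aic=_aic(rss, len(v), n_params, options.use_aicc),
        converged=success,
        k_floored=k_floored,
        degenerate=degenerate,
    )


def fit_participant(
    profile: IndifferenceProfile,
    family: str = "hyperbolic",
    options: FitOptions | None = None,
) -> DiscountFit:
    """Least-squares discounting fit to one participant's seven (N, v) points."""
    if family not in FAMILIES:
        raise UsageError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    options = options or FitOptions()
    n = np.asarray(profile.social_distances, dtype=float)
    v = np.asarray(profile.forgone_v, dtype=float)
    return _fit_family(n, v, family, options)


def fit_pooled(
    profiles: list[IndifferenceProfile],
    family: str = "hyperbolic",
    options: FitOptions | None = None,
) -> DiscountFit:
    """One fit to all participants' (N, v) observations pooled (family selection)."""
    if family not in FAMILIES:
        raise UsageError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    if not profiles:
        raise DataError("fit_pooled requires at least one profile")
    options = options or FitOptions()
    n = np.concatenate([np.asarray(p.social_distances, dtype=float) for p in profiles])
    v = np.concatenate([np.asarray(p.forgone_v, dtype=float) for p in profiles])
    return _fit_family(n, v, family, options)


def compare_models(aics: dict[str, float]) -> ModelComparison:
    """ΔAIC and Akaike weights across model families.

    weight_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2) with Δ_i = AIC_i − min AIC.
    """
    if len(aics) < 2:
        raise UsageError("compare_models requires at least two families")
    for fam, aic in aics.items():
        if not math.isfinite(aic):
            raise DataError(f"non-finite AIC for family {fam!r}")
    best = min(aics, key=aics.get)
    delta = {fam: aic - aics[best] for fam, aic in aics.items()}
    rel = {fam: math.exp(-d / 2.0) for fam, d in delta.items()}
    total = sum(rel.values())
    weights = {fam: r / total for fam, r in rel.items()}
    return ModelComparison(aic=dict(aics), delta_aic=delta, akaike_weight=weights, best_family=best)


def compute_logk(k: float, k_floor: float = K_FLOOR) -> float:
    """Natural log of the discount rate; callers must floor k first."""
    if k < k_floor:
        raise UsageError(f"k={k} below floor {k_floor}; floor in fitting before taking logs")
    return math.log(k)


def compute_auc(profile: IndifferenceProfile) -> AucResult:
    """Normalized trapezoidal area under the v-vs-N curve.

    The x-axis spans the observed distances (N = 1 … 100, no synthetic
    N = 0 anchor) and the y-axis is scaled by the maximum possible forgone
    amount ($80), so a uniformly maximally generous profile scores 1 and a
    never-generous profile scores 0.
    """
    n = np.asarray(profile.social_distances, dtype=float)
    v = np.asarray(profile.forgone_v, dtype=float)
    if len(n) < 2:
        raise DataError("AUC requires at least two (N, v) points")
    x_span = float(n[-1] - n[0])
    area = float(np.trapezoid(v, n))
    return AucResult(auc=area / (x_span * MAX_FORGONE), x_span=x_span, y_max=float(MAX_FORGONE))
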