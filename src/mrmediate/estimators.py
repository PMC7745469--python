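"""Two-sample MR estimators, heterogeneity, sensitivity series and power.

All estimators consume a :class:`~mrmediate.instruments.HarmonizedSet` of
aligned per-variant effects.  The inverse-variance-weighted (IVW) model is a
weighted regression of outcome betas on exposure betas through the origin
(weights 1/se_Y^2), with a multiplicative random-effects scale floored at 1.
The pleiotropy-robust alternatives are the intercept regression (average
directional pleiotropy as the intercept, causal effect as the slope), the
weighted median of per-variant ratio estimates, and the weighted mode via a
Gaussian kernel density over ratio estimates.  Median/mode standard errors
come from a seeded parametric bootstrap.

Confidence intervals and p-values are normal-based throughout (multiplier
1.959964 for 95%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import IdentifiabilityError, InsufficientInstrumentsError, UndefinedRatioError
from .instruments import HarmonizedPair, HarmonizedSet, orient_positive_exposure

Z_95 = 1.959964  # normal 97.5% quantile, to the precision used in reports


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate (or the pleiotropy intercept)."""

    method: str
    beta: float
    se: float
    ci_lower: float
    ci_upper: float
    pval: float
    nsnp: int
    random_effects_scale: float = 1.0
    exposure: str = ""
    outcome: str = ""
    outcome_binary: bool = False

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q for per-variant causal-effect heterogeneity."""

    Q: float
    df: int
    pval: float
    I2: float


@dataclass(frozen=True)
class BootstrapConfig:
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 100:
            raise ValueError("bootstrap needs at least 100 replicates")


@dataclass(frozen=True)
class PowerQuery:
    """Design for an approximate IVW power calculation on a binary outcome."""

    n_cases: int
    n_controls: int
    r2_instrument: float
    true_or_per_sd: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls) <= 0:
            raise ValueError("case and control counts must be positive")
        if not (0.0 < self.r2_instrument < 1.0):
            raise ValueError("r2_instrument must lie in (0, 1)")
        if self.true_or_per_sd <= 0:
            raise ValueError("odds ratio must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def _estimate(method, beta, se, nsnp, hset=None, phi=1.0) -> MREstimate:
    z = beta / se
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_lower=float(beta - Z_95 * se),
        ci_upper=float(beta + Z_95 * se),
        pval=float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny)),
        nsnp=int(nsnp),
        random_effects_scale=float(phi),
        exposure=hset.exposure if hset is not None else "",
        outcome=hset.outcome if hset is not None else "",
        outcome_binary=hset.outcome_binary if hset is not None else False,
    )


def wald_ratio(pair: HarmonizedPair, hset: HarmonizedSet | None = None) -> MREstimate:
    """Single-variant causal estimate: beta_Y / beta_X.

    The SE is first-order delta method, se_Y / |beta_X| (exposure
    uncertainty ignored, the convention for a genome-wide-significant
    instrument).
    """
    if pair.beta_exposure == 0:
        raise UndefinedRatioError(f"zero exposure beta for {pair.variant_id}")
    theta = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    return _estimate("wald_ratio", theta, se, 1, hset)


def _ivw_core(bx, by, sy):
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx ** -0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, se_fixed, q


def ivw(hset: HarmonizedSet) -> tuple[MREstimate, HeterogeneityStats]:
    """Random-effects IVW estimate with Cochran's Q heterogeneity.

    The point estimate is the weighted through-origin slope; the fixed-effect
    SE is inflated by max(1, sqrt(Q / (J - 1))) so heterogeneity widens but
    never narrows the interval.
    """
    bx, _, by, sy = hset.arrays()
    j = len(bx)
    if j < 2:
        raise InsufficientInstrumentsError("IVW requires at least 2 instruments")
    theta, se_fixed, q = _ivw_core(bx, by, sy)
    df = j - 1
    phi = max(1.0, math.sqrt(q / df))
    het = HeterogeneityStats(
        Q=q,
        df=df,
        pval=float(stats.chi2.sf(q, df)),
        I2=float(max(0.0, (q - df) / q)) if q > 0 else 0.0,
    )
    return _estimate("ivw", theta, se_fixed * phi, j, hset, phi), het


def mr_egger(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate, HeterogeneityStats]:
    """Pleiotropy-intercept regression: weighted regression with intercept.

    Exposure betas are first oriented non-negative (the model is not
    invariant to allele relabeling otherwise).  Returns (slope estimate,
    intercept estimate, residual heterogeneity Q').
    """
    oriented = orient_positive_exposure(hset)
    bx, _, by, sy = oriented.arrays()
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("the intercept regression requires >= 3 instruments")
    if np.ptp(bx) == 0:
        raise IdentifiabilityError("all exposure betas identical: slope and intercept collinear")
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtw = x.T * w
    cov = np.linalg.inv(xtw @ x)
    coef = cov @ (xtw @ by)
    resid = by - x @ coef
    q = float(np.sum(w * resid**2))
    df = j - 2
    phi = max(1.0, math.sqrt(q / df))
    ses = np.sqrt(np.diag(cov)) * phi
    het = HeterogeneityStats(
        Q=q,
        df=df,
        pval=float(stats.chi2.sf(q, df)),
        I2=float(max(0.0, (q - df) / q)) if q > 0 else 0.0,
    )
    slope = _estimate("egger_slope", coef[1], ses[1], j, hset, phi)
    intercept = _estimate("egger_intercept", coef[0], ses[0], j, hset, phi)
    return slope, intercept, het


def _ratio_weights(bx, by, sy):
    theta = by / bx
    w = bx**2 / sy**2
    return theta, w / np.sum(w)


def _weighted_median_point(theta, w):
    order = np.argsort(theta, kind="stable")
    theta_s, w_s = theta[order], w[order]
    s = np.cumsum(w_s) - 0.5 * w_s  # standardized cumulative weight
    return float(np.interp(0.5, s, theta_s))


def weighted_median(hset: HarmonizedSet, boot: BootstrapConfig | None = None) -> MREstimate:
    """Weighted median of per-variant ratio estimates.

    Weights are proportional to beta_X^2 / se_Y^2 (the inverse variance of
    each ratio).  Consistent when at least half of the total weight comes
    from valid instruments.  SE is a parametric bootstrap over both samples.
    """
    boot = boot or BootstrapConfig()
    bx, sx, by, sy = hset.arrays()
    j = len(bx)
    if j < 2:
        raise InsufficientInstrumentsError("weighted median requires at least 2 instruments")
    theta, w = _ratio_weights(bx, by, sy)
    point = _weighted_median_point(theta, w)
    se = _bootstrap_se(_weighted_median_point, bx, sx, by, sy, boot)
    return _estimate("weighted_median", point, se, j, hset)


def _mode_bandwidth(theta, bandwidth_factor):
    sd = float(np.std(theta, ddof=1))
    mad = float(stats.median_abs_deviation(theta, scale="normal"))
    scale = min(sd, mad) if mad > 0 else sd
    return bandwidth_factor * 0.9 * scale * len(theta) ** (-1 / 5)


def _weighted_mode_point(theta, w, bandwidth_factor=1.0, grid_size=10_000):
    h = _mode_bandwidth(theta, bandwidth_factor)
    if h == 0 or not np.isfinite(h):
        return float(theta[0])  # degenerate: all ratios identical
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    hset: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    boot: BootstrapConfig | None = None,
) -> MREstimate:
    """Weighted mode: argmax of a Gaussian kernel density over ratio estimates.

    Bandwidth h = factor * 0.9 * min(sd, normalized MAD) * J^(-1/5); the
    density is maximised on a 10,000-point grid spanning the ratios plus 3h.
    Consistent when the largest cluster of instruments is valid.
    """
    boot = boot or BootstrapConfig()
    bx, sx, by, sy = hset.arrays()
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("weighted mode requires at least 3 instruments")
    theta, w = _ratio_weights(bx, by, sy)

    def point_fn(t, ww):
        return _weighted_mode_point(t, ww, bandwidth_factor)

    point = point_fn(theta, w)
    se = _bootstrap_se(point_fn, bx, sx, by, sy, boot)
    return _estimate("weighted_mode", point, se, j, hset)


def _bootstrap_se(point_fn, bx, sx, by, sy, boot: BootstrapConfig) -> float:
    """Parametric bootstrap SE: redraw both samples' betas from their SEs."""
    rng = np.random.default_rng(boot.seed)
    j = len(bx)
    bx_draws = rng.normal(bx, sx, size=(boot.n_reps, j))
    by_draws = rng.normal(by, sy, size=(boot.n_reps, j))
    points = np.empty(boot.n_reps)
    for r in range(boot.n_reps):
        bxr = bx_draws[r]
        bxr = np.where(bxr == 0, np.finfo(float).tiny, bxr)  # guard exact zeros
        theta, w = _ratio_weights(bxr, by_draws[r], sy)
        points[r] = point_fn(theta, w)
    se = float(np.std(points, ddof=1))
    return max(se, np.finfo(float).tiny)


def leave_one_out(hset: HarmonizedSet) -> list:
    """IVW re-estimated with each variant omitted, plus the all-variant fit.

    Returns ``[(variant_id, estimate), ..., (None, full_estimate)]`` in input
    order; a large shift on one omission flags that variant as an outlier.
    """
    kept = hset.kept
    if len(kept) < 3:
        raise InsufficientInstrumentsError("leave-one-out requires at least 3 instruments")
    results = []
    for i, pair in enumerate(kept):
        sub = HarmonizedSet(
            hset.exposure, hset.outcome, kept[:i] + kept[i + 1 :], hset.outcome_binary
        )
        est, _ = ivw(sub)
        results.append((pair.variant_id, est))
    full, _ = ivw(hset)
    results.append((None, full))
    return results


def scatter_data(hset: HarmonizedSet, estimates: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant effects plus one fitted line per method, ready to plot.

    Through-origin methods get intercept 0; the intercept regression's line
    uses its own intercept estimate when present in ``estimates``.
    """
    kept = hset.kept
    points = pd.DataFrame(
        {
            "variant_id": [p.variant_id for p in kept],
            "beta_exposure": [p.beta_exposure for p in kept],
            "se_exposure": [p.se_exposure for p in kept],
            "beta_outcome": [p.beta_outcome for p in kept],
            "se_outcome": [p.se_outcome for p in kept],
        }
    )
    intercepts = {e.method: e.beta for e in estimates if e.method == "egger_intercept"}
    lines = []
    for est in estimates:
        if est.method == "egger_intercept":
            continue
        intercept = intercepts.get("egger_intercept", 0.0) if est.method == "egger_slope" else 0.0
        lines.append({"method": est.method, "slope": est.beta, "intercept": intercept})
    return points, pd.DataFrame(lines, columns=["method", "slope", "intercept"])


def mr_power(q: PowerQuery) -> float:
    """Approximate power of the IVW test for a binary outcome.

    Uses the normal approximation: the test statistic is centred at
    log(OR) * sqrt(n * v * (1 - v) * r2) with v the case fraction, so power
    is the two-tailed exceedance beyond the alpha critical value.  Monotone
    in n, r2 and |log OR|.
    """
    n = q.n_cases + q.n_controls
    v = q.n_cases / n
    ncp = math.log(q.true_or_per_sd) * math.sqrt(n * v * (1.0 - v) * q.r2_instrument)
    crit = stats.norm.isf(q.alpha / 2.0)
    return float(stats.norm.sf(crit - ncp) + stats.norm.cdf(-crit - ncp))
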