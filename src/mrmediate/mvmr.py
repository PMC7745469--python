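"""Multivariable MR: joint direct effects of several exposures on one outcome.

The model regresses per-variant outcome betas on K columns of exposure betas
with weights 1/se_Y^2 and no intercept; each coefficient is the direct
effect of that exposure holding the others fixed.  Instrument strength of
one exposure given the rest is summarised by a conditional F-statistic
computed from the minimised cross-exposure heterogeneity, assuming zero
covariance between exposures' summary estimates (non-overlapping samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import ConvergenceError, IdentifiabilityError, InsufficientInstrumentsError
from .estimators import MREstimate, Z_95, _estimate


@dataclass
class MultiHarmonizedSet:
    """Variant rows harmonized across K exposures and one outcome.

    ``beta_x`` and ``se_x`` are (J, K) arrays in the order of
    ``exposure_ids``; every row must have all exposure betas present.
    """

    outcome: str
    exposure_ids: list
    variant_ids: list
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    outcome_binary: bool = False

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        j, k = self.beta_x.shape
        if k != len(self.exposure_ids):
            raise ValueError("beta_x column count does not match exposure_ids")
        if j != len(self.variant_ids) or j != len(self.beta_y):
            raise ValueError("row counts inconsistent")
        if np.isnan(self.beta_x).any():
            raise ValueError("missing exposure betas are not allowed")

    @property
    def J(self) -> int:
        return self.beta_x.shape[0]

    @property
    def K(self) -> int:
        return self.beta_x.shape[1]


@dataclass
class MVMRResult:
    """Direct-effect estimates with residual heterogeneity and conditional F."""

    estimates: dict  # exposure_id -> MREstimate (method tag "mvmr")
    Q_mv: float
    df: int
    q_pval: float
    conditional_f: dict = field(default_factory=dict)
    random_effects_scale: float = 1.0


def _check_rank(mset: MultiHarmonizedSet) -> None:
    x = mset.beta_x
    if np.linalg.matrix_rank(x, tol=1e-10 * max(1.0, float(np.abs(x).max()))) < mset.K:
        # name the most collinear pair for the error message
        worst, pair = 0.0, (mset.exposure_ids[0], mset.exposure_ids[-1])
        for a in range(mset.K):
            for b in range(a + 1, mset.K):
                xa, xb = x[:, a], x[:, b]
                denom = np.linalg.norm(xa) * np.linalg.norm(xb)
                r = abs(float(xa @ xb) / denom) if denom > 0 else 1.0
                if r >= worst:
                    worst, pair = r, (mset.exposure_ids[a], mset.exposure_ids[b])
        raise IdentifiabilityError(
            f"collinear exposure instrument effects: {pair[0]} vs {pair[1]}"
        )


def mvmr_fit(mset: MultiHarmonizedSet, compute_conditional_f: bool = True) -> MVMRResult:
    """Weighted no-intercept multiple regression of outcome on exposure betas.

    SEs carry a multiplicative random-effects scale max(1, sqrt(Q_mv /
    (J - K))), mirroring the univariable convention.  With K = 1 this
    reduces exactly to the IVW estimate.
    """
    j, k = mset.J, mset.K
    if j < k + 2:
        raise InsufficientInstrumentsError(f"need at least K+2 = {k + 2} variants, got {j}")
    # an exactly-zero exposure column carries no information: its direct
    # effect is reported as 0 with infinite SE and the rest fit as usual
    zero_cols = [i for i in range(k) if not np.any(mset.beta_x[:, i])]
    active = [i for i in range(k) if i not in zero_cols]
    if not active:
        raise IdentifiabilityError("all exposure columns are zero")
    sub = MultiHarmonizedSet(
        mset.outcome,
        [mset.exposure_ids[i] for i in active],
        mset.variant_ids,
        mset.beta_x[:, active],
        mset.se_x[:, active],
        mset.beta_y,
        mset.se_y,
        mset.outcome_binary,
    )
    _check_rank(sub)
    w = 1.0 / mset.se_y**2
    x = sub.beta_x
    xtw = x.T * w
    cov = np.linalg.inv(xtw @ x)
    coef_active = cov @ (xtw @ mset.beta_y)
    resid = mset.beta_y - x @ coef_active
    q_mv = float(np.sum(w * resid**2))
    df = j - len(active)
    phi = max(1.0, math.sqrt(q_mv / df))
    ses_active = np.sqrt(np.diag(cov)) * phi
    coef = np.zeros(k)
    ses = np.full(k, np.inf)
    coef[active] = coef_active
    ses[active] = ses_active

    estimates = {}
    for idx, exp_id in enumerate(mset.exposure_ids):
        beta, se = float(coef[idx]), float(ses[idx])
        pval = (
            float(max(2.0 * stats.norm.sf(abs(beta / se)), np.finfo(float).tiny))
            if math.isfinite(se)
            else 1.0
        )
        est = MREstimate(
            method="mvmr",
            beta=beta,
            se=se,
            ci_lower=beta - Z_95 * se,
            ci_upper=beta + Z_95 * se,
            pval=pval,
            nsnp=j,
            random_effects_scale=float(phi),
            exposure=exp_id,
            outcome=mset.outcome,
            outcome_binary=mset.outcome_binary,
        )
        estimates[exp_id] = est

    cond_f = {}
    if compute_conditional_f:
        for idx, exp_id in enumerate(mset.exposure_ids):
            cond_f[exp_id] = conditional_f(mset, idx)
    return MVMRResult(
        estimates=estimates,
        Q_mv=q_mv,
        df=df,
        q_pval=float(stats.chi2.sf(q_mv, df)),
        conditional_f=cond_f,
        random_effects_scale=float(phi),
    )


def _q_exposure(delta: np.ndarray, bk, sk, b_other, s_other) -> float:
    pred = b_other @ delta
    var = sk**2 + (s_other**2) @ (delta**2)
    return float(np.sum((bk - pred) ** 2 / var))


def conditional_f(
    mset: MultiHarmonizedSet,
    exposure_index: int,
    n_restarts: int = 5,
    tol: float = 1e-8,
    seed: int = 0,
) -> float:
    """Conditional instrument strength of one exposure given the others.

    Minimises the heterogeneity of exposure-k betas about their best linear
    prediction from the other exposures' betas (variance-weighted, zero
    cross-study covariance), then scales by the degrees of freedom:
    F = Q_min / (J - K + 1).  With a single exposure this is the mean
    per-variant F.
    """
    j, k = mset.J, mset.K
    if j < k + 1:
        raise InsufficientInstrumentsError("conditional F requires J >= K+1")
    bk = mset.beta_x[:, exposure_index]
    sk = mset.se_x[:, exposure_index]
    # exactly-zero columns carry no information and make the Q minimisation
    # degenerate (delta -> inf empties the variance weight), so drop them
    others = [
        i for i in range(k) if i != exposure_index and np.any(mset.beta_x[:, i])
    ]
    if not others:
        return float(np.sum((bk / sk) ** 2)) / (j - k + 1)
    b_other = mset.beta_x[:, others]
    s_other = mset.se_x[:, others]

    rng = np.random.default_rng(seed)
    best: Optional[float] = None
    starts = [np.zeros(k - 1)] + [rng.normal(scale=0.5, size=k - 1) for _ in range(n_restarts)]
    last = None
    for x0 in starts:
        res = optimize.minimize(
            _q_exposure,
            x0,
            args=(bk, sk, b_other, s_other),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": tol, "maxiter": 5000},
        )
        last = res
        if res.success and (best is None or res.fun < best):
            best = float(res.fun)
    if best is None:
        raise ConvergenceError(f"conditional-F minimisation failed; last iterate {last.x}")
    return best / (j - k + 1)


def build_multi_set(
    outcome: str,
    exposure_ids: Sequence[str],
    rows: Sequence[dict],
    outcome_binary: bool = False,
) -> MultiHarmonizedSet:
    """Assemble a MultiHarmonizedSet from per-variant row dicts.

    Each row needs ``variant_id``, ``beta_y``, ``se_y`` and, per exposure id
    ``e``, ``beta_{e}`` and ``se_{e}``.
    """
    ids = [r["variant_id"] for r in rows]
    bx = np.array([[r[f"beta_{e}"] for e in exposure_ids] for r in rows], dtype=float)
    sx = np.array([[r[f"se_{e}"] for e in exposure_ids] for r in rows], dtype=float)
    by = np.array([r["beta_y"] for r in rows], dtype=float)
    sy = np.array([r["se_y"] for r in rows], dtype=float)
    return MultiHarmonizedSet(outcome, list(exposure_ids), ids, bx, sx, by, sy, outcome_binary)
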