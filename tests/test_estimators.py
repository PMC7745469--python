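import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrmediate import (
    BootstrapConfig,
    HarmonizedSet,
    PowerQuery,
    ivw,
    leave_one_out,
    mr_egger,
    mr_power,
    scatter_data,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from mrmediate.estimators import _mode_bandwidth, _ratio_weights
from mrmediate.exceptions import (
    IdentifiabilityError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from mrmediate.instruments import HarmonizedPair

from conftest import random_harmonized_set

BOOT = BootstrapConfig(n_reps=200, seed=7)


def _pair(bx, by, sy, sx=0.01, vid="rs1"):
    return HarmonizedPair(vid, bx, sx, by, sy, None, "kept")


# ---------------------------------------------------------------------------
# Wald ratio


def test_wald_ratio_arithmetic():
    est = wald_ratio(_pair(0.1, 0.3, 0.1))
    assert est.beta == pytest.approx(3.0)
    assert est.se == pytest.approx(1.0)
    assert est.nsnp == 1


def test_wald_identity_instrument():
    est = wald_ratio(_pair(1.0, -0.42, 0.05))
    assert est.beta == pytest.approx(-0.42)


def test_wald_zero_exposure_beta_errors():
    with pytest.raises(UndefinedRatioError):
        wald_ratio(_pair(0.0, 0.3, 0.1))


def test_wald_se_close_to_second_order_delta(rng):
    # first-order truncation: difference from the second-order expansion is
    # bounded by the (se_X / beta_X)^2 relative term
    bx, by, sx, sy = 0.08, 0.02, 0.004, 0.01
    est = wald_ratio(_pair(bx, by, sy, sx=sx))
    second_order = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    assert est.se <= second_order
    assert abs(est.se - second_order) / second_order < (sx / bx) ** 2 + (by * sx / (bx * sy)) ** 2


# ---------------------------------------------------------------------------
# IVW


def test_ivw_exact_line_through_origin():
    bx = np.array([0.02, 0.05, 0.08])
    hset = HarmonizedSet.from_arrays(bx, 0.01 * bx, 0.4 * bx, [0.01, 0.02, 0.03])
    est, het = ivw(hset)
    assert est.beta == pytest.approx(0.4, abs=1e-14)
    assert het.Q == pytest.approx(0.0, abs=1e-22)
    assert est.random_effects_scale == 1.0
    assert het.I2 == 0.0


def test_ivw_matches_wls_through_origin_oracle():
    bx = np.array([0.03, 0.06, 0.1])
    by = np.array([0.01, 0.02, 0.05])
    sy = np.array([0.01, 0.015, 0.02])
    hset = HarmonizedSet.from_arrays(bx, 0.01 * np.ones(3), by, sy)
    est, het = ivw(hset)
    fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
    assert est.beta == pytest.approx(float(fit.params[0]), abs=1e-12)
    se_fixed = float(fit.bse[0]) / math.sqrt(float(fit.scale))  # unit-scale SE
    phi = max(1.0, math.sqrt(het.Q / het.df))
    assert est.se == pytest.approx(se_fixed * phi, abs=1e-12)


def test_ivw_duplication_invariance(rng):
    hset = random_harmonized_set(rng, 8)
    bx, sx, by, sy = hset.arrays()
    doubled = HarmonizedSet.from_arrays(
        np.r_[bx, bx], np.r_[sx, sx], np.r_[by, by], np.r_[sy, sy]
    )
    assert ivw(doubled)[0].beta == pytest.approx(ivw(hset)[0].beta, abs=1e-14)


def test_ivw_two_snp_closed_form():
    # equal outcome SEs: IVW is the beta_x^2-weighted mean of the Wald ratios
    bx = np.array([0.04, 0.09])
    by = np.array([0.012, 0.02])
    hset = HarmonizedSet.from_arrays(bx, [0.01, 0.01], by, [0.02, 0.02])
    est, _ = ivw(hset)
    ratios = by / bx
    expected = float(np.sum(bx**2 * ratios) / np.sum(bx**2))
    assert est.beta == pytest.approx(expected, abs=1e-14)


def test_ivw_se_scales_with_outcome_se(rng):
    hset = random_harmonized_set(rng, 10)
    bx, sx, by, sy = hset.arrays()
    scaled = HarmonizedSet.from_arrays(bx, sx, by, 3.0 * sy)
    base, het0 = ivw(hset)
    scl, het1 = ivw(scaled)
    assert scl.beta == pytest.approx(base.beta, abs=1e-14)
    fixed0 = base.se / base.random_effects_scale
    fixed1 = scl.se / scl.random_effects_scale
    assert fixed1 == pytest.approx(3.0 * fixed0, abs=1e-12)


def test_ivw_needs_two_instruments(rng):
    hset = HarmonizedSet.from_arrays([0.05], [0.01], [0.01], [0.02])
    with pytest.raises(InsufficientInstrumentsError):
        ivw(hset)


# ---------------------------------------------------------------------------
# Egger regression


def test_egger_exact_affine_data():
    bx = np.array([0.02, 0.05, 0.08, 0.11])
    by = 0.1 + 0.5 * bx
    hset = HarmonizedSet.from_arrays(bx, 0.01 * np.ones(4), by, 0.02 * np.ones(4))
    slope, intercept, het = mr_egger(hset)
    assert intercept.beta == pytest.approx(0.1, abs=1e-12)
    assert slope.beta == pytest.approx(0.5, abs=1e-12)
    assert het.Q == pytest.approx(0.0, abs=1e-20)


def test_egger_reduces_to_ivw_without_pleiotropy():
    bx = np.array([0.02, 0.05, 0.08])
    by = 0.3 * bx
    hset = HarmonizedSet.from_arrays(bx, 0.01 * np.ones(3), by, [0.01, 0.02, 0.03])
    slope, intercept, _ = mr_egger(hset)
    est, _ = ivw(hset)
    assert intercept.beta == pytest.approx(0.0, abs=1e-14)
    assert slope.beta == pytest.approx(est.beta, abs=1e-12)


def test_egger_matches_wls_oracle(rng):
    for _ in range(20):
        hset = random_harmonized_set(rng, 10)
        bx, _, by, sy = hset.arrays()
        # the model's allele convention: exposure-increasing orientation
        flip = np.sign(bx)
        bx, by = bx * flip, by * flip
        slope, intercept, het = mr_egger(hset)
        design = sm.add_constant(bx)
        fit = sm.WLS(by, design, weights=1.0 / sy**2).fit()
        assert intercept.beta == pytest.approx(float(fit.params[0]), abs=1e-10)
        assert slope.beta == pytest.approx(float(fit.params[1]), abs=1e-10)
        phi = max(1.0, math.sqrt(het.Q / het.df))
        unit_bse = np.asarray(fit.bse) / math.sqrt(float(fit.scale))
        assert intercept.se == pytest.approx(unit_bse[0] * phi, abs=1e-10)
        assert slope.se == pytest.approx(unit_bse[1] * phi, abs=1e-10)


def test_egger_orients_internally(rng):
    hset = random_harmonized_set(rng, 8)
    bx, sx, by, sy = hset.arrays()
    flipped = HarmonizedSet.from_arrays(-bx, sx, -by, sy)
    a = mr_egger(hset)
    b = mr_egger(flipped)
    assert a[0].beta == pytest.approx(b[0].beta, abs=1e-12)
    assert a[1].beta == pytest.approx(b[1].beta, abs=1e-12)


def test_egger_collinear_exposure_errors():
    hset = HarmonizedSet.from_arrays([0.05] * 4, [0.01] * 4, [0.01, 0.02, 0.01, 0.03], [0.02] * 4)
    with pytest.raises(IdentifiabilityError):
        mr_egger(hset)


# ---------------------------------------------------------------------------
# weighted median


def test_weighted_median_middle_order_statistic():
    # equal weights, ratios 1, 2, 9 -> the middle ratio
    bx = np.array([0.1, 0.1, 0.1])
    by = np.array([0.1, 0.2, 0.9])
    hset = HarmonizedSet.from_arrays(bx, [0.01] * 3, by, [0.02] * 3)
    est = weighted_median(hset, BOOT)
    assert est.beta == pytest.approx(2.0, abs=1e-12)


def test_weighted_median_degenerate_ratios():
    bx = np.array([0.05, 0.1, 0.2])
    by = 0.7 * bx
    hset = HarmonizedSet.from_arrays(bx, [0.01] * 3, by, [0.02] * 3)
    est = weighted_median(hset, BOOT)
    assert est.beta == pytest.approx(0.7, abs=1e-12)


def brute_force_weighted_median(theta, w):
    order = np.argsort(theta)
    t, ww = np.asarray(theta)[order], np.asarray(w)[order]
    s = []
    acc = 0.0
    for k in range(len(t)):
        s.append(acc + ww[k] / 2.0)
        acc += ww[k]
    s = np.array(s)
    if 0.5 <= s[0]:
        return t[0]
    if 0.5 >= s[-1]:
        return t[-1]
    k = int(np.searchsorted(s, 0.5))
    frac = (0.5 - s[k - 1]) / (s[k] - s[k - 1])
    return t[k - 1] + frac * (t[k] - t[k - 1])


def test_weighted_median_matches_brute_force_oracle(rng):
    for _ in range(30):
        hset = random_harmonized_set(rng, 7)
        bx, _, by, sy = hset.arrays()
        theta, w = _ratio_weights(bx, by, sy)
        est = weighted_median(hset, BOOT)
        assert est.beta == pytest.approx(brute_force_weighted_median(theta, w), abs=1e-12)


def test_weighted_median_equals_plain_median_equal_weights():
    bx = np.full(5, 0.1)
    by = np.array([0.01, 0.09, 0.03, 0.02, 0.05])
    hset = HarmonizedSet.from_arrays(bx, [0.01] * 5, by, [0.02] * 5)
    est = weighted_median(hset, BOOT)
    assert est.beta == pytest.approx(float(np.median(by / bx)), abs=1e-12)


def test_bootstrap_se_reproducible_bit_exact(rng):
    hset = random_harmonized_set(rng, 6)
    a = weighted_median(hset, BootstrapConfig(n_reps=150, seed=11))
    b = weighted_median(hset, BootstrapConfig(n_reps=150, seed=11))
    assert a.se == b.se


# ---------------------------------------------------------------------------
# weighted mode


def test_weighted_mode_majority_cluster():
    bx = np.array([0.1, 0.1, 0.1, 0.1])
    by = np.array([0.05, 0.050001, 0.0502, 0.30])
    hset = HarmonizedSet.from_arrays(bx, [0.01] * 4, by, [0.02] * 4)
    est = weighted_mode(hset, boot=BOOT)
    assert est.beta == pytest.approx(0.5, abs=0.02)


def test_weighted_mode_degenerate_ratios():
    bx = np.array([0.05, 0.1, 0.2])
    by = 0.7 * bx
    hset = HarmonizedSet.from_arrays(bx, [0.01] * 3, by, [0.02] * 3)
    est = weighted_mode(hset, boot=BOOT)
    assert est.beta == pytest.approx(0.7, abs=1e-12)


def test_weighted_mode_matches_fine_grid_oracle(rng):
    for _ in range(5):
        hset = random_harmonized_set(rng, 10)
        bx, _, by, sy = hset.arrays()
        theta, w = _ratio_weights(bx, by, sy)
        h = _mode_bandwidth(theta, 1.0)
        grid = np.arange(theta.min() - 3 * h, theta.max() + 3 * h, 1e-4)
        dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w
        oracle = grid[int(np.argmax(dens))]
        impl_spacing = (theta.max() - theta.min() + 6 * h) / 10_000
        est = weighted_mode(hset, boot=BOOT)
        assert est.beta == pytest.approx(oracle, abs=max(2 * impl_spacing, 2e-4))


# ---------------------------------------------------------------------------
# leave-one-out and scatter


def test_leave_one_out_homogeneous(rng):
    bx = np.array([0.02, 0.05, 0.08, 0.1])
    hset = HarmonizedSet.from_arrays(bx, 0.01 * np.ones(4), 0.3 * bx, 0.02 * np.ones(4))
    series = leave_one_out(hset)
    assert len(series) == 5 and series[-1][0] is None
    for _, est in series:
        assert est.beta == pytest.approx(0.3, abs=1e-12)


def test_leave_one_out_flags_gross_outlier(rng):
    hset = random_harmonized_set(rng, 8, slope=0.2)
    bx, sx, by, sy = hset.arrays()
    by[3] = 1.0  # gross outlier
    spiked = HarmonizedSet.from_arrays(bx, sx, by, sy)
    series = leave_one_out(spiked)
    full = series[-1][1].beta
    shifts = {vid: abs(est.beta - full) for vid, est in series[:-1]}
    assert max(shifts, key=shifts.get) == spiked.kept[3].variant_id


def test_leave_one_out_equals_subset_ivw(rng):
    hset = random_harmonized_set(rng, 4)
    series = leave_one_out(hset)
    kept = hset.kept
    for i, (vid, est) in enumerate(series[:-1]):
        sub = HarmonizedSet(hset.exposure, hset.outcome, kept[:i] + kept[i + 1 :])
        assert est.beta == pytest.approx(ivw(sub)[0].beta, abs=1e-14)


def test_scatter_data_shapes_and_lines(rng):
    hset = random_harmonized_set(rng, 6)
    est, _ = ivw(hset)
    slope, intercept, _ = mr_egger(hset)
    points, lines = scatter_data(hset, [est, slope, intercept])
    assert len(points) == hset.n_kept
    ivw_line = lines[lines["method"] == "ivw"].iloc[0]
    assert ivw_line["intercept"] == 0.0
    egger_line = lines[lines["method"] == "egger_slope"].iloc[0]
    assert egger_line["intercept"] == pytest.approx(intercept.beta)


# ---------------------------------------------------------------------------
# power


def test_power_null_effect_equals_alpha():
    q = PowerQuery(50_000, 60_000, 0.02, 1.0, alpha=0.05)
    assert mr_power(q) == pytest.approx(0.05, abs=1e-12)


def test_power_monotone_in_r2_and_n():
    lo = mr_power(PowerQuery(50_000, 60_000, 0.003, 1.2))
    hi = mr_power(PowerQuery(50_000, 60_000, 0.006, 1.2))
    assert hi > lo
    small = mr_power(PowerQuery(5_000, 6_000, 0.003, 1.2))
    assert lo > small


def test_power_query_validation():
    with pytest.raises(ValueError):
        PowerQuery(0, 10, 0.01, 1.2)
    with pytest.raises(ValueError):
        PowerQuery(10, 10, 1.5, 1.2)


# ---------------------------------------------------------------------------
# cross-estimator agreement


def test_all_estimators_agree_under_exact_homogeneity():
    bx = np.array([0.02, 0.05, 0.08, 0.11, 0.14])
    hset = HarmonizedSet.from_arrays(bx, 0.005 * np.ones(5), 0.25 * bx, 0.02 * np.ones(5))
    est, het = ivw(hset)
    slope, _, _ = mr_egger(hset)
    wm = weighted_median(hset, BOOT)
    mode = weighted_mode(hset, boot=BOOT)
    single = wald_ratio(hset.kept[0])
    assert het.Q == pytest.approx(0.0, abs=1e-20)
    for b in (slope.beta, wm.beta, mode.beta, single.beta):
        assert b == pytest.approx(est.beta, abs=1e-10)


def test_q_calibrated_under_homogeneous_simulation(rng):
    # Q should behave as chi-square(J-1) when the model is correctly specified
    j, reps = 10, 1000
    qs = np.empty(reps)
    for r in range(reps):
        bx = rng.normal(0.08, 0.02, j)
        sy = rng.uniform(0.01, 0.03, j)
        by = 0.2 * bx + rng.normal(0, sy)
        _, het = ivw(HarmonizedSet.from_arrays(bx, np.zeros(j), by, sy))
        qs[r] = het.Q
    assert abs(np.mean(qs) / (j - 1) - 1.0) < 0.05
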