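"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of the real inputs to an
adiposity → metabolites → colorectal-cancer MR study: an exposure GWAS in SD
units (large sample), a panel of metabolite GWAS in SD units (moderate
sample) organised into named classes, and a binary outcome GWAS on the
log-odds scale (case-control).  Per-variant standard errors follow the usual
large-sample approximations for standardized traits,

    se_continuous = 1 / sqrt(2 p q n)
    se_logOR      = 1 / sqrt(2 p q n v (1 - v)),   v = case fraction,

with p the effect-allele frequency and q = 1 - p.  Observed betas are drawn
Normal(truth, se^2) independently in each study, realising the two-sample
design.

Causal structure (all effects per SD):

* each exposure instrument j carries a true effect gamma_j on the exposure,
  oriented positive by default (effect allele = exposure-increasing allele,
  the convention of published instrument lists);
* each metabolite class c has a latent factor: the exposure shifts it by
  kappa_class[c], class members load on it with lambda_m ~ U(0.7, 1), and it
  shifts the outcome by theta_class[c];
* a configurable fraction of exposure instruments carry direct (pleiotropic)
  outcome effects alpha_j, optionally correlated with gamma_j to break the
  InSIDE assumption;
* the total exposure→outcome effect is
  theta_total = theta_direct + sum_c kappa_class[c] * theta_class[c].

Block LD is realised by attaching proxy variants to exposure instruments
(pairwise r^2 fixed within a block, marginal effects attenuated by r), and
palindromic alleles, strand flips and allele swaps are injected into the
outcome table at configurable rates to exercise harmonization.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import ConfigError
from .instruments import COMPLEMENT, LDMatrix

#: metabolite classes mirroring a targeted NMR panel
DEFAULT_CLASS_NAMES = (
    "VLDL_lipids",
    "LDL_lipids",
    "HDL_lipids",
    "IDL_lipids",
    "fatty_acids",
    "amino_acids",
    "glycolysis_related",
    "ketone_bodies",
    "glycoprotein_acetyls",
    "other_lipids",
)

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
    ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class PleiotropyConfig:
    """Direct SNP→outcome effects bypassing the exposure."""

    fraction: float = 0.0  # share of exposure instruments that are invalid
    mean: float = 0.0      # mean direct effect (directional when nonzero)
    sd: float = 0.0
    gamma_cor: float = 0.0  # correlation with instrument strength (InSIDE break)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ConfigError("pleiotropy fraction must lie in [0, 1]")


@dataclass(frozen=True)
class LDBlockConfig:
    """Redundant proxy variants attached to each exposure instrument."""

    n_proxies: int = 2
    r2: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ConfigError("within-block r2 must lie in [0, 1]")


@dataclass
class ScenarioConfig:
    """Full generative specification for one synthetic study.

    Defaults mirror the real study's scale: 312 exposure instruments from an
    adiposity GWAS of N = 806,810; a 123-trait metabolite panel at
    N = 24,925; and a case-control outcome of 58,221 cases / 67,694
    controls.  ``tau2`` is tuned so mean per-SNP instrument F is ~100,
    inside the 75–125 band typical of adiposity instruments, giving a total
    variance explained of ~4%.
    """

    J: int = 312
    n_exposure: int = 806_810
    n_mediator: int = 24_925
    n_cases: int = 58_221
    n_controls: int = 67_694
    maf_range: tuple = (0.05, 0.5)
    tau2: float = 3.4e-4                 # variance of true SNP→exposure effects
    theta_direct: float = math.log(1.12)  # direct exposure→outcome log-OR per SD
    orient_gamma_positive: bool = True
    target_r2: Optional[float] = None    # rescale gamma so total R2 is exact

    # metabolite panel
    K_med: int = 0
    class_names: tuple = DEFAULT_CLASS_NAMES
    class_labels: Optional[tuple] = None  # per-mediator class, len K_med
    J_med: int = 5                        # instruments per metabolite class
    eta_sd: float = 0.13                  # sd of SNP→class-latent effects
    kappa_class: dict = field(default_factory=dict)   # exposure→latent, per class
    theta_class: dict = field(default_factory=dict)   # latent→outcome, per class
    loading_range: tuple = (0.7, 1.0)

    # second adiposity trait sharing the exposure instruments (positive control)
    exposure2: bool = False
    rho_exposures: float = 0.7
    theta_direct2: float = 0.0

    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    ld: Optional[LDBlockConfig] = None
    palindrome_rate: float = 0.0
    strand_flip_rate: float = 0.0
    allele_swap_rate: float = 0.0
    exposure_id: str = "BMI"
    exposure2_id: str = "WHR"
    outcome_id: str = "CRC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J <= 0 or min(self.n_exposure, self.n_mediator, self.n_cases, self.n_controls) <= 0:
            raise ConfigError("counts and sample sizes must be positive")
        if self.tau2 < 0 or self.eta_sd < 0:
            raise ConfigError("variances must be non-negative")
        if not (0.0 < self.maf_range[0] < self.maf_range[1] <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo < hi <= 0.5")
        for rate in (self.palindrome_rate, self.strand_flip_rate, self.allele_swap_rate):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError("injection rates must lie in [0, 1]")
        if self.K_med and self.class_labels is None:
            names = self.class_names
            self.class_labels = tuple(names[m % len(names)] for m in range(self.K_med))
        if self.class_labels is not None and len(self.class_labels) != self.K_med:
            raise ConfigError("class_labels length must equal K_med")

    @property
    def mediator_ids(self) -> list:
        return [f"met{m:03d}" for m in range(self.K_med)]

    @property
    def theta_total(self) -> float:
        mediated = sum(
            self.kappa_class.get(c, 0.0) * self.theta_class.get(c, 0.0)
            for c in set(self.class_labels or ())
        )
        return self.theta_direct + mediated


@dataclass
class GroundTruth:
    """Truth manifest for one simulated scenario."""

    gamma: np.ndarray              # true effect on exposure, per variant (0 off-instruments)
    alpha: np.ndarray              # direct outcome effect, per variant
    variant_ids: list
    kappa_m: dict                  # mediator -> true exposure→mediator effect
    theta_m: dict                  # mediator -> marginal mediator→outcome effect
    mediator_class: dict
    mediator_loading: dict
    theta_direct: float
    theta_total: float
    is_true_mediator: dict
    snp_flags: pd.DataFrame        # per-variant roles and injected representation changes

    def recompute_total(self, kappa_class: dict, theta_class: dict) -> float:
        return self.theta_direct + sum(
            kappa_class.get(c, 0.0) * theta_class.get(c, 0.0) for c in set(self.mediator_class.values())
        )

    def to_dict(self) -> dict:
        return {
            "variant_ids": list(self.variant_ids),
            "gamma": [float(g) for g in self.gamma],
            "alpha": [float(a) for a in self.alpha],
            "kappa_m": {k: float(v) for k, v in self.kappa_m.items()},
            "theta_m": {k: float(v) for k, v in self.theta_m.items()},
            "mediator_class": dict(self.mediator_class),
            "mediator_loading": {k: float(v) for k, v in self.mediator_loading.items()},
            "theta_direct": float(self.theta_direct),
            "theta_total": float(self.theta_total),
            "is_true_mediator": dict(self.is_true_mediator),
            "snp_flags": self.snp_flags.to_dict(orient="list"),
        }


@dataclass
class ScenarioData:
    """All tables of one simulated two-sample study."""

    exposures: dict          # trait_id -> canonical DataFrame
    mediators: dict
    outcome: pd.DataFrame
    ld: LDMatrix
    truth: GroundTruth
    config: ScenarioConfig

    def tables(self) -> dict:
        out = dict(self.exposures)
        out.update(self.mediators)
        out[self.config.outcome_id] = self.outcome
        return out


def se_continuous(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def se_log_or(maf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    n = n_cases + n_controls
    v = n_cases / n
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * v * (1.0 - v))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, np.finfo(float).tiny)


def _observe(rng, true_beta, se) -> np.ndarray:
    return rng.normal(true_beta, se)


def _build_table(ids, ea, oa, eaf, true_beta, se, n, rng) -> pd.DataFrame:
    beta = _observe(rng, np.asarray(true_beta, dtype=float), se)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": n,
        }
    )


def simulate_summary_stats(cfg: ScenarioConfig) -> ScenarioData:
    """Draw one complete synthetic study; fixed seed gives byte-identical output."""
    rng = np.random.default_rng(cfg.seed)

    # --- exposure instruments (leads) -------------------------------------
    maf_lead = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.J)
    gamma_lead = rng.normal(0.0, math.sqrt(cfg.tau2), cfg.J)
    if cfg.orient_gamma_positive:
        gamma_lead = np.abs(gamma_lead)
    if cfg.target_r2 is not None:
        var_explained = float(np.sum(gamma_lead**2 * 2 * maf_lead * (1 - maf_lead)))
        gamma_lead *= math.sqrt(cfg.target_r2 / var_explained)

    pl = cfg.pleiotropy
    alpha_lead = np.zeros(cfg.J)
    invalid = rng.random(cfg.J) < pl.fraction
    if invalid.any() and (pl.mean != 0 or pl.sd != 0):
        noise = rng.normal(size=cfg.J)
        if pl.gamma_cor != 0 and np.std(gamma_lead) > 0:
            z_gamma = (gamma_lead - gamma_lead.mean()) / gamma_lead.std()
            noise = pl.gamma_cor * z_gamma + math.sqrt(1 - pl.gamma_cor**2) * noise
        alpha_lead[invalid] = pl.mean + pl.sd * noise[invalid]

    ids = [f"rs{j + 1}" for j in range(cfg.J)]
    maf, gamma, alpha = list(maf_lead), list(gamma_lead), list(alpha_lead)
    lead_of = list(range(cfg.J))  # block id per variant
    if cfg.ld is not None and cfg.ld.n_proxies > 0:
        r = math.sqrt(cfg.ld.r2)
        for j in range(cfg.J):
            for k in range(cfg.ld.n_proxies):
                ids.append(f"rs{j + 1}_p{k + 1}")
                maf.append(maf_lead[j])
                gamma.append(r * gamma_lead[j])  # attenuated marginal effect
                alpha.append(r * alpha_lead[j])
                lead_of.append(j)
    maf = np.array(maf)
    gamma = np.array(gamma)
    alpha = np.array(alpha)
    n_exp_snps = len(ids)

    # --- metabolite-class instruments -------------------------------------
    classes = sorted(set(cfg.class_labels or ()))
    eta: dict[str, np.ndarray] = {}
    for c in classes:
        class_maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.J_med)
        class_eta = rng.normal(0.0, cfg.eta_sd, cfg.J_med)
        if cfg.orient_gamma_positive:
            class_eta = np.abs(class_eta)
        eta[c] = class_eta
        for j in range(cfg.J_med):
            ids.append(f"rs_{c}_{j + 1}")
            maf = np.append(maf, class_maf[j])
            gamma = np.append(gamma, 0.0)
            alpha = np.append(alpha, 0.0)
            lead_of.append(-1)

    n_snps = len(ids)
    maf = np.asarray(maf)
    class_snp_slice: dict[str, slice] = {}
    offset = n_exp_snps
    for c in classes:
        class_snp_slice[c] = slice(offset, offset + cfg.J_med)
        offset += cfg.J_med

    # --- alleles -----------------------------------------------------------
    palindromic = rng.random(n_snps) < cfg.palindrome_rate
    pair_idx = rng.integers(0, 8, n_snps)
    pal_idx = rng.integers(0, 4, n_snps)
    ea = np.empty(n_snps, dtype=object)
    oa = np.empty(n_snps, dtype=object)
    for i in range(n_snps):
        ea[i], oa[i] = (
            _PALINDROMIC_PAIRS[pal_idx[i]] if palindromic[i] else _NONPALINDROMIC_PAIRS[pair_idx[i]]
        )

    # --- mediator truth ----------------------------------------------------
    med_ids = cfg.mediator_ids
    loading = {}
    kappa_m = {}
    theta_m = {}
    med_class = {}
    is_true = {}
    for m, mid in enumerate(med_ids):
        c = cfg.class_labels[m]
        lam = rng.uniform(*cfg.loading_range)
        loading[mid] = lam
        med_class[mid] = c
        kc = cfg.kappa_class.get(c, 0.0)
        tc = cfg.theta_class.get(c, 0.0)
        kappa_m[mid] = kc * lam
        theta_m[mid] = tc / lam  # marginal mediator→outcome slope seen by step 2
        is_true[mid] = bool(kc != 0.0 and tc != 0.0)

    # --- true per-variant effects per trait --------------------------------
    theta_total = cfg.theta_total
    true_exposure = gamma.copy()
    true_outcome = theta_total * gamma + alpha
    for c in classes:
        sl = class_snp_slice[c]
        true_outcome[sl] += cfg.theta_class.get(c, 0.0) * eta[c]

    true_exposure2 = None
    if cfg.exposure2:
        noise = rng.normal(0.0, math.sqrt(cfg.tau2), n_snps)
        true_exposure2 = np.where(
            gamma != 0,
            cfg.rho_exposures * gamma + math.sqrt(1 - cfg.rho_exposures**2) * noise,
            0.0,
        )
        true_outcome = true_outcome + cfg.theta_direct2 * true_exposure2

    # --- observed tables ----------------------------------------------------
    se_exp = se_continuous(maf, cfg.n_exposure)
    se_med = se_continuous(maf, cfg.n_mediator)
    se_out = se_log_or(maf, cfg.n_cases, cfg.n_controls)

    exposures = {
        cfg.exposure_id: _build_table(ids, ea, oa, maf, true_exposure, se_exp, cfg.n_exposure, rng)
    }
    if cfg.exposure2:
        exposures[cfg.exposure2_id] = _build_table(
            ids, ea, oa, maf, true_exposure2, se_exp, cfg.n_exposure, rng
        )

    mediators = {}
    for mid in med_ids:
        c = med_class[mid]
        true_med = kappa_m[mid] * gamma
        sl = class_snp_slice[c]
        true_med = true_med.copy()
        true_med[sl] += loading[mid] * eta[c]
        mediators[mid] = _build_table(ids, ea, oa, maf, true_med, se_med, cfg.n_mediator, rng)

    n_out = cfg.n_cases + cfg.n_controls
    outcome = _build_table(ids, ea, oa, maf, true_outcome, se_out, n_out, rng)

    # --- representation perturbations in the outcome table ------------------
    strand_flip = rng.random(n_snps) < cfg.strand_flip_rate
    swap = rng.random(n_snps) < cfg.allele_swap_rate
    ea_o = outcome["effect_allele"].to_numpy(dtype=object)
    oa_o = outcome["other_allele"].to_numpy(dtype=object)
    beta_o = outcome["beta"].to_numpy().copy()
    eaf_o = outcome["eaf"].to_numpy().copy()
    for i in range(n_snps):
        if strand_flip[i]:
            ea_o[i], oa_o[i] = COMPLEMENT[ea_o[i]], COMPLEMENT[oa_o[i]]
        if swap[i]:
            ea_o[i], oa_o[i] = oa_o[i], ea_o[i]
            beta_o[i] = -beta_o[i]
            eaf_o[i] = 1.0 - eaf_o[i]
    outcome["effect_allele"] = ea_o
    outcome["other_allele"] = oa_o
    outcome["beta"] = beta_o
    outcome["eaf"] = eaf_o
    outcome["pval"] = _pvals(outcome["beta"].to_numpy(), outcome["se"].to_numpy())

    # --- LD matrix -----------------------------------------------------------
    r2_mat = np.eye(n_snps)
    if cfg.ld is not None and cfg.ld.n_proxies > 0:
        blocks: dict[int, list] = {}
        for i, b in enumerate(lead_of):
            if b >= 0:
                blocks.setdefault(b, []).append(i)
        for members in blocks.values():
            for a_i in members:
                for b_i in members:
                    if a_i != b_i:
                        r2_mat[a_i, b_i] = cfg.ld.r2
    ld = LDMatrix(list(ids), r2_mat)

    window = (0.42, 0.58)
    flags = pd.DataFrame(
        {
            "variant_id": ids,
            "role": ["exposure_instrument"] * n_exp_snps
            + [f"class_instrument:{c}" for c in classes for _ in range(cfg.J_med)],
            "is_palindromic": palindromic,
            "strand_flipped_in_outcome": strand_flip,
            "swapped_in_outcome": swap,
            "eaf_resolvable": ~((maf > window[0]) & (maf < window[1])),
            "valid_instrument": alpha == 0.0,
        }
    )
    truth = GroundTruth(
        gamma=gamma,
        alpha=alpha,
        variant_ids=list(ids),
        kappa_m=kappa_m,
        theta_m=theta_m,
        mediator_class=med_class,
        mediator_loading=loading,
        theta_direct=cfg.theta_direct,
        theta_total=theta_total,
        is_true_mediator=is_true,
        snp_flags=flags,
    )
    return ScenarioData(exposures, mediators, outcome, ld, truth, cfg)


def mediation_panel_config(
    n_true_per_class: int = 10,
    true_classes: Sequence[str] = ("VLDL_lipids", "amino_acids"),
    kappa: float = 0.25,
    theta_med: float = 0.2,
    theta_direct: float = 0.15,
    K_med: int = 123,
    assoc_kappa: float = 0.25,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """A mediation study condition: a 123-trait panel with two true mediator
    classes of ``n_true_per_class`` members each.

    Non-true classes keep an exposure→metabolite association (``assoc_kappa``)
    for a share of classes, emulating a panel where most metabolites respond
    to adiposity but do not transmit risk; true classes additionally carry a
    latent→outcome effect ``theta_med``.
    """
    class_names = list(DEFAULT_CLASS_NAMES)
    labels = []
    for c in true_classes:
        labels.extend([c] * n_true_per_class)
    rest = [c for c in class_names if c not in true_classes]
    m = 0
    while len(labels) < K_med:
        labels.append(rest[m % len(rest)])
        m += 1
    kappa_class = {c: kappa for c in true_classes}
    # six of the remaining classes respond to the exposure without mediating
    for c in rest[:6]:
        kappa_class[c] = assoc_kappa
    theta_class = {c: theta_med for c in true_classes}
    return ScenarioConfig(
        K_med=K_med,
        class_labels=tuple(labels[:K_med]),
        kappa_class=kappa_class,
        theta_class=theta_class,
        theta_direct=theta_direct,
        seed=seed,
        **overrides,
    )


def emit_panel_fixture(cfg: ScenarioConfig, out_dir: str | Path) -> dict:
    """Write the full fixture set for an end-to-end run: one table per trait,
    the LD matrix, the truth manifest and a matching pipeline config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_summary_stats(cfg)
    paths = {}
    for trait, frame in data.tables().items():
        p = out / f"{trait}.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format="%.17g")
        paths[trait] = str(p)
    ld_frame = pd.DataFrame(data.ld.r2, columns=data.ld.variant_ids)
    ld_frame.insert(0, "variant_id", data.ld.variant_ids)
    ld_path = out / "ld.tsv"
    ld_frame.to_csv(ld_path, sep="\t", index=False, float_format="%.17g")
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(data.truth.to_dict(), fh, indent=2)
    pipeline_cfg = {
        "exposures": list(data.exposures.keys()),
        "outcomes": [cfg.outcome_id],
        "mediators": {m: data.truth.mediator_class[m] for m in data.mediators},
        "fdr_alpha": 0.05,
        "p_instrument": 5e-8,
        "r2_clump": 0.001,
        "seed": cfg.seed,
        "tables": paths,
        "ld": str(ld_path),
        "n_by_trait": {
            **{e: cfg.n_exposure for e in data.exposures},
            **{m: cfg.n_mediator for m in data.mediators},
            cfg.outcome_id: cfg.n_cases + cfg.n_controls,
        },
        "n_cases": cfg.n_cases,
    }
    cfg_path = out / "pipeline_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    paths.update({"ld": str(ld_path), "truth": str(truth_path), "config": str(cfg_path)})
    return paths


def simulate_harmonized(cfg: ScenarioConfig, select: bool = False):
    """One simulated exposure→outcome harmonized set, ready for estimation.

    Runs the generator, validates the tables, optionally applies p-value /
    LD instrument selection, and harmonizes onto the exposure allele frame.
    Returns ``(HarmonizedSet, ScenarioData)``.
    """
    from .instruments import harmonize, select_instruments
    from .io import frame_to_records

    data = simulate_summary_stats(cfg)
    exp_records, _ = frame_to_records(data.exposures[cfg.exposure_id], cfg.exposure_id)
    out_records, _ = frame_to_records(data.outcome, cfg.outcome_id)
    if select:
        exp_records = select_instruments(exp_records, data.ld)
    hset = harmonize(exp_records, out_records, outcome_binary=True)
    return hset, data


def read_ld_matrix(path: str | Path) -> LDMatrix:
    frame = pd.read_csv(path, sep="\t")
    ids = frame["variant_id"].tolist()
    return LDMatrix(ids, frame[ids].to_numpy(dtype=float))
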