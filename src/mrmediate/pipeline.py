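"""Orchestration of the full mediation design.

Stages, in order: total-effect MR for each exposure×outcome (all applicable
estimators plus heterogeneity, leave-one-out and scatter tables); step-1 MR
of each exposure on every metabolite; a Benjamini-Hochberg FDR screen
(within exposure, union across exposures) to pick metabolites for step 2;
step-2 MR of each selected metabolite on the outcome; sign-consistency
classification of candidate mediation paths; and multivariable MR of each
exposure adjusted one-at-a-time for a representative metabolite per class
(chosen by maximal aggregate instrument F) and for the alternative adiposity
trait as a positive control.  Each stage writes one tab-delimited table and
the run ends with a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .estimators import (
    BootstrapConfig,
    MREstimate,
    ivw,
    leave_one_out,
    mr_egger,
    scatter_data,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from .exceptions import InsufficientInstrumentsError, MRError
from .instruments import (
    HarmonizedSet,
    LDMatrix,
    harmonize,
    instrument_strength,
    select_instruments,
)
from .mvmr import MultiHarmonizedSet, mvmr_fit


@dataclass
class PipelineConfig:
    """Configuration of one mediation-study run."""

    exposures: list
    mediators: dict                      # mediator trait_id -> class label
    outcomes: list
    fdr_alpha: float = 0.05
    p_instrument: float = 5e-8
    r2_clump: float = 0.001
    fdr_family: str = "per_exposure"     # or "joint"
    bootstrap_seed: int = 0
    bootstrap_reps: int = 1000
    mvmr_snp_restrict: dict = field(default_factory=dict)  # exposure -> allowed SNP ids
    n_by_trait: dict = field(default_factory=dict)
    binary_outcomes: Optional[list] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.fdr_family not in ("per_exposure", "joint"):
            raise ValueError("fdr_family must be 'per_exposure' or 'joint'")
        if self.binary_outcomes is None:
            self.binary_outcomes = list(self.outcomes)

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass
class MediationRecord:
    """One exposure→mediator→outcome path with its two-step estimates."""

    exposure: str
    mediator: str
    outcome: str
    step1: MREstimate
    step1_fdr_p: float
    step2: MREstimate
    label: str = ""          # consistent | inconsistent | weak_step2

    @property
    def sign_consistent(self) -> Optional[bool]:
        return None if self.label == "" else self.label == "consistent"


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj(i) = min over ranks k >= rank(i) of m * p(k) / k, clipped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = m * p[order] / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def screen_mediators(config: PipelineConfig, step1: pd.DataFrame) -> tuple[list, pd.DataFrame]:
    """FDR screen of step-1 results; returns (selected mediators, annotated table).

    ``step1`` needs columns exposure, mediator, pval.  The default family is
    within-exposure across the panel, with selection the union over
    exposures of mediators with adjusted p <= fdr_alpha.
    """
    step1 = step1.copy()
    if config.fdr_family == "joint":
        step1["pval_fdr"] = bh_fdr(step1["pval"])
    else:
        step1["pval_fdr"] = np.nan
        for exp in step1["exposure"].unique():
            mask = step1["exposure"] == exp
            step1.loc[mask, "pval_fdr"] = bh_fdr(step1.loc[mask, "pval"])
    hits = step1.loc[step1["pval_fdr"] <= config.fdr_alpha, "mediator"]
    selected = sorted(set(hits))
    step1["selected"] = step1["mediator"].isin(selected)
    return selected, step1


def classify_mediation(records: Sequence[MediationRecord], total: MREstimate) -> list:
    """Label each path consistent/inconsistent with mediating the total effect.

    A path is consistent when sign(step1) * sign(step2) equals the sign of
    the total effect; paths whose step-2 interval spans zero are labelled
    weak_step2 instead.
    """
    out = []
    for rec in records:
        if rec.step2.ci_lower < 0.0 < rec.step2.ci_upper:
            label = "weak_step2"
        else:
            prod = math.copysign(1.0, rec.step1.beta) * math.copysign(1.0, rec.step2.beta)
            label = "consistent" if prod == math.copysign(1.0, total.beta) else "inconsistent"
        out.append(dataclasses.replace(rec, label=label))
    return out


def select_representatives(diagnostics: pd.DataFrame) -> dict:
    """One mediator per class: maximal aggregate instrument F, ties lexicographic.

    ``diagnostics`` needs columns mediator, class, f_aggregate.
    """
    reps = {}
    for cls, group in diagnostics.groupby("class"):
        ordered = group.sort_values(["f_aggregate", "mediator"], ascending=[False, True])
        top_f = ordered["f_aggregate"].iloc[0]
        ties = sorted(ordered.loc[ordered["f_aggregate"] == top_f, "mediator"])
        reps[cls] = ties[0]
    return reps


# ---------------------------------------------------------------------------
# estimation helpers


def estimate_all(hset: HarmonizedSet, boot: BootstrapConfig | None = None) -> tuple[list, Optional[object]]:
    """All applicable estimators on one harmonized set.

    Wald ratio for a single instrument; IVW + weighted median from 2; the
    intercept regression and weighted mode from 3.  Returns
    (estimates, heterogeneity or None).
    """
    boot = boot or BootstrapConfig()
    j = hset.n_kept
    if j == 0:
        raise InsufficientInstrumentsError("no kept pairs")
    if j == 1:
        return [wald_ratio(hset.kept[0], hset)], None
    est, het = ivw(hset)
    results = [est]
    if j >= 3:
        slope, intercept, _ = mr_egger(hset)
        results.extend([slope, intercept])
    results.append(weighted_median(hset, boot))
    if j >= 3:
        results.append(weighted_mode(hset, boot=boot))
    return results, het


def primary_estimate(hset: HarmonizedSet) -> MREstimate:
    """IVW when >= 2 instruments, otherwise the Wald ratio."""
    if hset.n_kept >= 2:
        return ivw(hset)[0]
    if hset.n_kept == 1:
        return wald_ratio(hset.kept[0], hset)
    raise InsufficientInstrumentsError("no kept pairs")


def harmonize_multi(
    exposure_records: dict,
    outcome_records: Sequence,
    snp_ids: Sequence[str],
    outcome: str,
    outcome_binary: bool = True,
) -> MultiHarmonizedSet:
    """Harmonize several exposures and one outcome onto a shared frame.

    Each exposure is harmonized against the outcome independently; only
    variants kept for every exposure enter the joint set.
    """
    snp_set = set(snp_ids)
    per_exposure = {}
    for exp_id, records in exposure_records.items():
        subset = [r for r in records if r.variant_id in snp_set]
        hset = harmonize(subset, list(outcome_records), outcome_binary=outcome_binary)
        per_exposure[exp_id] = {p.variant_id: p for p in hset.kept}
    shared = sorted(set.intersection(*(set(d) for d in per_exposure.values())))
    exposure_ids = list(exposure_records)
    rows_bx, rows_sx, by, sy = [], [], [], []
    for vid in shared:
        rows_bx.append([per_exposure[e][vid].beta_exposure for e in exposure_ids])
        rows_sx.append([per_exposure[e][vid].se_exposure for e in exposure_ids])
        ref = per_exposure[exposure_ids[0]][vid]
        by.append(ref.beta_outcome)
        sy.append(ref.se_outcome)
    return MultiHarmonizedSet(
        outcome=outcome,
        exposure_ids=exposure_ids,
        variant_ids=shared,
        beta_x=np.array(rows_bx) if rows_bx else np.empty((0, len(exposure_ids))),
        se_x=np.array(rows_sx) if rows_sx else np.empty((0, len(exposure_ids))),
        beta_y=np.array(by),
        se_y=np.array(sy),
        outcome_binary=outcome_binary,
    )


def _estimate_row(est: MREstimate, **extra) -> dict:
    row = {
        "exposure": est.exposure,
        "outcome": est.outcome,
        "method": est.method,
        "nsnp": est.nsnp,
        "b": est.beta,
        "se": est.se,
        "ci_lower": est.ci_lower,
        "ci_upper": est.ci_upper,
        "pval": est.pval,
        "or": math.exp(est.beta) if est.outcome_binary else np.nan,
    }
    row.update(extra)
    return row


def run_mediation_study(
    config: PipelineConfig,
    tables: dict,
    ld: LDMatrix,
    out_dir: str | Path,
) -> dict:
    """Execute the full design and write stage tables plus a JSON manifest.

    ``tables`` maps trait_id to a canonical summary-statistics DataFrame
    covering every trait in the config.  Stage failures are recorded in the
    manifest; stages that depend on a failed stage are skipped while
    independent stages proceed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    boot = BootstrapConfig(n_reps=config.bootstrap_reps, seed=config.bootstrap_seed)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "fdr_alpha": config.fdr_alpha,
        "seed": config.bootstrap_seed,
        "stages": {},
        "tables": {},
    }

    records: dict[str, list] = {}
    rejections: dict[str, dict] = {}
    for trait, frame in tables.items():
        recs, report = sio.frame_to_records(frame, trait)
        records[trait] = recs
        rejections[trait] = report
    manifest["rejections"] = {t: r["rows_rejected"] for t, r in rejections.items()}

    instruments: dict[str, list] = {}
    for trait in list(config.exposures) + list(config.mediators):
        instruments[trait] = select_instruments(
            records[trait], ld, config.p_instrument, config.r2_clump
        )
    manifest["n_instruments"] = {t: len(v) for t, v in instruments.items()}

    def is_binary(outcome):
        return outcome in (config.binary_outcomes or [])

    # --- stage 1: total effects -------------------------------------------
    total_rows, loo_rows, scatter_rows = [], [], []
    totals: dict[tuple, MREstimate] = {}
    try:
        for exp in config.exposures:
            for outc in config.outcomes:
                hset = harmonize(
                    instruments[exp], records[outc], outcome_binary=is_binary(outc)
                )
                ests, het = estimate_all(hset, boot)
                totals[(exp, outc)] = ests[0]
                for e in ests:
                    total_rows.append(
                        _estimate_row(
                            e,
                            q=het.Q if het else np.nan,
                            q_df=het.df if het else np.nan,
                            q_pval=het.pval if het else np.nan,
                        )
                    )
                if hset.n_kept >= 3:
                    for vid, e in leave_one_out(hset):
                        loo_rows.append(_estimate_row(e, dropped=vid if vid else "none"))
                    points, lines = scatter_data(hset, ests)
                    points.insert(0, "exposure", exp)
                    points.insert(1, "outcome", outc)
                    scatter_rows.append(points)
        _write(out / "total_effects.tsv", pd.DataFrame(total_rows), manifest)
        _write(out / "leave_one_out.tsv", pd.DataFrame(loo_rows), manifest)
        if scatter_rows:
            _write(out / "scatter_data.tsv", pd.concat(scatter_rows, ignore_index=True), manifest)
        manifest["stages"]["total_effects"] = "ok"
    except MRError as err:
        manifest["stages"]["total_effects"] = f"failed: {err}"

    # --- stage 2: step-1 exposure -> mediator -------------------------------
    step1_frame = None
    try:
        rows = []
        for exp in config.exposures:
            for med in config.mediators:
                hset = harmonize(instruments[exp], records[med], outcome_binary=False)
                est = primary_estimate(hset)
                rows.append(
                    {
                        "exposure": exp,
                        "mediator": med,
                        "class": config.mediators[med],
                        "nsnp": est.nsnp,
                        "b": est.beta,
                        "se": est.se,
                        "ci_lower": est.ci_lower,
                        "ci_upper": est.ci_upper,
                        "pval": est.pval,
                    }
                )
        step1_frame = pd.DataFrame(rows)
        manifest["stages"]["step1"] = "ok"
    except MRError as err:
        manifest["stages"]["step1"] = f"failed: {err}"

    # --- stage 3: FDR screen -------------------------------------------------
    selected: list = []
    if step1_frame is not None and len(step1_frame):
        selected, step1_frame = screen_mediators(config, step1_frame)
        _write(out / "step1_metabolites.tsv", step1_frame, manifest)
        manifest["stages"]["screen"] = "ok"
        manifest["selected_mediators"] = selected
    else:
        manifest["stages"]["screen"] = "skipped: step1 unavailable"

    # --- stage 4: step-2 mediator -> outcome ---------------------------------
    step2: dict[tuple, MREstimate] = {}
    if manifest["stages"].get("screen") == "ok":
        rows = []
        for med in selected:
            for outc in config.outcomes:
                hset = harmonize(
                    instruments[med], records[outc], outcome_binary=is_binary(outc)
                )
                try:
                    est = primary_estimate(hset)
                except InsufficientInstrumentsError:
                    continue
                step2[(med, outc)] = est
                rows.append(
                    _estimate_row(est, mediator=med, **{"class": config.mediators[med]})
                )
        _write(out / "step2_metabolites.tsv", pd.DataFrame(rows), manifest)
        manifest["stages"]["step2"] = "ok"
    else:
        manifest["stages"]["step2"] = "skipped"

    # --- stage 5: mediation classification -----------------------------------
    mediation_records: list = []
    if manifest["stages"].get("step2") == "ok" and step1_frame is not None:
        rows = []
        for exp in config.exposures:
            for outc in config.outcomes:
                total = totals.get((exp, outc))
                if total is None:
                    continue
                recs = []
                for med in selected:
                    if (med, outc) not in step2:
                        continue
                    s1 = step1_frame[
                        (step1_frame["exposure"] == exp) & (step1_frame["mediator"] == med)
                    ].iloc[0]
                    step1_est = MREstimate(
                        method="ivw",
                        beta=float(s1["b"]),
                        se=float(s1["se"]),
                        ci_lower=float(s1["ci_lower"]),
                        ci_upper=float(s1["ci_upper"]),
                        pval=float(s1["pval"]),
                        nsnp=int(s1["nsnp"]),
                        exposure=exp,
                        outcome=med,
                    )
                    recs.append(
                        MediationRecord(
                            exposure=exp,
                            mediator=med,
                            outcome=outc,
                            step1=step1_est,
                            step1_fdr_p=float(s1["pval_fdr"]),
                            step2=step2[(med, outc)],
                        )
                    )
                for rec in classify_mediation(recs, total):
                    mediation_records.append(rec)
                    rows.append(
                        {
                            "exposure": rec.exposure,
                            "mediator": rec.mediator,
                            "outcome": rec.outcome,
                            "step1_b": rec.step1.beta,
                            "step1_fdr_p": rec.step1_fdr_p,
                            "step2_b": rec.step2.beta,
                            "total_b": total.beta,
                            "label": rec.label,
                        }
                    )
        _write(out / "mediation_classification.tsv", pd.DataFrame(rows), manifest)
        manifest["stages"]["classification"] = "ok"
    else:
        manifest["stages"]["classification"] = "skipped"

    # --- stage 6: representatives and MVMR ----------------------------------
    try:
        diag_rows = []
        for med in config.mediators:
            if not instruments[med]:
                continue
            n_med = config.n_by_trait.get(med) or max(r.n for r in instruments[med])
            diag = instrument_strength(instruments[med], n=n_med)
            diag_rows.append(
                {
                    "mediator": med,
                    "class": config.mediators[med],
                    "f_aggregate": diag.f_aggregate,
                    "r2_total": diag.r2_total,
                    "nsnp": diag.k,
                }
            )
        diag_frame = pd.DataFrame(diag_rows)
        reps = select_representatives(diag_frame) if len(diag_rows) else {}
        manifest["representatives"] = reps
        _write(out / "instrument_strength.tsv", diag_frame, manifest)

        mvmr_rows = []
        for exp in config.exposures:
            covariates = [reps[c] for c in sorted(reps)]
            covariates += [e for e in config.exposures if e != exp]  # positive control
            for cov in covariates:
                for outc in config.outcomes:
                    exp_snps = [a.variant_id for a in instruments[exp]]
                    restrict = config.mvmr_snp_restrict.get(exp)
                    if restrict is not None:
                        exp_snps = [v for v in exp_snps if v in set(restrict)]
                    snp_ids = exp_snps + [a.variant_id for a in instruments[cov]]
                    mset = harmonize_multi(
                        {exp: records[exp], cov: records[cov]},
                        records[outc],
                        snp_ids,
                        outc,
                        outcome_binary=is_binary(outc),
                    )
                    try:
                        res = mvmr_fit(mset)
                    except MRError as err:
                        manifest.setdefault("mvmr_failures", []).append(
                            {"exposure": exp, "covariate": cov, "outcome": outc, "error": str(err)}
                        )
                        continue
                    uni = totals.get((exp, outc))
                    for trait_id, est in res.estimates.items():
                        mvmr_rows.append(
                            _estimate_row(
                                est,
                                adjusted_for=cov if trait_id == exp else exp,
                                conditional_f=res.conditional_f.get(trait_id, np.nan),
                                q_mv=res.Q_mv,
                                univariable_b=uni.beta
                                if (uni is not None and trait_id == exp)
                                else np.nan,
                            )
                        )
        _write(out / "mvmr_adjusted.tsv", pd.DataFrame(mvmr_rows), manifest)
        manifest["stages"]["mvmr"] = "ok"
    except MRError as err:
        manifest["stages"]["mvmr"] = f"failed: {err}"

    manifest["n_mediation_records"] = len(mediation_records)
    sio.write_json_report(manifest, out / "manifest.json")
    return manifest


def _write(path: Path, frame: pd.DataFrame, manifest: dict) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    manifest["tables"][path.name] = len(frame)


def load_pipeline_inputs(config_path: str | Path) -> tuple[PipelineConfig, dict, LDMatrix]:
    """Load a fixture-style YAML config plus its referenced tables and LD."""
    from .simulate import read_ld_matrix

    with open(config_path) as fh:
        doc = yaml.safe_load(fh)
    tables = {t: pd.read_csv(p, sep="\t") for t, p in doc["tables"].items()}
    ld = read_ld_matrix(doc["ld"])
    config = PipelineConfig(
        exposures=doc["exposures"],
        mediators=doc["mediators"],
        outcomes=doc["outcomes"],
        fdr_alpha=doc.get("fdr_alpha", 0.05),
        p_instrument=doc.get("p_instrument", 5e-8),
        r2_clump=doc.get("r2_clump", 0.001),
        bootstrap_seed=doc.get("seed", 0),
        n_by_trait=doc.get("n_by_trait", {}),
    )
    return config, tables, ld
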