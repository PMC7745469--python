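"""Instrument selection, allele harmonization and strength diagnostics.

Instruments are genome-wide-significant variants pruned to mutual linkage
disequilibrium below an r-squared threshold by greedy p-value-ordered
clumping.  Exposure and outcome associations are then aligned onto a shared
effect-allele frame: allele swaps flip the outcome beta, strand flips are
resolved by complementing, and palindromic (A/T, C/G) variants are aligned
by allele-frequency agreement or dropped when the frequency is too close to
0.5 to be informative.

Instrument strength is summarised by per-variant F = (beta/se)^2, the
per-variant variance explained R^2 = beta^2 / (beta^2 + n * se^2) (the
large-sample approximation for a standardized trait), and the aggregate
F = (R^2 / (1 - R^2)) * ((N - K - 1) / K) over K independent instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import DataError, InsufficientInstrumentsError
from .io import StudyMeta, SummaryAssociation

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: effect-allele frequencies inside this open interval cannot resolve a
#: palindromic variant's strand
DEFAULT_PALINDROME_EAF_WINDOW = (0.42, 0.58)


@dataclass
class LDMatrix:
    """Pairwise r-squared among a set of variants (unit diagonal, symmetric)."""

    variant_ids: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise DataError("LD matrix shape does not match variant list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise DataError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise DataError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise DataError("LD r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(variant_ids)))


@dataclass(frozen=True)
class HarmonizedPair:
    """One variant's exposure and outcome effects on a shared allele frame."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_aligned: Optional[float]
    status: str  # kept | sign_flipped | strand_flipped | dropped_*
    effect_allele: str = ""
    other_allele: str = ""

    @property
    def is_kept(self) -> bool:
        return not self.status.startswith("dropped")


@dataclass
class HarmonizedSet:
    """Variant-aligned exposure and outcome effects ready for estimation."""

    exposure: str
    outcome: str
    pairs: list = field(default_factory=list)
    outcome_binary: bool = False

    @property
    def kept(self) -> list:
        return [p for p in self.pairs if p.is_kept]

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) of kept pairs."""
        kept = self.kept
        bx = np.array([p.beta_exposure for p in kept])
        sx = np.array([p.se_exposure for p in kept])
        by = np.array([p.beta_outcome for p in kept])
        sy = np.array([p.se_outcome for p in kept])
        return bx, sx, by, sy

    def status_counts(self) -> dict:
        counts: dict[str, int] = {}
        for p in self.pairs:
            counts[p.status] = counts.get(p.status, 0) + 1
        return counts

    @classmethod
    def from_arrays(
        cls,
        bx,
        sx,
        by,
        sy,
        exposure: str = "exposure",
        outcome: str = "outcome",
        variant_ids: Optional[Sequence[str]] = None,
        outcome_binary: bool = False,
    ) -> "HarmonizedSet":
        """Build a pre-aligned set directly from effect arrays (all kept)."""
        bx, sx, by, sy = (np.asarray(a, dtype=float) for a in (bx, sx, by, sy))
        ids = list(variant_ids) if variant_ids is not None else [f"snp{i}" for i in range(len(bx))]
        pairs = [
            HarmonizedPair(ids[j], bx[j], sx[j], by[j], sy[j], None, "kept")
            for j in range(len(bx))
        ]
        return cls(exposure, outcome, pairs, outcome_binary)


@dataclass
class InstrumentDiagnostics:
    """Per-variant and aggregate instrument-strength measures."""

    variant_ids: list
    f_per_snp: np.ndarray
    r2_per_snp: np.ndarray
    r2_total: float
    f_aggregate: float
    k: int
    n: int

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.f_per_snp)) if self.k else float("nan")


def select_instruments(
    assocs: Sequence[SummaryAssociation],
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
) -> list:
    """Greedy LD clumping of genome-wide-significant variants.

    Candidates with p below ``p_threshold`` are ranked by p (ties broken by
    variant_id); the best remaining variant is kept and every candidate in
    LD with it (r^2 >= ``r2_threshold``) is removed, until none remain.
    """
    candidates = [a for a in assocs if a.pval < p_threshold]
    for a in candidates:
        if a.variant_id not in ld:
            raise DataError(f"variant {a.variant_id!r} absent from LD matrix")
    candidates.sort(key=lambda a: (a.pval, a.variant_id))
    kept: list[SummaryAssociation] = []
    removed: set[str] = set()
    for cand in candidates:
        if cand.variant_id in removed:
            continue
        kept.append(cand)
        for other in candidates:
            if other.variant_id in removed or other.variant_id == cand.variant_id:
                continue
            if ld.lookup(cand.variant_id, other.variant_id) >= r2_threshold:
                removed.add(other.variant_id)
    return kept


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def _eaf_informative(eaf: Optional[float], window: tuple) -> bool:
    return eaf is not None and not (window[0] < eaf < window[1])


def harmonize(
    exposure: Sequence[SummaryAssociation],
    outcome: Sequence[SummaryAssociation],
    palindrome_eaf_window: tuple = DEFAULT_PALINDROME_EAF_WINDOW,
    outcome_binary: bool = False,
) -> HarmonizedSet:
    """Align outcome associations onto the exposure effect-allele frame.

    For each variant shared between the studies the outcome alleles are
    matched to the exposure's as-is, swapped, strand-complemented, or
    complemented-and-swapped; swaps negate the outcome beta and reflect its
    frequency.  Palindromic variants are aligned by frequency agreement only
    when both studies' frequencies fall outside ``palindrome_eaf_window``,
    and dropped otherwise.  Nothing is fatal; every exclusion carries a
    status reason.
    """
    out_by_id = {}
    for rec in outcome:
        if rec.variant_id in out_by_id:
            raise DataError(f"duplicate variant_id {rec.variant_id!r} in outcome")
        out_by_id[rec.variant_id] = rec

    pairs: list[HarmonizedPair] = []
    seen: set[str] = set()
    for exp in exposure:
        if exp.variant_id in seen:
            raise DataError(f"duplicate variant_id {exp.variant_id!r} in exposure")
        seen.add(exp.variant_id)
        out = out_by_id.get(exp.variant_id)

        def pair(status, beta_out=None, se_out=None, eaf=None):
            return HarmonizedPair(
                variant_id=exp.variant_id,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=beta_out if beta_out is not None else float("nan"),
                se_outcome=se_out if se_out is not None else float("nan"),
                eaf_aligned=eaf if eaf is not None else exp.eaf,
                status=status,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
            )

        if out is None:
            pairs.append(pair("dropped_missing_outcome"))
            continue

        ea_x, oa_x = exp.effect_allele, exp.other_allele
        ea_y, oa_y = out.effect_allele, out.other_allele

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                pairs.append(pair("dropped_incompatible"))
                continue
            if not (
                _eaf_informative(exp.eaf, palindrome_eaf_window)
                and _eaf_informative(out.eaf, palindrome_eaf_window)
            ):
                pairs.append(pair("dropped_palindromic"))
                continue
            # orient the outcome record so its effect allele matches textually
            beta_y, eaf_y = out.beta, out.eaf
            if ea_y != ea_x:
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            # frequency disagreement means the studies report opposite strands
            if (exp.eaf < 0.5) == (eaf_y < 0.5):
                pairs.append(pair("kept", beta_y, out.se, exp.eaf))
            else:
                pairs.append(pair("sign_flipped", -beta_y, out.se, exp.eaf))
            continue

        comp_pair = (COMPLEMENT[ea_y], COMPLEMENT[oa_y])
        if (ea_y, oa_y) == (ea_x, oa_x):
            pairs.append(pair("kept", out.beta, out.se, out.eaf))
        elif (oa_y, ea_y) == (ea_x, oa_x):
            eaf = None if out.eaf is None else 1.0 - out.eaf
            pairs.append(pair("sign_flipped", -out.beta, out.se, eaf))
        elif comp_pair == (ea_x, oa_x):
            pairs.append(pair("strand_flipped", out.beta, out.se, out.eaf))
        elif comp_pair[::-1] == (ea_x, oa_x):
            eaf = None if out.eaf is None else 1.0 - out.eaf
            pairs.append(pair("strand_flipped", -out.beta, out.se, eaf))
        else:
            pairs.append(pair("dropped_incompatible"))

    return HarmonizedSet(
        exposure=exposure[0].trait_id if exposure else "exposure",
        outcome=outcome[0].trait_id if outcome else "outcome",
        pairs=pairs,
        outcome_binary=outcome_binary,
    )


def orient_positive_exposure(hset: HarmonizedSet) -> HarmonizedSet:
    """Flip each kept pair so every exposure beta is non-negative.

    Negating both betas of a pair re-expresses the association relative to
    the opposite allele; slope-type estimates are invariant under it, but the
    pleiotropy-intercept regression requires the convention.
    """
    if hset.n_kept < 1:
        raise InsufficientInstrumentsError("orientation requires at least one kept pair")
    new_pairs = []
    for p in hset.pairs:
        if p.is_kept and p.beta_exposure < 0:
            eaf = None if p.eaf_aligned is None else 1.0 - p.eaf_aligned
            new_pairs.append(
                replace(
                    p,
                    beta_exposure=-p.beta_exposure,
                    beta_outcome=-p.beta_outcome,
                    eaf_aligned=eaf,
                    effect_allele=p.other_allele,
                    other_allele=p.effect_allele,
                )
            )
        else:
            new_pairs.append(p)
    return HarmonizedSet(hset.exposure, hset.outcome, new_pairs, hset.outcome_binary)


def instrument_strength(
    source,
    meta: Optional[StudyMeta] = None,
    n: Optional[int] = None,
) -> InstrumentDiagnostics:
    """Instrument-strength diagnostics from exposure betas and SEs.

    ``source`` is a :class:`HarmonizedSet` or a list of exposure
    :class:`SummaryAssociation` records; the exposure sample size comes from
    ``n``, ``meta.n_total``, or the records themselves.
    """
    if isinstance(source, HarmonizedSet):
        kept = source.kept
        ids = [p.variant_id for p in kept]
        betas = np.array([p.beta_exposure for p in kept])
        ses = np.array([p.se_exposure for p in kept])
        n_eff = n if n is not None else (meta.n_total if meta is not None else None)
    else:
        ids = [a.variant_id for a in source]
        betas = np.array([a.beta for a in source])
        ses = np.array([a.se for a in source])
        n_eff = n if n is not None else (meta.n_total if meta is not None else None)
        if n_eff is None and len(source) and source[0].n:
            n_eff = int(max(a.n for a in source))
    if n_eff is None or n_eff <= 0:
        raise DataError("exposure sample size required for instrument diagnostics")

    f_per = (betas / ses) ** 2
    r2_per = betas**2 / (betas**2 + n_eff * ses**2)
    r2_total = float(np.sum(r2_per))
    k = len(ids)
    if k == 0:
        raise InsufficientInstrumentsError("no instruments to diagnose")
    f_agg = (r2_total / (1.0 - r2_total)) * ((n_eff - k - 1) / k)
    return InstrumentDiagnostics(
        variant_ids=ids,
        f_per_snp=f_per,
        r2_per_snp=r2_per,
        r2_total=r2_total,
        f_aggregate=float(f_agg),
        k=k,
        n=int(n_eff),
    )
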