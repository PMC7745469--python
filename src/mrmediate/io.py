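"""Reading, validating and writing GWAS summary-statistics and result tables.

The canonical on-disk dialect is tab-delimited UTF-8 with one header row.
Arbitrary source headers are adapted through a :class:`ColumnMap` (loadable
from YAML).  Rows that violate the record invariants are dropped, not
repaired, and counted in a rejection report so that
``rows_in == rows_out + rows_rejected`` always holds.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import ConfigError, DataError

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

#: canonical column order of a summary-statistics table
CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


@dataclass(frozen=True)
class SummaryAssociation:
    """One variant's estimated effect on one trait.

    ``beta`` is per effect-allele copy, in SD units for continuous traits and
    log-odds for a binary outcome.  ``eaf`` (effect-allele frequency) may be
    missing (``None``); such variants cannot be strand-resolved if
    palindromic.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    trait_id: str
    eaf: Optional[float] = None

    def invariant_violation(self) -> Optional[str]:
        """Return a rejection-reason tag, or ``None`` if the record is valid."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not (math.isfinite(self.beta)):
            return "missing_beta"
        if not (math.isfinite(self.se) and self.se > 0):
            return "nonpositive_se"
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            return "eaf_out_of_range"
        if not (0.0 < self.pval <= 1.0):
            return "pval_out_of_range"
        if not (self.n > 0):
            return "nonpositive_n"
        return None

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class StudyMeta:
    """Study-level context for one trait's GWAS."""

    trait_id: str
    trait_type: str = "continuous"  # or "binary"
    unit: str = "SD"  # "logOR" for binary outcomes
    n_total: Optional[int] = None
    n_cases: Optional[int] = None
    ancestry_note: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.n_cases is None:
                raise ConfigError("binary trait requires n_cases")
            if self.n_total is not None and not (0 < self.n_cases < self.n_total):
                raise ConfigError("need 0 < n_cases < n_total for a binary trait")


# canonical fields that a ColumnMap must cover; eaf and n may be absent
_REQUIRED_MAPPED = ("variant_id", "effect_allele", "other_allele", "beta", "se")


@dataclass
class ColumnMap:
    """Mapping from canonical field names to source-file column headers."""

    mapping: dict = field(default_factory=lambda: {c: c for c in CANONICAL_COLUMNS})
    na_sentinel: str = "NA"

    def __post_init__(self) -> None:
        missing = [f for f in _REQUIRED_MAPPED if f not in self.mapping]
        if missing:
            raise ConfigError(f"column map missing canonical fields: {missing}")

    @classmethod
    def identity(cls) -> "ColumnMap":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(mapping=doc.get("mapping", doc), na_sentinel=doc.get("na_sentinel", "NA"))


class ReadResult(NamedTuple):
    records: list
    report: dict


def _parse_float(value, na: str) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, str):
        if value.strip() in ("", na):
            return None
        value = float(value)
    value = float(value)
    return None if math.isnan(value) else value


def read_summary_stats(
    path: str | Path,
    colmap: Optional[ColumnMap] = None,
    meta: Optional[StudyMeta] = None,
) -> ReadResult:
    """Read and validate one trait's summary-statistics table.

    Invalid rows are dropped and tallied by reason in the rejection report.
    Missing p-values are recomputed from beta/se (two-sided normal); a
    missing per-row n falls back to ``meta.n_total``.  A duplicate
    ``variant_id`` is a fatal data error.
    """
    colmap = colmap or ColumnMap.identity()
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for canonical, source in colmap.mapping.items():
        if source not in frame.columns and canonical in _REQUIRED_MAPPED:
            raise ConfigError(f"mapped column {source!r} (for {canonical!r}) absent from {path}")
    trait_id = meta.trait_id if meta is not None else Path(path).stem
    return ReadResult(*frame_to_records(frame, trait_id, colmap=colmap, meta=meta))


def frame_to_records(
    frame: pd.DataFrame,
    trait_id: str,
    colmap: Optional[ColumnMap] = None,
    meta: Optional[StudyMeta] = None,
) -> tuple[list, dict]:
    """Validate a raw table into :class:`SummaryAssociation` records.

    Returns ``(records, rejection_report)``; the report satisfies
    ``rows_in == rows_out + sum(rejections)``.
    """
    colmap = colmap or ColumnMap.identity()
    na = colmap.na_sentinel
    get = colmap.mapping.get
    records: list[SummaryAssociation] = []
    rejections: dict[str, int] = {}
    seen: set[str] = set()
    fallback_n = meta.n_total if meta is not None else None

    for row in frame.itertuples(index=False):
        row = row._asdict()

        def col(canonical, default=None):
            source = get(canonical)
            return row.get(source, default) if source is not None else default

        try:
            beta = _parse_float(col("beta"), na)
            se = _parse_float(col("se"), na)
            eaf = _parse_float(col("eaf"), na)
            pval = _parse_float(col("pval"), na)
            n_raw = _parse_float(col("n"), na)
        except ValueError:
            rejections["unparseable_numeric"] = rejections.get("unparseable_numeric", 0) + 1
            continue
        if beta is None or se is None:
            rejections["missing_beta_or_se"] = rejections.get("missing_beta_or_se", 0) + 1
            continue
        if pval is None and se > 0:
            pval = float(2.0 * stats.norm.sf(abs(beta) / se))
            pval = max(pval, np.finfo(float).tiny)  # keep within (0, 1]
        n = int(n_raw) if n_raw is not None else fallback_n
        rec = SummaryAssociation(
            variant_id=str(col("variant_id", "")).strip(),
            effect_allele=str(col("effect_allele", "")).strip().upper(),
            other_allele=str(col("other_allele", "")).strip().upper(),
            beta=beta,
            se=se,
            pval=pval if pval is not None else 1.0,
            n=n if n is not None else 0,
            trait_id=trait_id,
            eaf=eaf,
        )
        reason = rec.invariant_violation()
        if reason is not None:
            rejections[reason] = rejections.get(reason, 0) + 1
            continue
        if rec.variant_id in seen:
            raise DataError(f"duplicate variant_id {rec.variant_id!r} for trait {trait_id!r}")
        seen.add(rec.variant_id)
        records.append(rec)

    report = {
        "trait_id": trait_id,
        "rows_in": int(len(frame)),
        "rows_out": len(records),
        "rows_rejected": int(sum(rejections.values())),
        "rejections": rejections,
    }
    return records, report


def records_to_frame(records: Sequence[SummaryAssociation]) -> pd.DataFrame:
    """Canonical-column DataFrame view of a record list."""
    return pd.DataFrame(
        [
            {c: getattr(r, c) for c in CANONICAL_COLUMNS}
            for r in records
        ],
        columns=list(CANONICAL_COLUMNS),
    )


def write_summary_stats(records: Sequence[SummaryAssociation], path: str | Path) -> None:
    """Write records in the canonical tab-delimited dialect."""
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


RESULTS_COLUMNS = (
    "exposure",
    "outcome",
    "method",
    "nsnp",
    "b",
    "se",
    "ci_lower",
    "ci_upper",
    "pval",
    "or",
)


def write_results_table(estimates: Sequence, path: str | Path) -> None:
    """Write MR estimates as a tab-delimited results table.

    The ``or`` column carries ``exp(b)`` for estimates on a binary outcome
    (log-odds scale) and is blank otherwise.  Floats are printed with 17
    significant digits so a read-back reproduces them bitwise.
    """
    if not estimates:
        raise DataError("cannot write an empty results table")
    rows = []
    for est in estimates:
        rows.append(
            {
                "exposure": est.exposure,
                "outcome": est.outcome,
                "method": est.method,
                "nsnp": est.nsnp,
                "b": est.beta,
                "se": est.se,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
                "pval": est.pval,
                "or": math.exp(est.beta) if est.outcome_binary else None,
            }
        )
    frame = pd.DataFrame(rows, columns=list(RESULTS_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", keep_default_na=True, float_precision="round_trip")


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def asdict(obj) -> dict:
    return dataclasses.asdict(obj)
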