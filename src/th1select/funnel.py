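"""Candidate vaccine-antigen selection from differential-expression summaries.

The funnel starts from per-gene summary statistics (log2 fold change and FDR
versus normal tissue, reported separately for a low-grade stratum, Gleason
score <= 6, and a high-grade stratum, Gleason score >= 8) and retains genes
that are upregulated in malignancy regardless of grade, then applies curated
annotation filters: literature evidence of expression in prostatic
intraepithelial neoplasia (PIN, marking "early" antigens) and detection of
the protein in the target tumor line.  A small include-list allows antigens
chosen on external grounds (e.g. an established vaccine target, or a gene the
tumor line is known to express) to bypass the expression filters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "FunnelConfig",
    "FunnelReport",
    "select_upregulated",
    "apply_annotation_filters",
    "run_funnel",
    "read_gene_table",
    "write_gene_table",
]

# ordered stage labels used in FunnelReport
STAGE_INPUT = "input"
STAGE_DE = "upregulated"
STAGE_INCLUDE = "with_include_list"
STAGE_PIN = "pin_evidence"
STAGE_TUMOR = "tumor_line_expressed"
STAGE_RETAINED = "retained"


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene differential-expression summary for both Gleason strata.

    ``pin_evidence`` and ``tumor_line_expressed`` are curated annotations
    supplied with the table (literature review and Western blot), not
    quantities this package computes.  ``tumor_line_expressed`` may be
    ``None`` when the protein was not assayed.
    """

    gene_symbol: str
    log2fc_low: float
    fdr_low: float
    log2fc_high: float
    fdr_high: float
    pin_evidence: bool = False
    tumor_line_expressed: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        for name in ("fdr_low", "fdr_high"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"gene {self.gene_symbol}: {name}={v!r} outside [0, 1]"
                )


@dataclass(frozen=True)
class FunnelConfig:
    """Thresholds and filter switches for the antigen funnel.

    Upregulation means log2 fold change strictly greater than
    ``lfc_threshold`` and FDR strictly below ``fdr_threshold``; with
    ``require_both_strata`` the rule must hold in both the low- and
    high-grade stratum.  Genes in ``include_list`` bypass the expression and
    PIN filters but not the tumor-line-expression filter.
    """

    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    require_both_strata: bool = True
    include_list: tuple[str, ...] = ()
    require_pin: bool = False
    require_tumor_expression: bool = False

    def __post_init__(self) -> None:
        if not self.lfc_threshold > 0:
            raise ValueError("lfc_threshold must be > 0")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must be in (0, 1)")
        object.__setattr__(self, "include_list", tuple(self.include_list))


@dataclass
class FunnelReport:
    """Stage-by-stage account of one funnel run."""

    stage_names: list[str]
    stage_counts: list[int]
    retained: list[str]
    excluded: dict[str, str]  # gene -> first failing stage
    force_included: list[str] = field(default_factory=list)
    flagged_unannotated: list[str] = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)

    def stage_table(self) -> str:
        width = max(len(s) for s in self.stage_names)
        lines = [f"{name.ljust(width)}  {count:>6d}"
                 for name, count in zip(self.stage_names, self.stage_counts)]
        return "\n".join(lines)


def _validate_records(records: Sequence[GeneRecord]) -> None:
    if not records:
        raise ValueError("empty input: no gene records supplied")
    seen: set[str] = set()
    for rec in records:
        if rec.gene_symbol in seen:
            raise ValueError(f"duplicate gene symbol: {rec.gene_symbol}")
        seen.add(rec.gene_symbol)
        for name in ("log2fc_low", "fdr_low", "log2fc_high", "fdr_high"):
            if not math.isfinite(getattr(rec, name)):
                raise ValueError(
                    f"gene {rec.gene_symbol}: non-finite {name}"
                )


def _is_upregulated(rec: GeneRecord, cfg: FunnelConfig) -> bool:
    low = rec.log2fc_low > cfg.lfc_threshold and rec.fdr_low < cfg.fdr_threshold
    if not cfg.require_both_strata:
        return low
    high = rec.log2fc_high > cfg.lfc_threshold and rec.fdr_high < cfg.fdr_threshold
    return low and high


def select_upregulated(
    records: Sequence[GeneRecord], config: FunnelConfig
) -> list[GeneRecord]:
    """Return records upregulated per the strict log2FC/FDR rule, order kept.

    A gene passes when log2FC > threshold and FDR < threshold in the
    low-grade stratum and, when ``require_both_strata``, also in the
    high-grade stratum.  Both inequalities are strict: log2FC exactly at the
    threshold fails.
    """
    _validate_records(records)
    return [rec for rec in records if _is_upregulated(rec, config)]


def apply_annotation_filters(
    records: Sequence[GeneRecord], config: FunnelConfig
) -> list[GeneRecord]:
    """Apply the PIN-evidence and tumor-line-expression filters.

    Records with ``tumor_line_expressed`` unset survive the tumor filter
    (the protein was never assayed); :func:`run_funnel` flags them in its
    report.
    """
    out = []
    for rec in records:
        if config.require_pin and not rec.pin_evidence:
            continue
        if config.require_tumor_expression and rec.tumor_line_expressed is False:
            continue
        out.append(rec)
    return out


def run_funnel(
    records: Sequence[GeneRecord], config: FunnelConfig
) -> FunnelReport:
    """Run the full antigen-selection funnel and report per-stage counts.

    Stages: differential-expression filter, include-list union (force-included
    genes bypass DE and PIN but not the tumor-expression filter), PIN filter,
    tumor-line-expression filter.  ``excluded`` maps every dropped gene to the
    first stage it failed; deterministic for a given input order.
    """
    _validate_records(records)
    by_symbol = {rec.gene_symbol: rec for rec in records}
    include = [g for g in config.include_list if g in by_symbol]

    upregulated = select_upregulated(records, config)
    up_symbols = {r.gene_symbol for r in upregulated}

    force_included = [g for g in include if g not in up_symbols]
    pool = upregulated + [by_symbol[g] for g in force_included]
    pool_symbols = up_symbols | set(force_included)

    excluded: dict[str, str] = {}
    for rec in records:
        if rec.gene_symbol not in pool_symbols:
            excluded[rec.gene_symbol] = STAGE_DE

    # PIN filter: bypassed by force-included genes
    after_pin = []
    for rec in pool:
        if (
            config.require_pin
            and not rec.pin_evidence
            and rec.gene_symbol not in force_included
        ):
            excluded[rec.gene_symbol] = STAGE_PIN
        else:
            after_pin.append(rec)

    # tumor-expression filter applies to every gene, include-list or not
    retained_records = []
    flagged = []
    for rec in after_pin:
        if config.require_tumor_expression and rec.tumor_line_expressed is False:
            excluded[rec.gene_symbol] = STAGE_TUMOR
        else:
            if config.require_tumor_expression and rec.tumor_line_expressed is None:
                flagged.append(rec.gene_symbol)
            retained_records.append(rec)

    counts = [
        len(records),
        len(upregulated),
        len(pool),
        len(after_pin),
        len(retained_records),
        len(retained_records),
    ]
    return FunnelReport(
        stage_names=[STAGE_INPUT, STAGE_DE, STAGE_INCLUDE, STAGE_PIN,
                     STAGE_TUMOR, STAGE_RETAINED],
        stage_counts=counts,
        retained=[r.gene_symbol for r in retained_records],
        excluded=excluded,
        force_included=force_included,
        flagged_unannotated=flagged,
    )


_COLUMNS = ["gene", "log2fc_low", "fdr_low", "log2fc_high", "fdr_high",
            "pin_evidence", "tumor_line_expressed"]


def _parse_bool(value) -> Optional[bool]:
    if value is None or (not isinstance(value, str) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"cannot parse boolean field: {value!r}")


def read_gene_table(path) -> list[GeneRecord]:
    """Read a TSV gene summary table (booleans as true/false, missing empty)."""
    df = pd.read_csv(path, sep="\t", dtype={"pin_evidence": "string",
                                            "tumor_line_expressed": "string"})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(GeneRecord(
            gene_symbol=str(row.gene),
            log2fc_low=float(row.log2fc_low),
            fdr_low=float(row.fdr_low),
            log2fc_high=float(row.log2fc_high),
            fdr_high=float(row.fdr_high),
            pin_evidence=bool(_parse_bool(row.pin_evidence)),
            tumor_line_expressed=_parse_bool(row.tumor_line_expressed),
        ))
    _validate_records(records)
    return records


def write_gene_table(records: Sequence[GeneRecord], path) -> None:
    def fmt_bool(v: Optional[bool]) -> str:
        return "" if v is None else ("true" if v else "false")

    df = pd.DataFrame({
        "gene": [r.gene_symbol for r in records],
        "log2fc_low": [r.log2fc_low for r in records],
        "fdr_low": [r.fdr_low for r in records],
        "log2fc_high": [r.log2fc_high for r in records],
        "fdr_high": [r.fdr_high for r in records],
        "pin_evidence": [fmt_bool(r.pin_evidence) for r in records],
        "tumor_line_expressed": [fmt_bool(r.tumor_line_expressed) for r in records],
    })
    df.to_csv(path, sep="\t", index=False)
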