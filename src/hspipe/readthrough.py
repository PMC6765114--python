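"""Three-rule false-positive filter for heat-shock-upregulated coding genes.

Rules (applied to the upregulated list only; reasons accumulate):
  A. DOG_READTHROUGH — intron/exon score > 0.4 AND intergenic-junction
     HS/CTRL ratio > 2 (readthrough from an upstream induced gene).
  B. INTRONIC_NCRNA  — intron/exon score > 1 (independently transcribed
     ncRNA resident in an intron).
  C. REPEAT_OVERLAP  — gene span covered > 50% by repetitive elements.

All inequalities are strict.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotation import GeneModel, GenomicInterval, interval_union_length
from .counts import CountTable

REASON_DOG = "DOG_READTHROUGH"
REASON_INTRONIC = "INTRONIC_NCRNA"
REASON_REPEAT = "REPEAT_OVERLAP"


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class FilterThresholds:
    ir_dog: float = 0.4
    ij_min: float = 2.0
    ir_ncrna: float = 1.0
    repeat_frac: float = 0.5

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise FilterError(f"threshold {name} must be > 0, got {v}")


@dataclass
class FilterReport:
    gene_id: str
    ir_score: float
    ij_ratio: float
    repeat_overlap_fraction: float
    removed: bool
    reasons: frozenset[str]
    edge_flags: frozenset[str] = frozenset()


def ir_score(intron_norm_total: float, exon_norm_total: float) -> float:
    """Intron-retention score: total normalized intron reads / exon reads.

    0/0 -> 0; positive/0 -> +inf (such genes fall to the intronic-ncRNA rule).
    """
    if intron_norm_total < 0 or exon_norm_total < 0:
        raise FilterError("counts must be non-negative")
    if exon_norm_total == 0:
        return 0.0 if intron_norm_total == 0 else math.inf
    return intron_norm_total / exon_norm_total


def ij_ratio(hs_ij_norm: float, ctrl_ij_norm: float, pseudocount: float = 1.0) -> float:
    """HS/CTRL ratio of normalized intergenic-junction window counts."""
    if hs_ij_norm < 0 or ctrl_ij_norm < 0:
        raise FilterError("counts must be non-negative")
    return (hs_ij_norm + pseudocount) / (ctrl_ij_norm + pseudocount)


def repeat_overlap_fraction(
    gene_span: GenomicInterval, repeats: Sequence[GenomicInterval]
) -> float:
    """Fraction of the gene span covered by the union of repeat intervals."""
    if gene_span.length <= 0:
        raise FilterError("zero-length gene span")
    covered = interval_union_length(repeats, within=gene_span)
    return covered / gene_span.length


def evaluate(
    *,
    gene_id: str = "",
    ir: float = 0.0,
    ij: float = 1.0,
    repeat_frac: float = 0.0,
    thresholds: FilterThresholds = FilterThresholds(),
    edge_flags: frozenset[str] = frozenset(),
) -> FilterReport:
    """Build a FilterReport from the three scores, applying strict thresholds."""
    reasons = set()
    if ir > thresholds.ir_dog and ij > thresholds.ij_min:
        reasons.add(REASON_DOG)
    if ir > thresholds.ir_ncrna:
        reasons.add(REASON_INTRONIC)
    if repeat_frac > thresholds.repeat_frac:
        reasons.add(REASON_REPEAT)
    return FilterReport(
        gene_id=gene_id,
        ir_score=ir,
        ij_ratio=ij,
        repeat_overlap_fraction=repeat_frac,
        removed=bool(reasons),
        reasons=frozenset(reasons),
        edge_flags=edge_flags,
    )


def reports_from_counts(
    table: CountTable,
    genes: Sequence[GeneModel],
    repeats: Sequence[GenomicInterval] = (),
    thresholds: FilterThresholds = FilterThresholds(),
    pseudocount: float = 1.0,
    edge_clipped: Mapping[str, bool] | None = None,
) -> dict[str, FilterReport]:
    """Score every gene in the table.

    IR totals sum normalized counts over ALL samples (both conditions);
    the IJ ratio compares per-condition means of normalized window counts.
    """
    norm = table.normalized
    ctrl = table.samples_of("CTRL")
    hs = table.samples_of("HS")
    exon = table.of_kind("exon")
    reports: dict[str, FilterReport] = {}
    for gene in genes:
        gid = gene.gene_id
        if gid not in exon.index:
            continue
        exon_total = float(norm.loc[("exon", gid)].sum())
        intron_total = float(norm.loc[("intron", gid)].sum())
        ir = ir_score(intron_total, exon_total)
        if ("ij", gid) in norm.index:
            hs_mean = float(norm.loc[("ij", gid), hs].mean()) if hs else 0.0
            ctrl_mean = float(norm.loc[("ij", gid), ctrl].mean()) if ctrl else 0.0
            ij = ij_ratio(hs_mean, ctrl_mean, pseudocount)
        else:
            ij = 1.0
        frac = repeat_overlap_fraction(gene.span, list(repeats)) if repeats else 0.0
        flags = set()
        if edge_clipped and edge_clipped.get(gid):
            flags.add("edge_clipped")
        reports[gid] = evaluate(
            gene_id=gid, ir=ir, ij=ij, repeat_frac=frac,
            thresholds=thresholds, edge_flags=frozenset(flags),
        )
    return reports


def apply_filters(
    upregulated_genes: Sequence[str], reports: Mapping[str, FilterReport]
) -> tuple[list[str], list[FilterReport]]:
    """Split an upregulated gene list into kept ids and removed reports.

    Only the upregulated list is filtered; input order is preserved in the
    outputs but does not affect any verdict.
    """
    missing = [g for g in upregulated_genes if g not in reports]
    if missing:
        raise FilterError(f"missing filter reports for genes: {', '.join(sorted(missing))}")
    kept, removed = [], []
    for gid in upregulated_genes:
        rep = reports[gid]
        (removed if rep.removed else kept).append(rep if rep.removed else gid)
    return kept, removed


def reports_to_frame(reports: Mapping[str, FilterReport]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "ir_score": r.ir_score,
            "ij_ratio": r.ij_ratio,
            "repeat_overlap_fraction": r.repeat_overlap_fraction,
            "removed": r.removed,
            "reasons": ",".join(sorted(r.reasons)),
            "edge_flags": ",".join(sorted(r.edge_flags)),
        }
        for r in reports.values()
    ]
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
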