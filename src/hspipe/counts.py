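"""Read-to-feature counting, median-of-ratios depth normalization, and
fold-change classification.

Feature kinds:
  ``exon``   — reads overlapping >=1 bp of any exon of a gene
  ``intron`` — reads overlapping a gene's introns but none of its exons
  ``ij``     — reads overlapping an intergenic-junction window by >=1 bp,
               counted independently of gene assignment
  ``repeat`` — one count per read per repeat family (primary assignment:
               largest overlap wins, ties broken lexicographically)

Counting is strand-aware by default (read strand must match the feature
strand); features with strand '.' match reads on either strand.
"""
from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, IJWindow, intervals_from_bed

KINDS = ("exon", "intron", "ij", "repeat")


class CountError(ValueError):
    pass


class _IntervalIndex:
    """Per-chromosome sorted-start index with max-length lookback."""

    def __init__(self) -> None:
        self._items: dict[str, list[tuple[int, int, str, object]]] = {}
        self._starts: dict[str, list[int]] = {}
        self._maxlen: dict[str, int] = {}

    def add(self, iv: GenomicInterval, payload: object) -> None:
        self._items.setdefault(iv.chrom, []).append((iv.start, iv.end, iv.strand, payload))

    def build(self) -> None:
        for chrom, items in self._items.items():
            items.sort(key=lambda t: (t[0], t[1]))
            self._starts[chrom] = [t[0] for t in items]
            self._maxlen[chrom] = max((t[1] - t[0] for t in items), default=0)

    def query(self, chrom: str, start: int, end: int):
        """Yield (start, end, strand, payload) for intervals overlapping [start, end)."""
        items = self._items.get(chrom)
        if not items:
            return
        starts = self._starts[chrom]
        lookback = self._maxlen[chrom]
        hi = bisect_right(starts, end - 1)
        i = hi - 1
        while i >= 0 and items[i][0] > start - lookback:
            s, e, st, payload = items[i]
            if e > start:
                yield s, e, st, payload
            i -= 1


@dataclass
class CountTable:
    """Raw counts per (kind, feature) x sample, with optional size factors."""

    raw: pd.DataFrame  # MultiIndex (kind, feature) rows, sample columns
    conditions: dict[str, str]  # sample -> 'CTRL' | 'HS'
    size_factors: pd.Series | None = None
    skipped_reads: dict[str, int] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise CountError("size factors not computed; call compute_size_factors")
        return self.raw.div(self.size_factors, axis=1)

    def of_kind(self, kind: str) -> pd.DataFrame:
        if kind not in self.raw.index.get_level_values("kind"):
            return self.raw.iloc[0:0].droplevel("kind")
        return self.raw.xs(kind, level="kind")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]

    # -- long-format TSV round trip -------------------------------------
    def to_tsv(self, path: str | Path | IO[str]) -> None:
        norm = self.normalized if self.size_factors is not None else None
        raw = self.raw.copy()
        raw.columns.name = "sample"
        long = raw.stack().rename("raw").reset_index()
        long["condition"] = long["sample"].map(self.conditions)
        if norm is not None:
            norm = norm.copy()
            norm.columns.name = "sample"
            nlong = norm.stack().rename("normalized").reset_index()
            long = long.merge(nlong, on=["kind", "feature", "sample"])
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path | IO[str]) -> "CountTable":
        long = pd.read_csv(path, sep="\t")
        raw = long.pivot_table(
            index=["kind", "feature"], columns="sample", values="raw", aggfunc="first"
        ).astype(int)
        raw.columns.name = None
        conditions = dict(zip(long["sample"], long["condition"]))
        table = cls(raw=raw, conditions=conditions)
        if "normalized" in long.columns:
            # recover size factors from any feature with nonzero raw count
            nz = long[(long["raw"] > 0) & (long["normalized"] > 0)]
            if not nz.empty:
                sf = (nz["raw"] / nz["normalized"]).groupby(nz["sample"]).median()
                table.size_factors = sf.reindex(raw.columns)
        return table


def _strand_ok(read_strand: str, feat_strand: str, stranded: bool) -> bool:
    if not stranded or feat_strand == "." or read_strand == ".":
        return True
    return read_strand == feat_strand


def infer_conditions(samples: Sequence[str]) -> dict[str, str]:
    out = {}
    for s in samples:
        u = s.upper()
        if u.startswith("HS"):
            out[s] = "HS"
        elif u.startswith("CTRL") or u.startswith("CONTROL"):
            out[s] = "CTRL"
        else:
            raise CountError(f"cannot infer condition from sample name {s!r}")
    return out


def count_features(
    reads: Mapping[str, pd.DataFrame],
    genes: Sequence[GeneModel],
    windows: Sequence[IJWindow] = (),
    repeats: pd.DataFrame | None = None,
    stranded: bool = True,
    conditions: Mapping[str, str] | None = None,
) -> CountTable:
    """Count BED reads per sample into exon/intron/ij/repeat features.

    ``reads`` maps sample name to a BED6-like DataFrame. Reads on
    chromosomes absent from every feature set are skipped with a counted
    warning.
    """
    exon_idx, intron_idx, window_idx, repeat_idx = (
        _IntervalIndex(),
        _IntervalIndex(),
        _IntervalIndex(),
        _IntervalIndex(),
    )
    known_chroms: set[str] = set()
    for gene in genes:
        known_chroms.add(gene.chrom)
        for iv in gene.exons:
            exon_idx.add(iv, gene.gene_id)
        for iv in gene.introns:
            intron_idx.add(iv, gene.gene_id)
    for w in windows:
        known_chroms.add(w.interval.chrom)
        window_idx.add(w.interval, w.gene_id)
    families: list[str] = []
    if repeats is not None and len(repeats):
        for r in repeats.itertuples():
            iv = GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand))
            known_chroms.add(iv.chrom)
            repeat_idx.add(iv, str(r.name))
        families = sorted(set(repeats["name"].astype(str)))
    for idx in (exon_idx, intron_idx, window_idx, repeat_idx):
        idx.build()

    samples = list(reads)
    if conditions is None:
        conditions = infer_conditions(samples)

    rows: list[tuple[str, str]] = []
    for gene in genes:
        rows.append(("exon", gene.gene_id))
        rows.append(("intron", gene.gene_id))
    rows.extend(("ij", w.gene_id) for w in windows)
    rows.extend(("repeat", fam) for fam in families)
    index = pd.MultiIndex.from_tuples(rows, names=["kind", "feature"])
    raw = pd.DataFrame(0, index=index, columns=samples, dtype=int)
    pos = {key: i for i, key in enumerate(index)}
    mat = raw.to_numpy()

    skipped: dict[str, int] = {}
    for col, sample in enumerate(samples):
        df = reads[sample]
        n_skip = 0
        for r in df.itertuples():
            chrom, start, end, strand = str(r.chrom), int(r.start), int(r.end), str(r.strand)
            if chrom not in known_chroms:
                n_skip += 1
                continue
            exon_hits = {
                p
                for s, e, st, p in exon_idx.query(chrom, start, end)
                if _strand_ok(strand, st, stranded)
            }
            for gid in exon_hits:
                mat[pos[("exon", gid)], col] += 1
            for s, e, st, gid in intron_idx.query(chrom, start, end):
                if gid in exon_hits or not _strand_ok(strand, st, stranded):
                    continue
                mat[pos[("intron", gid)], col] += 1
                exon_hits.add(gid)  # guard against multi-intron double count
            seen_windows = set()
            for s, e, st, gid in window_idx.query(chrom, start, end):
                if gid in seen_windows or not _strand_ok(strand, st, stranded):
                    continue
                seen_windows.add(gid)
                mat[pos[("ij", gid)], col] += 1
            best_fam, best_ov = None, 0
            fam_ov: dict[str, int] = {}
            for s, e, st, fam in repeat_idx.query(chrom, start, end):
                if not _strand_ok(strand, st, stranded):
                    continue
                fam_ov[fam] = fam_ov.get(fam, 0) + (min(e, end) - max(s, start))
            for fam in sorted(fam_ov):
                if fam_ov[fam] > best_ov:
                    best_fam, best_ov = fam, fam_ov[fam]
            if best_fam is not None:
                mat[pos[("repeat", best_fam)], col] += 1
        if n_skip:
            warnings.warn(f"sample {sample}: skipped {n_skip} reads on unknown chromosomes")
            skipped[sample] = n_skip

    raw.iloc[:, :] = mat
    return CountTable(raw=raw, conditions=dict(conditions), skipped_reads=skipped)


# ---------------------------------------------------------------------------
# Normalization and fold changes
# ---------------------------------------------------------------------------


def size_factors(exonic: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from a genes x samples count matrix.

    factor_j = median_i( K_ij / geomean_j'(K_ij') ) over genes with nonzero
    counts in every sample.
    """
    counts = exonic.astype(float)
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise CountError(
            "no gene has nonzero counts in every sample; "
            "add a pseudocount or supply more data"
        )
    logs = np.log(positive)
    log_geomean = logs.mean(axis=1)
    sf = np.exp(logs.sub(log_geomean, axis=0).median(axis=0))
    sf.name = "size_factor"
    return sf


def compute_size_factors(table: CountTable) -> pd.Series:
    """Compute and attach exonic-gene size factors to the table."""
    table.size_factors = size_factors(table.of_kind("exon"))
    return table.size_factors


def fold_changes(
    table: CountTable,
    ctrl_samples: Sequence[str] | None = None,
    hs_samples: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    kinds: Sequence[str] = ("exon",),
) -> pd.DataFrame:
    """Per-feature baseMean and log2 fold change from normalized counts.

    baseMean is the mean of normalized counts over all samples; log2fc is
    log2((mean_HS + pc) / (mean_CTRL + pc)).
    """
    if ctrl_samples is None:
        ctrl_samples = table.samples_of("CTRL")
    if hs_samples is None:
        hs_samples = table.samples_of("HS")
    if not ctrl_samples or not hs_samples:
        raise CountError("need at least one sample per condition")
    norm = table.normalized
    norm = norm[norm.index.get_level_values("kind").isin(kinds)]
    base_mean = norm[list(ctrl_samples) + list(hs_samples)].mean(axis=1)
    mean_ctrl = norm[list(ctrl_samples)].mean(axis=1)
    mean_hs = norm[list(hs_samples)].mean(axis=1)
    log2fc = np.log2((mean_hs + pseudocount) / (mean_ctrl + pseudocount))
    out = pd.DataFrame(
        {
            "kind": norm.index.get_level_values("kind"),
            "feature": norm.index.get_level_values("feature"),
            "baseMean": base_mean.to_numpy(),
            "log2fc": log2fc.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def classify_de(
    records: pd.DataFrame,
    fc_threshold: float = 2.0,
    basemean_min: float = 50.0,
    direction: str = "up",
) -> set[str]:
    """Feature ids passing |fold change| >= fc_threshold with baseMean >= basemean_min."""
    if fc_threshold <= 0 or basemean_min < 0:
        raise CountError("thresholds must be positive")
    cut = np.log2(fc_threshold)
    ok_base = records["baseMean"] >= basemean_min
    if direction == "up":
        mask = (records["log2fc"] >= cut) & ok_base
    elif direction == "down":
        mask = (records["log2fc"] <= -cut) & ok_base
    else:
        raise CountError(f"direction must be 'up' or 'down', got {direction!r}")
    return set(records.loc[mask, "feature"])
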