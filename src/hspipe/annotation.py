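"""Genome data model and standard-format I/O.

All internal coordinates are 0-based half-open; GTF I/O converts from/to
the 1-based inclusive convention. Strand-aware constructions (intergenic
junction windows, promoters) live here so every downstream module shares
one geometry.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence, Union

import pandas as pd
from gffutils.feature import feature_from_line

IJ_INTO_GENE = 11  # bases of gene body covered, including the 5' base
IJ_UPSTREAM = 10  # bases upstream of the 5' base
PROMOTER_BP = 1000

_STRANDS = ("+", "-", ".")

Source = Union[str, Path, IO[str], Iterable[str]]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise AnnotationError(
                f"end must exceed start in {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise AnnotationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 (with a warning) across chromosomes."""
    if a.chrom != b.chrom:
        warnings.warn(
            f"overlap_length on different chromosomes ({a.chrom} vs {b.chrom})",
            stacklevel=2,
        )
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def interval_union_length(
    intervals: Sequence[GenomicInterval], within: GenomicInterval | None = None
) -> int:
    """Total bp covered by the union of intervals, optionally clipped to ``within``."""
    spans = []
    for iv in intervals:
        s, e = iv.start, iv.end
        if within is not None:
            if iv.chrom != within.chrom:
                continue
            s, e = max(s, within.start), min(e, within.end)
        if e > s:
            spans.append((s, e))
    spans.sort()
    total = 0
    cur_s = cur_e = None
    for s, e in spans:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomicInterval]
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"{a.start}-{a.end} vs {b.start}-{b.end}"
                )

    @property
    def introns(self) -> list[GenomicInterval]:
        return derive_introns(self.exons)

    @property
    def utr3_length(self) -> int:
        return sum(iv.length for iv in self.utr3)


def derive_introns(exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Gaps between consecutive sorted exons; [] for single-exon transcripts."""
    if not exons:
        raise AnnotationError("cannot derive introns without exons")
    ordered = sorted(exons, key=lambda iv: iv.start)
    introns = []
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise AnnotationError("overlapping exons")
        if b.start > a.end:
            introns.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
    return introns


BIOTYPES = {
    "protein_coding",
    "miRNA",
    "piRNA",
    "lincRNA",
    "ncRNA",
    "pseudogene",
    "repeat",
}


@dataclass
class GeneModel:
    """One gene with its transcripts; exons define the span and annotated 5' start."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -")
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")
        for tx in self.transcripts:
            for ex in tx.exons:
                if ex.chrom != self.chrom or ex.strand != self.strand:
                    raise AnnotationError(
                        f"gene {self.gene_id}: exon on {ex.chrom}{ex.strand} "
                        f"does not match gene {self.chrom}{self.strand}"
                    )

    @property
    def span(self) -> GenomicInterval:
        start = min(ex.start for tx in self.transcripts for ex in tx.exons)
        end = max(ex.end for tx in self.transcripts for ex in tx.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def tss0(self) -> int:
        """0-based position of the annotated 5'-most base of the gene span."""
        sp = self.span
        return sp.start if self.strand == "+" else sp.end - 1

    @property
    def exons(self) -> list[GenomicInterval]:
        return [ex for tx in self.transcripts for ex in tx.exons]

    @property
    def introns(self) -> list[GenomicInterval]:
        return [iv for tx in self.transcripts for iv in tx.introns]


@dataclass(frozen=True)
class IJWindow:
    """21-bp window spanning a gene's annotated 5' start (11 in, 10 upstream)."""

    gene_id: str
    interval: GenomicInterval
    edge_clipped: bool = False


def ij_window(gene: GeneModel, chrom_length: int | None = None) -> IJWindow:
    """Strand-aware intergenic-junction window around the annotated 5' start.

    Covers IJ_INTO_GENE bases of gene body (including the 5' base) and
    IJ_UPSTREAM upstream bases; in genomic coordinates this is
    [tss0 - 10, tss0 + 11) on either strand. Windows running past
    chromosome bounds are clipped and flagged.
    """
    t0 = gene.tss0
    start, end = t0 - IJ_UPSTREAM, t0 + IJ_INTO_GENE
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return IJWindow(gene.gene_id, GenomicInterval(gene.chrom, start, end, gene.strand), clipped)


def promoter_interval(
    gene: GeneModel, promoter_bp: int = PROMOTER_BP, chrom_length: int | None = None
) -> GenomicInterval | None:
    """Strand-aware promoter window: ``promoter_bp`` bases strictly upstream
    of the annotated 5' base (the 5' base itself excluded). None if it falls
    entirely off-chromosome."""
    t0 = gene.tss0
    if gene.strand == "+":
        start, end = t0 - promoter_bp, t0
    else:
        start, end = t0 + 1, t0 + 1 + promoter_bp
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if end <= start:
        return None
    return GenomicInterval(gene.chrom, start, end, gene.strand)


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect: exon / three_prime_utr features)
# ---------------------------------------------------------------------------


def _iter_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def read_gene_models(source: Source) -> list[GeneModel]:
    """Parse a GTF stream into GeneModels (0-based half-open coordinates).

    Groups exon and three_prime_utr features by gene_id/transcript_id;
    gene_biotype defaults to protein_coding when absent.
    """
    exons: dict[str, dict[str, list[GenomicInterval]]] = {}
    utrs: dict[str, dict[str, list[GenomicInterval]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # gene -> (chrom, strand, biotype)
    order: list[str] = []

    for lineno, line in enumerate(_iter_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise AnnotationError(
                f"malformed GTF line {lineno}: expected 9 tab-separated fields"
            )
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises plain ValueError/AttributeError
            raise AnnotationError(f"malformed GTF line {lineno}: {exc}") from exc
        if feat.featuretype not in ("exon", "three_prime_utr"):
            continue
        if feat.end < feat.start:
            raise AnnotationError(f"GTF line {lineno}: end < start")
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(f"GTF line {lineno}: missing {exc} attribute") from exc
        biotype = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if gene_id not in meta:
            meta[gene_id] = (feat.seqid, feat.strand, biotype)
            order.append(gene_id)
        bucket = exons if feat.featuretype == "exon" else utrs
        bucket.setdefault(gene_id, {}).setdefault(tx_id, []).append(iv)

    genes = []
    for gid in order:
        chrom, strand, biotype = meta[gid]
        txs = []
        for tx_id in sorted(exons.get(gid, {})):
            txs.append(
                Transcript(tx_id, exons[gid][tx_id], utrs.get(gid, {}).get(tx_id, []))
            )
        if not txs:
            continue  # UTR-only entries without exons are dropped
        genes.append(GeneModel(gid, chrom, strand, txs, biotype))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path | IO[str]) -> None:
    """Write GeneModels as Ensembl-dialect GTF (1-based inclusive)."""

    def emit(fh: IO[str]) -> None:
        for gene in genes:
            for tx in gene.transcripts:
                for kind, ivs in (("exon", tx.exons), ("three_prime_utr", tx.utr3)):
                    for iv in ivs:
                        attrs = (
                            f'gene_id "{gene.gene_id}"; '
                            f'transcript_id "{tx.transcript_id}"; '
                            f'gene_biotype "{gene.biotype}";'
                        )
                        fh.write(
                            f"{gene.chrom}\thspipe\t{kind}\t{iv.start + 1}\t{iv.end}"
                            f"\t.\t{gene.strand}\t.\t{attrs}\n"
                        )

    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            emit(fh)
    else:
        emit(path)


# ---------------------------------------------------------------------------
# BED6 and chrom-sizes I/O
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path | IO[str]) -> pd.DataFrame:
    """Read BED6 (or fewer columns, padded) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] > 6:
        df = df.iloc[:, :6]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    if (df["end"] < df["start"]).any():
        raise AnnotationError("BED record with end < start")
    return df[BED_COLUMNS]


def write_bed(df: pd.DataFrame, path: str | Path | IO[str]) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def intervals_from_bed(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    ]


def windows_to_bed(windows: Sequence[IJWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.interval.chrom for w in windows],
            "start": [w.interval.start for w in windows],
            "end": [w.interval.end for w in windows],
            "name": [w.gene_id for w in windows],
            "score": [int(w.edge_clipped) for w in windows],
            "strand": [w.interval.strand for w in windows],
        }
    )


def read_chrom_sizes(path: str | Path | IO[str]) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path | IO[str]) -> None:
    pd.DataFrame(sorted(sizes.items())).to_csv(path, sep="\t", header=False, index=False)
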