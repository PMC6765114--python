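"""PWM motif scanning with exact null p-values, summit-region overlap
classification, and promoter reporting.

The scanner scores log-odds sums against a background model and converts
scores to p-values with an exact dynamic program over the discretized
per-position score distribution (granularity = 1/1000 of the total score
range by default). Hits on both strands with p < threshold are reported.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, overlap_length, promoter_interval
from .sequence import DNA_BASES, encode_dna, revcomp_dna

P_THRESHOLD = 1e-4
REGION_HALF = 100  # 201-bp summit regions
MIN_BOUND_OVERLAP = 14
DEFAULT_PSEUDOCOUNT = 1e-4
DEFAULT_GRANULARITY_BINS = 1000


class MotifError(ValueError):
    pass


@dataclass
class PWM:
    """Position probability matrix over ACGT with background and log-odds."""

    probs: np.ndarray  # (W, 4), rows sum to 1 after pseudocounting
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise MotifError("probability matrix must be (W, 4)")
        if (self.background <= 0).any():
            raise MotifError("background must be strictly positive")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise MotifError("each PWM position must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.probs / self.background)

    @property
    def consensus(self) -> str:
        return "".join(DNA_BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1], self.background[::-1], self.name + "_rc")

    @classmethod
    def from_counts_or_probs(
        cls,
        matrix: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        name: str = "motif",
    ) -> "PWM":
        m = np.asarray(matrix, dtype=float)
        m = m / m.sum(axis=1, keepdims=True)
        m = m + pseudocount
        m = m / m.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(m, bg, name)

    @classmethod
    def from_meme(
        cls,
        path: str | Path | IO[str],
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        index: int = 0,
    ) -> "PWM":
        """Read a MEME-minimal motif file (first motif by default).

        Parsed directly to preserve the full precision of the printed
        letter-probability matrix (Biopython's minimal parser rounds the
        matrix to integer counts).
        """
        if isinstance(path, (str, Path)):
            text = Path(path).read_text()
        else:
            text = path.read()
        lines = [ln.strip() for ln in text.splitlines()]
        bg = np.full(4, 0.25)
        motifs: list[tuple[str, np.ndarray]] = []
        i = 0
        while i < len(lines):
            line = lines[i]
            if line.startswith("Background letter frequencies"):
                tokens = lines[i + 1].split()
                freqs = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
                bg = np.array([freqs.get(b, 0.25) for b in DNA_BASES])
                i += 2
                continue
            if line.startswith("MOTIF"):
                name = line.split()[1] if len(line.split()) > 1 else "motif"
                while i < len(lines) and not lines[i].startswith(
                    "letter-probability matrix"
                ):
                    i += 1
                if i == len(lines):
                    raise MotifError(f"motif {name}: no letter-probability matrix")
                header = lines[i]
                width = None
                tokens = header.replace("=", " = ").split()
                if "w" in tokens:
                    width = int(tokens[tokens.index("w") + 2])
                i += 1
                rows = []
                while i < len(lines) and lines[i] and lines[i][0] in "0123456789.":
                    rows.append([float(v) for v in lines[i].split()])
                    i += 1
                if width is not None and len(rows) != width:
                    raise MotifError(
                        f"motif {name}: expected {width} matrix rows, got {len(rows)}"
                    )
                motifs.append((name, np.array(rows)))
                continue
            i += 1
        if not motifs:
            raise MotifError("no motifs in MEME file")
        name, probs = motifs[index]
        if not bg.all():
            bg = np.full(4, 0.25)
        return cls.from_counts_or_probs(probs, bg, pseudocount, name)

    def to_meme(self, path: str | Path | IO[str]) -> None:
        def emit(fh: IO[str]) -> None:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write("Background letter frequencies\n")
            fh.write(
                " ".join(f"{b} {f:.5f}" for b, f in zip(DNA_BASES, self.background)) + "\n\n"
            )
            fh.write(f"MOTIF {self.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {self.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in self.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")

        if isinstance(path, (str, Path)):
            with open(path, "w") as fh:
                emit(fh)
        else:
            emit(path)


def score_window(pwm: PWM, sequence_window: str, strand: str = "+") -> float | None:
    """Log-odds score of one window; None when the window contains an
    ambiguous base. Minus-strand windows are scored as their reverse
    complement."""
    if len(sequence_window) != pwm.width:
        raise MotifError(
            f"window length {len(sequence_window)} != motif width {pwm.width}"
        )
    seq = sequence_window.upper()
    if strand == "-":
        seq = revcomp_dna(seq)
    codes = encode_dna(seq)
    if (codes < 0).any():
        return None
    return float(pwm.log_odds[np.arange(pwm.width), codes].sum())


class ScoreDistribution:
    """Exact distribution of background W-mer log-odds scores, discretized.

    Each per-position log-odds value is rounded to an integer multiple of
    ``delta`` (default: total score range / 1000); the distribution of the
    integer sum is built by column-wise convolution under the background.
    """

    def __init__(self, pwm: PWM, granularity_bins: int = DEFAULT_GRANULARITY_BINS):
        lo = pwm.log_odds
        span = float((lo.max(axis=1) - lo.min(axis=1)).sum())
        self.delta = span / granularity_bins if span > 0 else 1.0
        self.int_scores = np.rint(lo / self.delta).astype(np.int64)  # (W, 4)
        bg = pwm.background
        # column-wise convolution; track the attainable integer range explicitly
        cur = np.array([1.0])
        cur_min = 0
        for w in range(self.int_scores.shape[0]):
            col = self.int_scores[w]
            new_min = cur_min + int(col.min())
            new_max = cur_min + len(cur) - 1 + int(col.max())
            new = np.zeros(new_max - new_min + 1)
            for j in range(4):
                shift = cur_min + int(col[j]) - new_min
                new[shift : shift + len(cur)] += bg[j] * cur
            cur, cur_min = new, new_min
        self.pmf = cur
        self.min_int = cur_min
        self.max_int = cur_min + len(cur) - 1
        # survival[i] = P(S >= min_int + i)
        self.survival = cur[::-1].cumsum()[::-1]

    def pvalue_int(self, int_score: int) -> float:
        if int_score <= self.min_int:
            return 1.0
        if int_score > self.max_int:
            return float(self.survival[-1])  # smallest attainable tail
        return float(self.survival[int_score - self.min_int])

    def pvalue(self, score: float) -> float:
        if not math.isfinite(score):
            raise MotifError("non-finite score")
        return self.pvalue_int(int(round(score / self.delta)))

    def min_int_score_for(self, p_threshold: float) -> int | None:
        """Smallest integer score whose p-value is < p_threshold; None when
        no attainable score passes."""
        # survival is non-increasing; find first index with survival < p
        passing = np.nonzero(self.survival < p_threshold)[0]
        if len(passing) == 0:
            return None
        return int(self.min_int + passing[0])


def score_pvalue(
    pwm: PWM, score: float, granularity_bins: int = DEFAULT_GRANULARITY_BINS
) -> float:
    """P(background W-mer scores >= score), exact up to discretization."""
    return ScoreDistribution(pwm, granularity_bins).pvalue(score)


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    score: float
    p_value: float


def _scan_strand(
    lo: np.ndarray, int_scores: np.ndarray, codes: np.ndarray, W: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized window scores over one encoded sequence.

    Returns (real_scores, int_score_sums, valid_mask) for all windows.
    """
    n = len(codes) - W + 1
    if n <= 0:
        empty = np.empty(0)
        return empty, np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    real = np.zeros(n)
    ints = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(W):
        sl = safe[i : i + n]
        real += lo[i, sl]
        ints += int_scores[i, sl]
        valid &= codes[i : i + n] >= 0
    return real, ints, valid


def scan_genome(
    pwm: PWM,
    sequences: Mapping[str, str],
    p_threshold: float = P_THRESHOLD,
    granularity_bins: int = DEFAULT_GRANULARITY_BINS,
) -> list[MotifHit]:
    """All windows on both strands with p < p_threshold; overlapping hits
    are all reported. Windows containing N are skipped."""
    if p_threshold <= 0:
        return []
    W = pwm.width
    hits: list[MotifHit] = []
    scorers = []
    for strand, matrix in (("+", pwm), ("-", pwm.reverse_complement())):
        dist = ScoreDistribution(matrix, granularity_bins)
        scorers.append((strand, matrix.log_odds, dist))
    for chrom in sorted(sequences):
        codes = encode_dna(sequences[chrom])
        for strand, lo, dist in scorers:
            real, ints, valid = _scan_strand(lo, dist.int_scores, codes, W)
            if len(real) == 0:
                continue
            min_pass = dist.min_int_score_for(p_threshold)
            if min_pass is None:
                continue
            idx = np.nonzero(valid & (ints >= min_pass))[0]
            for pos in idx:
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(chrom, int(pos), int(pos) + W, strand),
                        strand=strand,
                        score=float(real[pos]),
                        p_value=dist.pvalue_int(int(ints[pos])),
                    )
                )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
    return hits


@dataclass(frozen=True)
class SummitRegion:
    chrom: str
    summit: int  # 0-based
    interval: GenomicInterval
    clipped: bool = False


def summit_regions(
    summits: Sequence[tuple[str, int]], chrom_sizes: Mapping[str, int] | None = None
) -> list[SummitRegion]:
    """201-bp regions [summit-100, summit+101) centered on each summit,
    clipped and flagged at chromosome edges. No merging."""
    regions = []
    for chrom, pos in summits:
        start, end = pos - REGION_HALF, pos + REGION_HALF + 1
        clipped = False
        if start < 0:
            start, clipped = 0, True
        if chrom_sizes is not None and end > chrom_sizes[chrom]:
            end, clipped = chrom_sizes[chrom], True
        regions.append(SummitRegion(chrom, pos, GenomicInterval(chrom, start, end), clipped))
    return regions


@dataclass(frozen=True)
class BoundCall:
    hit: MotifHit
    bound: bool
    max_overlap_bp: int


def classify_bound(
    hits: Sequence[MotifHit],
    regions: Sequence[SummitRegion],
    min_overlap: int = MIN_BOUND_OVERLAP,
) -> list[BoundCall]:
    """An HSE is bound iff its maximum overlap with any summit region is
    >= min_overlap bp. Hit strand is ignored."""
    calls = []
    for hit in hits:
        best = 0
        for region in regions:
            if region.chrom != hit.interval.chrom:
                continue
            best = max(best, overlap_length(hit.interval, region.interval))
        calls.append(BoundCall(hit, best >= min_overlap, best))
    return calls


def promoter_hse_report(
    genes: Sequence[GeneModel],
    hits: Sequence[MotifHit],
    calls: Sequence[BoundCall] = (),
    promoter_bp: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene count of HSE hits (>=1 bp overlap) in the strand-aware 1-kb
    upstream promoter window, with bound-HSE counts when calls are given."""
    bound_by_hit = {id(c.hit): c.bound for c in calls}
    rows = []
    for gene in genes:
        promoter = promoter_interval(
            gene,
            promoter_bp,
            chrom_sizes.get(gene.chrom) if chrom_sizes else None,
        )
        n_hse = n_bound = 0
        if promoter is not None:
            for hit in hits:
                if hit.interval.chrom != promoter.chrom:
                    continue
                if overlap_length(hit.interval, promoter) >= 1:
                    n_hse += 1
                    if bound_by_hit.get(id(hit), False):
                        n_bound += 1
        rows.append(
            {
                "gene_id": gene.gene_id,
                "n_hses": n_hse,
                "n_bound": n_bound,
                "has_bound_hse": n_bound > 0,
            }
        )
    return pd.DataFrame(rows)


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [h.interval.chrom for h in hits],
            "start": [h.interval.start for h in hits],
            "end": [h.interval.end for h in hits],
            "strand": [h.strand for h in hits],
            "score": [h.score for h in hits],
            "p_value": [h.p_value for h in hits],
        }
    )


def calls_to_frame(calls: Sequence[BoundCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.hit.interval.chrom for c in calls],
            "start": [c.hit.interval.start for c in calls],
            "end": [c.hit.interval.end for c in calls],
            "strand": [c.hit.strand for c in calls],
            "max_overlap_bp": [c.max_overlap_bp for c in calls],
            "bound": [c.bound for c in calls],
        }
    )
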