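"""Synthetic genomes, alignments, seed-site plants and motif plants with
recorded ground truth.

The generator emulates the statistical structure the analysis assumes:
negative-binomial exonic counts across replicates, strongly induced
"driver" genes whose readthrough tails decay exponentially into a
downstream "victim" gene (crossing its intergenic-junction window and
introns), heat-shock-only small-RNA signal confined to one intron,
repeat-overlapping induced genes, planted 6-mer seed sites in UTRs, and
planted motif instances at controlled overlaps with summit regions.

Everything is deterministic given the configuration seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomicInterval,
    IJWindow,
    Transcript,
    ij_window,
)
from .hse import PWM, MotifHit, scan_genome, summit_regions
from .seeds import seed_of, site_motif
from .sequence import random_dna

READ_LENGTH = 100


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_chromosomes: int = 1
    chrom_length: int = 420_000
    n_clean_induced: int = 8
    n_readthrough_pairs: int = 4
    n_intronic_ncrna: int = 3
    n_repeat_overlap: int = 3
    n_unchanged: int = 60
    n_replicates: int = 3
    read_length: int = READ_LENGTH
    nb_dispersion: float = 0.1
    depth_log_sd: float = 0.2
    base_mean: float = 100.0
    victim_base_mean: float = 25.0
    ncrna_exon_mean: float = 40.0
    driver_base_mean: float = 60.0
    induced_log2fc_range: tuple[float, float] = (2.0, 4.0)
    driver_log2fc_range: tuple[float, float] = (3.5, 4.5)
    artifact_log2fc: float = 2.5  # exonic boost mimicking spill for ncRNA/repeat genes
    readthrough_fraction: float = 0.6
    tail_decay_bp: float = 2000.0
    intron_signal_mean: float = 400.0
    repeat_overlap_target: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_clean_induced",
            "n_readthrough_pairs",
            "n_intronic_ncrna",
            "n_repeat_overlap",
            "n_unchanged",
            "n_replicates",
            "read_length",
        ):
            if getattr(self, name) < 0 or (
                name in ("n_chromosomes", "chrom_length", "n_replicates", "read_length")
                and getattr(self, name) <= 0
            ):
                raise SimulationError(f"{name} must be positive")
        if self.tail_decay_bp <= 0:
            raise SimulationError("tail_decay_bp must be > 0")
        if self.readthrough_fraction < 0:
            raise SimulationError("readthrough_fraction must be >= 0")

    @property
    def n_genes(self) -> int:
        return (
            self.n_clean_induced
            + 2 * self.n_readthrough_pairs
            + self.n_intronic_ncrna
            + self.n_repeat_overlap
            + self.n_unchanged
        )


@dataclass
class GenomeBundle:
    sequences: dict[str, str]
    genes: list[GeneModel]
    repeats: pd.DataFrame  # BED6 with name = repeat family
    truth: pd.DataFrame  # indexed by gene_id
    config: SimulationConfig

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def windows(self) -> list[IJWindow]:
        return [ij_window(g, self.chrom_sizes[g.chrom]) for g in self.genes]


# exon/intron templates per gene role
_STRUCTURES = {
    "driver": ([400, 400, 400], [100, 100]),
    "victim": ([150, 150, 150], [800, 800]),
    "clean": ([300, 300, 300], [100, 100]),
    "intronic_ncrna": ([150, 150, 150], [300, 800]),
    "repeat": ([300, 300, 300], [100, 100]),
    "unchanged": ([300, 300, 300], [100, 100]),
}

UTR3_LEN = 80


def _make_gene(
    gene_id: str, chrom: str, start: int, strand: str, role: str
) -> GeneModel:
    exon_lens, intron_lens = _STRUCTURES[role]
    exons = []
    pos = start
    for i, ex_len in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + ex_len, strand))
        pos += ex_len
        if i < len(intron_lens):
            pos += intron_lens[i]
    last = exons[-1] if strand == "+" else exons[0]
    if strand == "+":
        utr = GenomicInterval(chrom, last.end - UTR3_LEN, last.end, strand)
    else:
        utr = GenomicInterval(chrom, last.start, last.start + UTR3_LEN, strand)
    tx = Transcript(f"{gene_id}.t1", exons, [utr])
    return GeneModel(gene_id, chrom, strand, [tx])


def _gene_span_length(role: str) -> int:
    exon_lens, intron_lens = _STRUCTURES[role]
    return sum(exon_lens) + sum(intron_lens)


def generate_genome(config: SimulationConfig) -> GenomeBundle:
    """Place genes (drivers immediately upstream of victims), repeats and
    random sequence; returns the bundle with per-gene ground truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    # build the placement schedule: driver/victim pairs stay adjacent
    units: list[list[tuple[str, str]]] = []  # list of [(role, gene_id), ...]
    gi = 0

    def next_id(prefix: str) -> str:
        nonlocal gi
        gi += 1
        return f"{prefix}{gi:03d}"

    for _ in range(config.n_readthrough_pairs):
        units.append([("driver", next_id("drv")), ("victim", next_id("vic"))])
    for _ in range(config.n_clean_induced):
        units.append([("clean", next_id("cln"))])
    for _ in range(config.n_intronic_ncrna):
        units.append([("intronic_ncrna", next_id("inc"))])
    for _ in range(config.n_repeat_overlap):
        units.append([("repeat", next_id("rep"))])
    for _ in range(config.n_unchanged):
        units.append([("unchanged", next_id("unc"))])
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: 2000 for c in chroms}
    genes: list[GeneModel] = []
    repeats_rows = []
    truth_rows = []
    rep_i = 0

    for u_idx, unit in enumerate(units):
        chrom = chroms[u_idx % len(chroms)]
        pair_strand = "+"
        for role, gene_id in unit:
            strand = (
                pair_strand
                if role in ("driver", "victim")
                else ("+" if rng.random() < 0.5 else "-")
            )
            start = cursors[chrom]
            gene = _make_gene(gene_id, chrom, start, strand, role)
            span = gene.span
            if span.end + 2000 > config.chrom_length:
                raise SimulationError(
                    f"cannot place gene {gene_id}: chromosome {chrom} too short "
                    f"({config.chrom_length} bp) for the configured gene count"
                )
            genes.append(gene)

            repeat_frac = 0.0
            if role == "repeat":
                rep_i += 1
                rep_len = int(round(config.repeat_overlap_target * span.length))
                rep_start = span.start
                repeats_rows.append(
                    (chrom, rep_start, rep_start + rep_len, f"SimRep{rep_i}", 0, strand)
                )
                repeat_frac = rep_len / span.length

            if role == "driver":
                log2fc = rng.uniform(*config.driver_log2fc_range)
                mu = config.driver_base_mean
            elif role == "clean":
                log2fc = rng.uniform(*config.induced_log2fc_range)
                mu = config.base_mean
            elif role == "victim":
                log2fc, mu = 0.0, config.victim_base_mean
            elif role == "intronic_ncrna":
                log2fc, mu = config.artifact_log2fc, config.ncrna_exon_mean
            elif role == "repeat":
                log2fc, mu = config.artifact_log2fc, config.base_mean
            else:
                log2fc, mu = 0.0, config.base_mean

            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "role": role,
                    "strand": strand,
                    "mu": mu,
                    "log2fc": log2fc,
                    "is_truly_induced": role in ("driver", "clean"),
                    "has_readthrough_contamination": role == "victim",
                    "has_intronic_ncRNA": role == "intronic_ncrna",
                    "repeat_overlap_fraction": repeat_frac,
                }
            )
            gap = 200 if role == "driver" else int(rng.integers(600, 1500))
            cursors[chrom] = span.end + gap

    # background repeats in intergenic space (never overlapping genes)
    for chrom in chroms:
        pos = cursors[chrom] + 500
        for k in range(3):
            if pos + 400 < config.chrom_length:
                rep_i += 1
                repeats_rows.append((chrom, pos, pos + 300, f"SimRep{rep_i}", 0, "."))
                pos += 1000

    sequences = {c: random_dna(rng, config.chrom_length) for c in chroms}
    repeats = pd.DataFrame(
        repeats_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    truth_cols = [
        "gene_id", "role", "strand", "mu", "log2fc", "is_truly_induced",
        "has_readthrough_contamination", "has_intronic_ncRNA",
        "repeat_overlap_fraction",
    ]
    truth = pd.DataFrame(truth_rows, columns=truth_cols).set_index(
        "gene_id", drop=False
    )
    truth.index.name = None
    return GenomeBundle(sequences, genes, repeats, truth, config)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedReads:
    reads: dict[str, pd.DataFrame]  # sample -> BED6 frame
    conditions: dict[str, str]
    depth_factors: dict[str, float]


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def simulate_alignments(bundle: GenomeBundle) -> SimulatedReads:
    """Per-sample BED read intervals from the genome bundle.

    Exonic counts are NB(mu * FC(condition) * depth, dispersion); drivers
    additionally shed readthrough reads whose start distance past the 3'
    end is exponential with scale ``tail_decay_bp`` (uniform over 6 kb when
    the decay length is infinite); intron-ncRNA genes receive HS-only reads
    confined to their largest intron.
    """
    config = bundle.config
    rng = np.random.default_rng([config.seed, 1])
    rl = config.read_length
    n = config.n_replicates
    samples = [f"CTRL_{i + 1}" for i in range(n)] + [f"HS_{i + 1}" for i in range(n)]
    conditions = {s: ("HS" if s.startswith("HS") else "CTRL") for s in samples}
    depths = {s: float(rng.lognormal(0.0, config.depth_log_sd)) for s in samples}
    sizes = bundle.chrom_sizes
    truth = bundle.truth

    out: dict[str, pd.DataFrame] = {}
    for sample in samples:
        is_hs = conditions[sample] == "HS"
        depth = depths[sample]
        rows: list[tuple[str, int, int, str]] = []

        for gene in bundle.genes:
            info = truth.loc[gene.gene_id]
            fc = 2.0 ** float(info["log2fc"]) if is_hs else 1.0
            mean = float(info["mu"]) * fc * depth
            n_reads = _nb_draw(rng, mean, config.nb_dispersion)
            exons = gene.transcripts[0].exons
            lens = np.array([e.length for e in exons], dtype=float)
            if n_reads > 0:
                choice = rng.choice(len(exons), size=n_reads, p=lens / lens.sum())
                for ci in choice:
                    ex = exons[ci]
                    if ex.length > rl:
                        s = int(rng.integers(ex.start, ex.end - rl + 1))
                        e = s + rl
                    else:
                        s, e = ex.start, ex.end
                    rows.append((gene.chrom, s, e, gene.strand))

            if info["role"] == "driver" and is_hs and config.readthrough_fraction > 0:
                rt_mean = config.readthrough_fraction * mean
                n_rt = _nb_draw(rng, rt_mean, config.nb_dispersion)
                span_end = gene.span.end
                for _ in range(n_rt):
                    if math.isinf(config.tail_decay_bp):
                        d = int(rng.uniform(0, 6000))
                    else:
                        d = int(rng.exponential(config.tail_decay_bp))
                    s = span_end + d
                    e = min(s + rl, sizes[gene.chrom])
                    if e - s >= 1:
                        rows.append((gene.chrom, s, e, gene.strand))

            if info["role"] == "intronic_ncrna" and is_hs:
                introns = gene.transcripts[0].introns
                target = max(introns, key=lambda iv: iv.length)
                n_nc = _nb_draw(rng, config.intron_signal_mean * depth, config.nb_dispersion)
                hi = target.end - min(rl, target.length) + 1
                for _ in range(n_nc):
                    s = int(rng.integers(target.start, hi))
                    e = min(s + rl, target.end)
                    rows.append((gene.chrom, s, e, gene.strand))

        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        df = df.sort_values(["chrom", "start", "end", "strand"]).reset_index(drop=True)
        df.insert(3, "name", [f"{sample}_r{i}" for i in range(len(df))])
        df.insert(4, "score", 0)
        out[sample] = df

    return SimulatedReads(out, conditions, depths)


# ---------------------------------------------------------------------------
# Planted miRNA seed sites
# ---------------------------------------------------------------------------


def _dna_site(mirna_sequence: str) -> str:
    return site_motif(seed_of(mirna_sequence)).replace("U", "T")


def _count_occurrences(motif: str, seq: str) -> int:
    count = start = 0
    while True:
        idx = seq.find(motif, start)
        if idx == -1:
            return count
        count += 1
        start = idx + 1


def plant_seed_sites(
    utr_lengths: Mapping[str, int],
    mirna_sequences: Mapping[str, str],
    counts: Mapping[tuple[str, str], int],
    seed: int = 0,
    max_attempts: int = 500,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate DNA target sequences with exactly the requested number of
    seed-site plants per (mirna, target) and no spurious sites for any
    listed miRNA.

    ``counts`` maps (mirna_id, target_id) -> number of sites to plant.
    Returns (target sequences, truth table with recorded positions).
    """
    rng = np.random.default_rng([seed, 2])
    motifs = {mid: _dna_site(seq) for mid, seq in mirna_sequences.items()}
    per_target: dict[str, list[tuple[str, int]]] = {t: [] for t in utr_lengths}
    for (mid, tid), k in counts.items():
        if mid not in motifs:
            raise SimulationError(f"unknown miRNA {mid!r} in counts")
        if tid not in per_target:
            raise SimulationError(f"unknown target {tid!r} in counts")
        if k > 0:
            per_target[tid].append((mid, k))

    sequences: dict[str, str] = {}
    truth_rows = []
    for tid in sorted(utr_lengths):
        length = utr_lengths[tid]
        plants = sorted(per_target[tid])
        needed = sum(6 * k for _, k in plants)
        if needed > length:
            raise SimulationError(
                f"target {tid}: UTR length {length} too short for {needed} bp of sites"
            )
        for _ in range(max_attempts):
            seq = list(random_dna(rng, length))
            taken: list[tuple[int, int]] = []
            positions: dict[str, list[int]] = {}
            ok = True
            for mid, k in plants:
                positions[mid] = []
                for _ in range(k):
                    for _try in range(200):
                        pos = int(rng.integers(0, length - 6 + 1))
                        if all(pos + 6 <= s or pos >= e for s, e in taken):
                            break
                    else:
                        ok = False
                        break
                    taken.append((pos, pos + 6))
                    positions[mid].append(pos)
                    seq[pos : pos + 6] = motifs[mid]
                if not ok:
                    break
            if not ok:
                continue
            final = "".join(seq)
            expected = {mid: k for mid, k in plants}
            if all(
                _count_occurrences(motifs[mid], final) == expected.get(mid, 0)
                for mid in motifs
            ):
                sequences[tid] = final
                for mid, k in plants:
                    truth_rows.append(
                        {
                            "mirna_id": mid,
                            "target_id": tid,
                            "n_planted": k,
                            "positions": ",".join(map(str, sorted(positions[mid]))),
                        }
                    )
                break
        else:
            raise SimulationError(
                f"target {tid}: could not generate a clean background in "
                f"{max_attempts} attempts"
            )
    truth = pd.DataFrame(
        truth_rows, columns=["mirna_id", "target_id", "n_planted", "positions"]
    )
    return sequences, truth


# ---------------------------------------------------------------------------
# Planted HSEs
# ---------------------------------------------------------------------------

HSE_CONSENSUS = "TTCTAGAACGTTCTAG"


def default_hse_pwm(match_prob: float = 0.85) -> PWM:
    """A sharply peaked motif over a fixed consensus, uniform background."""
    idx = {b: i for i, b in enumerate("ACGT")}
    probs = np.full((len(HSE_CONSENSUS), 4), (1 - match_prob) / 3)
    for i, b in enumerate(HSE_CONSENSUS):
        probs[i, idx[b]] = match_prob
    return PWM(probs, name="SimHSE")


def plant_hses(
    pwm: PWM,
    n_bound: int,
    n_unbound: int,
    seed: int = 0,
    p_threshold: float = 1e-4,
    spacing: int = 3000,
    max_cleanup_rounds: int = 60,
) -> tuple[dict[str, str], list[tuple[str, int]], pd.DataFrame]:
    """Plant consensus motif instances at controlled overlaps with 201-bp
    summit regions.

    Bound instances overlap a region by >= 14 bp (cycling full containment,
    20 and exactly 14); unbound instances overlap by <= 13 bp or sit far
    from every summit. Background windows that scan above threshold are
    re-randomized so planted instances are the only intended hits.
    Returns (sequences, summits, truth table).
    """
    W = pwm.width
    if W > 201:
        raise SimulationError("motif wider than a summit region")
    rng = np.random.default_rng([seed, 3])
    chrom = "chrS"
    n_sites = n_bound + n_unbound
    length = 4000 + max(n_sites, 1) * spacing
    seq = list(random_dna(rng, length))

    summits = [2500 + i * spacing for i in range(n_sites)]
    regions = summit_regions([(chrom, s) for s in summits])
    consensus = pwm.consensus

    bound_overlaps = [W, 20, max(14, min(W, 14))]
    unbound_overlaps = [13, 6, 0]
    truth_rows = []
    planted: list[tuple[int, int]] = []
    for i in range(n_sites):
        region = regions[i].interval
        is_bound = i < n_bound
        cycle = bound_overlaps if is_bound else unbound_overlaps
        k = min(cycle[i % len(cycle)], W)
        if is_bound and k == W:
            start = summits[i] - W // 2  # fully inside the region
            overlap = W
        elif k == 0:
            start = region.end + 500  # far from every region
            overlap = 0
        else:
            start = region.start + k - W
            overlap = k
        seq[start : start + W] = consensus
        planted.append((start, start + W))
        truth_rows.append(
            {
                "instance_id": f"hse{i + 1:03d}",
                "chrom": chrom,
                "start": start,
                "end": start + W,
                "planned_overlap": overlap,
                "bound_truth": overlap >= 14,
            }
        )

    # scrub spurious background hits that do not touch a planted instance
    def spurious(hits: Sequence[MotifHit]) -> list[MotifHit]:
        out = []
        for h in hits:
            if not any(h.interval.start < e and h.interval.end > s for s, e in planted):
                out.append(h)
        return out

    for _ in range(max_cleanup_rounds):
        hits = scan_genome(pwm, {chrom: "".join(seq)}, p_threshold)
        bad = spurious(hits)
        if not bad:
            break
        for h in bad:
            replacement = random_dna(rng, h.interval.length)
            seq[h.interval.start : h.interval.end] = replacement
    else:
        raise SimulationError("could not scrub spurious motif hits from background")

    truth = pd.DataFrame(
        truth_rows,
        columns=["instance_id", "chrom", "start", "end", "planned_overlap", "bound_truth"],
    )
    return {chrom: "".join(seq)}, [(chrom, s) for s in summits], truth


# ---------------------------------------------------------------------------
# FASTA / bundle writers (deterministic, text-only)
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path | IO[str]) -> None:
    def emit(fh: IO[str]) -> None:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            emit(fh)
    else:
        emit(path)


def read_fasta(path: str | Path | IO[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    if isinstance(path, (str, Path)):
        fh = open(path)
        close = True
    else:
        fh, close = path, False
    try:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            out[name] = "".join(chunks)
    finally:
        if close:
            fh.close()
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["induced_log2fc_range"] = list(d["induced_log2fc_range"])
    d["driver_log2fc_range"] = list(d["driver_log2fc_range"])
    return d
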