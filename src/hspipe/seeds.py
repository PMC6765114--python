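"""miRNA seed extraction, seed-site scanning in targets, and the
>=3-miRNA bipartite target network.

Sites are perfect Watson-Crick 6-mer matches to miRNA nucleotides 2-7;
no wobble pairing and no extended site classes. DNA targets are mapped
T -> U before scanning and overlapping occurrences are all counted.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneModel
from .sequence import SequenceError, check_rna, revcomp_rna

SEED_START = 1  # 0-based: miRNA nucleotides 2..7
SEED_END = 7
MIN_DEGREE = 3

REGULATIONS = ("up", "down", "unchanged")


@dataclass(frozen=True)
class MirnaRecord:
    mirna_id: str
    sequence: str  # RNA, 5'->3'
    regulation: str = "unchanged"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", check_rna(self.sequence))
        if len(self.sequence) < 8:
            raise SequenceError(
                f"{self.mirna_id}: miRNA must be >= 8 nt for seed extraction"
            )
        if self.regulation not in REGULATIONS:
            raise SequenceError(f"{self.mirna_id}: bad regulation {self.regulation!r}")

    @property
    def seed(self) -> str:
        return seed_of(self.sequence)


def seed_of(mirna_sequence: str) -> str:
    """Seed = miRNA nucleotides 2-7 (6-mer), 5'->3'."""
    seq = check_rna(mirna_sequence)
    if len(seq) < SEED_END:
        raise SequenceError("miRNA sequence too short for a 2-7 seed")
    return seq[SEED_START:SEED_END]


def site_motif(seed: str) -> str:
    """Target-strand site: reverse complement of the seed, reported 5'->3' RNA."""
    seed = check_rna(seed)
    return revcomp_rna(seed)


@dataclass
class SeedSiteSet:
    mirna_id: str
    target_id: str
    seed: str
    motif: str
    positions: list[int]  # 0-based offsets in the target sequence

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def scan_sites(motif: str, target_sequence: str, mirna_id: str = "", target_id: str = "") -> SeedSiteSet:
    """All start offsets of exact motif matches in the target (overlaps included)."""
    motif = check_rna(motif)
    target = check_rna(target_sequence)
    pattern = re.compile("(?=" + re.escape(motif) + ")")
    positions = [m.start() for m in pattern.finditer(target)]
    return SeedSiteSet(
        mirna_id=mirna_id,
        target_id=target_id,
        seed=site_motif(motif),  # involution: motif's revcomp is the seed
        motif=motif,
        positions=positions,
    )


def longest_utr(
    gene: GeneModel, utr_sequences: Mapping[str, str]
) -> tuple[str, str] | None:
    """Longest annotated 3'UTR isoform of a gene, ties to the smallest
    transcript_id; None (with a warning) when no transcript has a UTR."""
    candidates = []
    for tx in gene.transcripts:
        if tx.utr3 and tx.transcript_id in utr_sequences:
            candidates.append((-len(utr_sequences[tx.transcript_id]), tx.transcript_id))
        elif tx.transcript_id in utr_sequences and not tx.utr3:
            # sequence supplied without annotation: still usable
            candidates.append((-len(utr_sequences[tx.transcript_id]), tx.transcript_id))
    if not candidates:
        warnings.warn(f"gene {gene.gene_id}: no annotated 3'UTR; skipped")
        return None
    candidates.sort()
    tx_id = candidates[0][1]
    return tx_id, utr_sequences[tx_id]


@dataclass
class TargetNetwork:
    """Bipartite miRNA -> target network restricted to targets with
    degree >= min_degree distinct miRNA partners."""

    edges: pd.DataFrame  # columns: mirna_id, target_id, n_sites
    degrees: pd.Series  # target_id -> distinct-miRNA degree (retained targets)
    min_degree: int = MIN_DEGREE
    all_sites: list[SeedSiteSet] = field(default_factory=list)


def build_network(
    targets: Mapping[str, str],
    mirnas: Iterable[MirnaRecord | tuple[str, str]],
    min_degree: int = MIN_DEGREE,
) -> TargetNetwork:
    """Scan every miRNA against every target sequence and keep targets hit by
    at least ``min_degree`` distinct miRNAs.

    ``targets`` maps target id -> sequence (3'UTR for mRNAs; full transcript
    for lincRNA checks). Direction pairing (up-miRNAs vs down-mRNAs and vice
    versa) is the caller's responsibility.
    """
    records = [
        m if isinstance(m, MirnaRecord) else MirnaRecord(m[0], m[1]) for m in mirnas
    ]
    sites: list[SeedSiteSet] = []
    rows = []
    for rec in records:
        motif = site_motif(rec.seed)
        for target_id in sorted(targets):
            hit = scan_sites(motif, targets[target_id], rec.mirna_id, target_id)
            if hit.n_sites:
                sites.append(hit)
                rows.append((rec.mirna_id, target_id, hit.n_sites))
    edges = pd.DataFrame(rows, columns=["mirna_id", "target_id", "n_sites"])
    if edges.empty:
        degrees = pd.Series(dtype=int, name="degree")
        return TargetNetwork(edges, degrees, min_degree, sites)
    degree_all = edges.groupby("target_id")["mirna_id"].nunique()
    keep = degree_all[degree_all >= min_degree]
    edges = (
        edges[edges["target_id"].isin(keep.index)]
        .sort_values(["target_id", "mirna_id"])
        .reset_index(drop=True)
    )
    degrees = keep.rename("degree").sort_index()
    return TargetNetwork(edges, degrees, min_degree, sites)


def sites_to_frame(sites: Sequence[SeedSiteSet]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": s.mirna_id,
            "target_id": s.target_id,
            "seed": s.seed,
            "motif": s.motif,
            "n_sites": s.n_sites,
            "positions": ",".join(map(str, s.positions)),
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "seed", "motif", "n_sites", "positions"]
    )


def read_mirna_table(path) -> list[MirnaRecord]:
    """TSV with columns mirna_id, sequence, regulation."""
    df = pd.read_csv(path, sep="\t")
    return [
        MirnaRecord(str(r.mirna_id), str(r.sequence), str(r.regulation))
        for r in df.itertuples()
    ]


def write_mirna_table(records: Sequence[MirnaRecord], path) -> None:
    pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "sequence": [r.sequence for r in records],
            "regulation": [r.regulation for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
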