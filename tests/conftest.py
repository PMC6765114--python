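from __future__ import annotations

import numpy as np
import pytest

from hspipe.annotation import GeneModel, GenomicInterval, Transcript, ij_window
from hspipe.counts import (
    classify_de,
    compute_size_factors,
    count_features,
    fold_changes,
)
from hspipe.readthrough import apply_filters, reports_from_counts
from hspipe.annotation import intervals_from_bed
from hspipe.simulate import SimulationConfig, generate_genome, simulate_alignments


def make_gene(
    gene_id: str = "g1",
    chrom: str = "chr1",
    strand: str = "+",
    exons: list[tuple[int, int]] = ((1000, 1200), (1400, 1600)),
    utr3: list[tuple[int, int]] = (),
    biotype: str = "protein_coding",
    tx_id: str | None = None,
) -> GeneModel:
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    u3 = [GenomicInterval(chrom, s, e, strand) for s, e in utr3]
    tx = Transcript(tx_id or f"{gene_id}.t1", ivs, u3)
    return GeneModel(gene_id, chrom, strand, [tx], biotype)


@pytest.fixture
def plus_gene() -> GeneModel:
    return make_gene("gplus", strand="+", exons=[(1000, 1200), (1400, 1600)])


@pytest.fixture
def minus_gene() -> GeneModel:
    return make_gene("gminus", strand="-", exons=[(500, 600), (700, 800)])


def run_filter_pipeline(seed: int, config: SimulationConfig | None = None):
    """simulate -> count -> normalize -> DE -> filter, in memory.

    Returns (bundle, up-set, removed-id set, reports).
    """
    cfg = config or SimulationConfig()
    cfg = SimulationConfig(**{**cfg.__dict__, "seed": seed})
    bundle = generate_genome(cfg)
    sim = simulate_alignments(bundle)
    table = count_features(
        sim.reads, bundle.genes, bundle.windows, bundle.repeats, conditions=sim.conditions
    )
    compute_size_factors(table)
    up = classify_de(fold_changes(table), 2.0, 50.0, "up")
    reports = reports_from_counts(
        table, bundle.genes, intervals_from_bed(bundle.repeats)
    )
    _, removed = apply_filters(sorted(up), reports)
    return bundle, up, {r.gene_id for r in removed}, reports


SMALL_SIM = dict(
    n_clean_induced=2,
    n_readthrough_pairs=1,
    n_intronic_ncrna=1,
    n_repeat_overlap=1,
    n_unchanged=10,
    chrom_length=80_000,
)


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(**SMALL_SIM)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
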