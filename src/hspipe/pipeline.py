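"""End-to-end orchestration: simulate -> count -> normalize -> fold change
-> readthrough filter -> seed network -> HSE scan, with a JSON run manifest.

Every stage writes self-describing TSV/text outputs; re-running with the
same configuration reproduces byte-identical stage outputs (the manifest
additionally records a timestamp).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    ij_window,
    read_bed,
    read_gene_models,
    windows_to_bed,
    write_bed,
    write_chrom_sizes,
    write_gene_models,
)
from .counts import CountTable, classify_de, compute_size_factors, count_features, fold_changes
from .hse import (
    PWM,
    classify_bound,
    calls_to_frame,
    hits_to_frame,
    promoter_hse_report,
    scan_genome,
    summit_regions,
)
from .readthrough import (
    FilterThresholds,
    apply_filters,
    reports_from_counts,
    reports_to_frame,
)
from .seeds import MirnaRecord, build_network, sites_to_frame, write_mirna_table
from .simulate import (
    SimulationConfig,
    config_to_dict,
    default_hse_pwm,
    generate_genome,
    plant_hses,
    plant_seed_sites,
    read_fasta,
    simulate_alignments,
    write_fasta,
)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All thresholds default to the published values."""

    seed: int = 0
    fc_threshold: float = 2.0
    basemean_min: float = 50.0
    basemean_min_repeats: float = 100.0
    ir_dog: float = 0.4
    ij_min: float = 2.0
    ir_ncrna: float = 1.0
    repeat_frac: float = 0.5
    min_degree: int = 3
    p_threshold: float = 1e-4
    region_width: int = 201
    min_overlap: int = 14
    promoter_bp: int = 1000
    stranded: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        for name in (
            "fc_threshold",
            "basemean_min",
            "basemean_min_repeats",
            "ir_dog",
            "ij_min",
            "ir_ncrna",
            "repeat_frac",
            "min_degree",
            "p_threshold",
            "region_width",
            "min_overlap",
            "promoter_bp",
        ):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config: {name} must be > 0")
        self.simulation.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        sim_cfg = SimulationConfig(**sim) if isinstance(sim, dict) else sim
        cfg = cls(**{k: v for k, v in data.items() if k in _FIELD_NAMES}, simulation=sim_cfg)
        unknown = set(data) - _FIELD_NAMES
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "seed" in data:
            cfg.simulation.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = config_to_dict(self.simulation)
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig) if f.name != "simulation"}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ----------------------------------------------------------------------
# Demo seed/motif inputs bundled into the simulation stage
# ----------------------------------------------------------------------


def _demo_mirnas(rng_seed: int) -> list[MirnaRecord]:
    import numpy as np

    from .sequence import random_dna

    rng = np.random.default_rng([rng_seed, 4])
    records = []
    for i in range(4):
        seq = random_dna(rng, 22).replace("T", "U")
        records.append(MirnaRecord(f"sim-miR-u{i + 1}", seq, "up"))
    for i in range(4):
        seq = random_dna(rng, 22).replace("T", "U")
        records.append(MirnaRecord(f"sim-miR-d{i + 1}", seq, "down"))
    return records


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on freshly simulated inputs; returns the manifest."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "reads").mkdir(exist_ok=True)
    stages: dict[str, dict] = {}

    # -- simulate ------------------------------------------------------
    # config.seed is the single source of randomness for the whole run
    bundle = generate_genome(dataclasses.replace(config.simulation, seed=config.seed))
    sim = simulate_alignments(bundle)
    write_fasta(bundle.sequences, out / "genome.fa")
    write_gene_models(bundle.genes, out / "genes.gtf")
    write_bed(bundle.repeats, out / "repeats.bed")
    write_chrom_sizes(bundle.chrom_sizes, out / "chrom.sizes")
    bundle.truth.reset_index(drop=True).to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    for sample, df in sim.reads.items():
        write_bed(df, out / "reads" / f"{sample}.bed")
    stages["simulate"] = {
        "n_genes": len(bundle.genes),
        "n_reads": {s: len(df) for s, df in sim.reads.items()},
    }

    # seed-site plants for the seeds stage
    mirnas = _demo_mirnas(config.seed)
    up_mirnas = [m for m in mirnas if m.regulation == "up"]
    down_targets = [f"down_gene{i + 1}" for i in range(6)]
    plant_counts = {}
    for t_i, tid in enumerate(down_targets):
        for m_i, m in enumerate(up_mirnas):
            # first three targets are hit by >= 3 miRNAs, the rest by fewer
            k = 2 if (t_i < 3 and m_i < 3) or (m_i == t_i % 4) else 0
            if k:
                plant_counts[(m.mirna_id, tid)] = k
    utr_lengths = {tid: 400 for tid in down_targets}
    utr_seqs, seed_truth = plant_seed_sites(
        utr_lengths,
        {m.mirna_id: m.sequence for m in up_mirnas},
        plant_counts,
        seed=config.seed,
    )
    write_fasta(utr_seqs, out / "utrs.fa")
    write_mirna_table(mirnas, out / "mirnas.tsv")
    seed_truth.to_csv(out / "truth_seeds.tsv", sep="\t", index=False)

    # motif plants for the HSE stage
    pwm = default_hse_pwm()
    hse_seqs, summits, hse_truth = plant_hses(
        pwm, n_bound=5, n_unbound=5, seed=config.seed, p_threshold=config.p_threshold
    )
    write_fasta(hse_seqs, out / "hse_genome.fa")
    pwm.to_meme(out / "motif.meme")
    pd.DataFrame(
        [(c, s, s + 1, f"summit{i + 1}", 0, ".") for i, (c, s) in enumerate(summits)],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    ).to_csv(out / "summits.bed", sep="\t", header=False, index=False)
    hse_truth.to_csv(out / "truth_hses.tsv", sep="\t", index=False)

    # -- count + normalize ---------------------------------------------
    windows = bundle.windows
    pd.DataFrame(windows_to_bed(windows)).pipe(write_bed, out / "ij_windows.bed")
    table = count_features(
        sim.reads,
        bundle.genes,
        windows,
        bundle.repeats,
        stranded=config.stranded,
        conditions=sim.conditions,
    )
    compute_size_factors(table)
    table.to_tsv(out / "counts.tsv")
    table.size_factors.rename_axis("sample").reset_index().to_csv(
        out / "size_factors.tsv", sep="\t", index=False
    )
    stages["count"] = {"n_features": len(table.raw), "n_samples": len(table.samples)}

    # -- fold changes + DE classification ------------------------------
    fc = fold_changes(table, kinds=("exon", "repeat"))
    fc.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
    gene_fc = fc[fc["kind"] == "exon"]
    rep_fc = fc[fc["kind"] == "repeat"]
    up = classify_de(gene_fc, config.fc_threshold, config.basemean_min, "up")
    down = classify_de(gene_fc, config.fc_threshold, config.basemean_min, "down")
    up_repeats = classify_de(rep_fc, config.fc_threshold, config.basemean_min_repeats, "up")
    (out / "de_up.txt").write_text("".join(f"{g}\n" for g in sorted(up)))
    (out / "de_down.txt").write_text("".join(f"{g}\n" for g in sorted(down)))
    (out / "de_up_repeats.txt").write_text("".join(f"{g}\n" for g in sorted(up_repeats)))
    stages["de"] = {"n_up": len(up), "n_down": len(down), "n_up_repeats": len(up_repeats)}

    # -- readthrough filter --------------------------------------------
    thresholds = FilterThresholds(
        config.ir_dog, config.ij_min, config.ir_ncrna, config.repeat_frac
    )
    from .annotation import intervals_from_bed

    reports = reports_from_counts(
        table,
        bundle.genes,
        intervals_from_bed(bundle.repeats),
        thresholds,
        edge_clipped={w.gene_id: w.edge_clipped for w in windows},
    )
    kept, removed = apply_filters(sorted(up), reports)
    reports_to_frame(reports).to_csv(out / "filter_report.tsv", sep="\t", index=False)
    (out / "kept.txt").write_text("".join(f"{g}\n" for g in kept))
    pd.DataFrame(
        [(r.gene_id, ",".join(sorted(r.reasons))) for r in removed],
        columns=["gene_id", "reasons"],
    ).to_csv(out / "removed.tsv", sep="\t", index=False)
    stages["filter"] = {"n_input": len(up), "n_kept": len(kept), "n_removed": len(removed)}

    # -- seed network ---------------------------------------------------
    network = build_network(
        utr_seqs, up_mirnas, min_degree=config.min_degree
    )
    sites_to_frame(network.all_sites).to_csv(out / "seed_sites.tsv", sep="\t", index=False)
    network.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    network.degrees.rename_axis("target_id").reset_index().to_csv(
        out / "target_degrees.tsv", sep="\t", index=False
    )
    stages["seeds"] = {
        "n_sites": len(network.all_sites),
        "n_network_targets": len(network.degrees),
    }

    # -- HSE scan -------------------------------------------------------
    hits = scan_genome(pwm, hse_seqs, config.p_threshold)
    regions = summit_regions(summits, {c: len(s) for c, s in hse_seqs.items()})
    calls = classify_bound(hits, regions, config.min_overlap)
    hits_to_frame(hits).to_csv(out / "hse_hits.tsv", sep="\t", index=False)
    calls_to_frame(calls).to_csv(out / "bound_calls.tsv", sep="\t", index=False)
    report = promoter_hse_report(
        bundle.genes, hits, calls, config.promoter_bp, bundle.chrom_sizes
    )
    report.to_csv(out / "promoter_report.tsv", sep="\t", index=False)
    stages["hse"] = {"n_hits": len(hits), "n_bound": sum(c.bound for c in calls)}

    # -- manifest -------------------------------------------------------
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config.to_dict(),
        "stages": stages,
        "checksums": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def validate_inputs(
    gtf: str | None = None,
    fasta: str | None = None,
    beds: dict[str, str] | None = None,
    conditions: dict[str, str] | None = None,
) -> list[str]:
    """Best-effort consistency report; returns a list of failure strings."""
    failures: list[str] = []
    gtf_chroms: set[str] = set()
    fasta_chroms: set[str] = set()
    if gtf:
        try:
            genes = read_gene_models(gtf)
            gtf_chroms = {g.chrom for g in genes}
        except Exception as exc:
            failures.append(f"GTF parse error: {exc}")
    if fasta:
        try:
            fasta_chroms = set(read_fasta(fasta))
        except Exception as exc:
            failures.append(f"FASTA parse error: {exc}")
    if gtf_chroms and fasta_chroms and not gtf_chroms <= fasta_chroms:
        failures.append(
            f"chromosome names in GTF not in FASTA: {sorted(gtf_chroms - fasta_chroms)}"
        )
    for label, path in (beds or {}).items():
        try:
            df = read_bed(path)
            bed_chroms = set(df["chrom"].astype(str))
            if fasta_chroms and not bed_chroms <= fasta_chroms:
                failures.append(
                    f"{label}: chromosomes not in FASTA: {sorted(bed_chroms - fasta_chroms)}"
                )
        except Exception as exc:
            failures.append(f"{label} parse error: {exc}")
    for sample, cond in (conditions or {}).items():
        if cond not in ("CTRL", "HS"):
            failures.append(f"sample {sample}: condition label {cond!r} is not CTRL/HS")
    return failures
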