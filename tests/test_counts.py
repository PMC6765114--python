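import numpy as np
import pandas as pd
import pytest

from hspipe.annotation import GenomicInterval, ij_window
from hspipe.counts import (
    CountError,
    CountTable,
    classify_de,
    compute_size_factors,
    count_features,
    fold_changes,
    size_factors,
)
from .conftest import make_gene


def reads_frame(rows):
    """rows: (chrom, start, end, strand)"""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df.insert(3, "name", [f"r{i}" for i in range(len(df))])
    df.insert(4, "score", 0)
    return df


@pytest.fixture
def one_gene():
    return make_gene("g1", exons=[(100, 200), (300, 400)])


class TestCountFeatures:
    def test_junction_read_is_exonic(self, one_gene):
        # read [150,250) overlaps exon [100,200) and intron [200,300)
        table = count_features(
            {"CTRL_1": reads_frame([("chr1", 150, 250, "+")])}, [one_gene]
        )
        assert table.raw.loc[("exon", "g1"), "CTRL_1"] == 1
        assert table.raw.loc[("intron", "g1"), "CTRL_1"] == 0

    def test_intron_only_read(self, one_gene):
        table = count_features(
            {"CTRL_1": reads_frame([("chr1", 210, 290, "+")])}, [one_gene]
        )
        assert table.raw.loc[("exon", "g1"), "CTRL_1"] == 0
        assert table.raw.loc[("intron", "g1"), "CTRL_1"] == 1

    def test_ij_window_one_bp(self, one_gene):
        w = ij_window(one_gene)  # [90, 111)
        table = count_features(
            {"CTRL_1": reads_frame([("chr1", 110, 150, "+")])}, [one_gene], [w]
        )
        assert table.raw.loc[("ij", "g1"), "CTRL_1"] == 1
        table2 = count_features(
            {"CTRL_1": reads_frame([("chr1", 111, 150, "+")])}, [one_gene], [w]
        )
        assert table2.raw.loc[("ij", "g1"), "CTRL_1"] == 0

    def test_strand_mismatch_not_counted(self, one_gene):
        table = count_features(
            {"CTRL_1": reads_frame([("chr1", 150, 180, "-")])}, [one_gene]
        )
        assert table.raw.loc[("exon", "g1"), "CTRL_1"] == 0
        table_un = count_features(
            {"CTRL_1": reads_frame([("chr1", 150, 180, "-")])}, [one_gene],
            stranded=False,
        )
        assert table_un.raw.loc[("exon", "g1"), "CTRL_1"] == 1

    def test_unknown_chrom_skipped_with_warning(self, one_gene):
        with pytest.warns(UserWarning, match="skipped 1"):
            table = count_features(
                {"CTRL_1": reads_frame([("chrX", 150, 180, "+")])}, [one_gene]
            )
        assert table.skipped_reads == {"CTRL_1": 1}

    def test_repeat_primary_assignment_tie_lexicographic(self, one_gene):
        repeats = pd.DataFrame(
            [
                ("chr1", 1000, 1100, "famB", 0, "+"),
                ("chr1", 1050, 1150, "famA", 0, "+"),
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        # read [1040,1110): famB overlap 60, famA overlap 60 -> tie -> famA
        table = count_features(
            {"CTRL_1": reads_frame([("chr1", 1040, 1110, "+")])}, [one_gene],
            repeats=repeats,
        )
        assert table.raw.loc[("repeat", "famA"), "CTRL_1"] == 1
        assert table.raw.loc[("repeat", "famB"), "CTRL_1"] == 0

    def test_read_conservation_per_gene(self, one_gene):
        """A read contributes at most 1 to a gene's exon+intron pair."""
        rng = np.random.default_rng(0)
        rows = [
            ("chr1", int(s), int(s) + 50, "+")
            for s in rng.integers(0, 450, size=200)
        ]
        table = count_features({"CTRL_1": reads_frame(rows)}, [one_gene])
        total = (
            table.raw.loc[("exon", "g1"), "CTRL_1"]
            + table.raw.loc[("intron", "g1"), "CTRL_1"]
        )
        # every counted read overlaps the gene span once
        span = GenomicInterval("chr1", 100, 400)
        n_overlapping = sum(1 for c, s, e, st in rows if s < span.end and e > span.start)
        assert total <= n_overlapping


def brute_force_counts(reads_rows, genes, windows, repeats_df, stranded=True):
    """Independent per-read oracle with plain loops."""
    from collections import Counter

    def ov(s1, e1, s2, e2):
        return max(0, min(e1, e2) - max(s1, s2))

    def match(rs, fs):
        return (not stranded) or fs == "." or rs == fs

    counts = Counter()
    for chrom, start, end, strand in reads_rows:
        for g in genes:
            if g.chrom != chrom or not match(strand, g.strand):
                continue
            if any(ov(start, end, e.start, e.end) > 0 for e in g.exons):
                counts[("exon", g.gene_id)] += 1
            elif any(ov(start, end, i.start, i.end) > 0 for i in g.introns):
                counts[("intron", g.gene_id)] += 1
        for w in windows:
            if w.interval.chrom == chrom and match(strand, w.interval.strand):
                if ov(start, end, w.interval.start, w.interval.end) > 0:
                    counts[("ij", w.gene_id)] += 1
        fam_ov = {}
        for r in repeats_df.itertuples():
            if str(r.chrom) != chrom or not match(strand, str(r.strand)):
                continue
            o = ov(start, end, int(r.start), int(r.end))
            if o > 0:
                fam_ov[str(r.name)] = fam_ov.get(str(r.name), 0) + o
        if fam_ov:
            best = max(fam_ov.values())
            fam = sorted(f for f, o in fam_ov.items() if o == best)[0]
            counts[("repeat", fam)] += 1
    return counts


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_instance(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(50):
            start = int(rng.integers(0, 48_000))
            n_ex = int(rng.integers(1, 4))
            exons, pos = [], start
            for _ in range(n_ex):
                le = int(rng.integers(50, 300))
                exons.append((pos, pos + le))
                pos += le + int(rng.integers(50, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(make_gene(f"g{i:02d}", exons=exons, strand=strand))
        windows = [ij_window(g) for g in genes]
        repeats = pd.DataFrame(
            [
                ("chr1", int(s), int(s) + int(rng.integers(100, 500)),
                 f"fam{rng.integers(0, 5)}", 0, ".")
                for s in rng.integers(0, 50_000, size=20)
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        rows = [
            ("chr1", int(s), int(s) + 100, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(0, 50_000, size=1000)
        ]
        table = count_features(
            {"CTRL_1": reads_frame(rows)}, genes, windows, repeats
        )
        oracle = brute_force_counts(rows, genes, windows, repeats)
        for key in table.raw.index:
            assert table.raw.loc[key, "CTRL_1"] == oracle.get(key, 0), key


class TestSizeFactors:
    def test_doubling(self):
        m = pd.DataFrame({"s1": [10, 20, 30, 40], "s2": [20, 40, 60, 80]})
        sf = size_factors(m)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        # median-of-ratios closed form: geomean per gene = K*sqrt(2)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))

    def test_single_sample(self):
        m = pd.DataFrame({"s1": [10, 20, 30]})
        assert size_factors(m)["s1"] == pytest.approx(1.0)

    def test_identical_samples(self):
        m = pd.DataFrame({"a": [5, 7, 9], "b": [5, 7, 9], "c": [5, 7, 9]})
        assert size_factors(m).nunique() == 1

    def test_zero_rows_excluded(self):
        m = pd.DataFrame({"s1": [0, 10, 20], "s2": [100, 10, 20]})
        sf = size_factors(m)  # first gene has a zero -> excluded
        assert sf["s1"] == pytest.approx(sf["s2"])

    def test_all_zero_error(self):
        m = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(CountError, match="pseudocount"):
            size_factors(m)


def small_table():
    idx = pd.MultiIndex.from_tuples(
        [("exon", "gA"), ("exon", "gB")], names=["kind", "feature"]
    )
    raw = pd.DataFrame(
        {"CTRL_1": [100, 100], "HS_1": [200, 100]}, index=idx
    )
    table = CountTable(raw=raw, conditions={"CTRL_1": "CTRL", "HS_1": "HS"})
    table.size_factors = pd.Series({"CTRL_1": 1.0, "HS_1": 1.0})
    return table


class TestFoldChanges:
    def test_doubling_is_log2fc_1(self):
        fc = fold_changes(small_table(), pseudocount=0)
        rec = fc.set_index("feature")
        assert rec.loc["gA", "log2fc"] == pytest.approx(1.0)
        assert rec.loc["gB", "log2fc"] == pytest.approx(0.0)

    def test_zero_ctrl_with_pseudocount(self):
        idx = pd.MultiIndex.from_tuples([("exon", "g")], names=["kind", "feature"])
        table = CountTable(
            raw=pd.DataFrame({"CTRL_1": [0], "HS_1": [63]}, index=idx),
            conditions={"CTRL_1": "CTRL", "HS_1": "HS"},
        )
        table.size_factors = pd.Series({"CTRL_1": 1.0, "HS_1": 1.0})
        fc = fold_changes(table, pseudocount=1)
        assert fc["log2fc"].iloc[0] == pytest.approx(6.0)

    def test_basemean_is_mean_over_all_samples(self):
        fc = fold_changes(small_table())
        assert fc.set_index("feature").loc["gA", "baseMean"] == pytest.approx(150.0)

    def test_scaling_invariance(self):
        """Scaling one sample's raw counts scales its size factor relative to
        the others and leaves fold changes unchanged (size factors are
        defined up to a common rescaling)."""
        rng = np.random.default_rng(1)
        idx = pd.MultiIndex.from_tuples(
            [("exon", f"g{i}") for i in range(20)], names=["kind", "feature"]
        )
        base = rng.integers(10, 200, size=(20, 4))
        raw = pd.DataFrame(base, index=idx, columns=["CTRL_1", "CTRL_2", "HS_1", "HS_2"])
        conditions = {"CTRL_1": "CTRL", "CTRL_2": "CTRL", "HS_1": "HS", "HS_2": "HS"}
        t1 = CountTable(raw=raw, conditions=conditions)
        compute_size_factors(t1)
        scaled = raw.copy()
        scaled["HS_1"] = scaled["HS_1"] * 3
        t2 = CountTable(raw=scaled, conditions=conditions)
        compute_size_factors(t2)
        rel1 = t1.size_factors / t1.size_factors["CTRL_1"]
        rel2 = t2.size_factors / t2.size_factors["CTRL_1"]
        assert rel2["HS_1"] / rel1["HS_1"] == pytest.approx(3.0)
        for s in ("CTRL_2", "HS_2"):
            assert rel2[s] == pytest.approx(rel1[s])
        fc1 = fold_changes(t1, pseudocount=0)["log2fc"].to_numpy()
        fc2 = fold_changes(t2, pseudocount=0)["log2fc"].to_numpy()
        np.testing.assert_allclose(fc1, fc2, rtol=1e-9)


class TestClassifyDE:
    def records(self):
        return pd.DataFrame(
            {
                "feature": ["a", "b", "c"],
                "baseMean": [50.0, 1000.0, 100.0],
                "log2fc": [1.0, 0.9, -1.0],
            }
        )

    def test_inclusive_boundaries(self):
        assert classify_de(self.records(), 2, 50, "up") == {"a"}

    def test_below_fc_excluded(self):
        assert "b" not in classify_de(self.records(), 2, 50, "up")

    def test_down_symmetric(self):
        assert classify_de(self.records(), 2, 50, "down") == {"c"}


class TestRoundTrip:
    def test_tsv_round_trip(self, tmp_path, one_gene):
        rows = [("chr1", 150, 250, "+"), ("chr1", 310, 390, "+")]
        table = count_features(
            {"CTRL_1": reads_frame(rows), "HS_1": reads_frame(rows)}, [one_gene]
        )
        compute_size_factors(table)
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        back = CountTable.from_tsv(path)
        pd.testing.assert_frame_equal(
            back.raw.sort_index(), table.raw.sort_index(), check_names=False
        )
        assert back.conditions == table.conditions
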