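import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hspipe.annotation import GenomicInterval
from hspipe.hse import (
    PWM,
    MotifError,
    MotifHit,
    ScoreDistribution,
    classify_bound,
    promoter_hse_report,
    scan_genome,
    score_pvalue,
    score_window,
    summit_regions,
)
from hspipe.sequence import random_dna, revcomp_dna
from hspipe.simulate import default_hse_pwm, plant_hses
from .conftest import make_gene


def uniform_pwm(width=4):
    return PWM(np.full((width, 4), 0.25))


def peaked_pwm(consensus, p=0.9):
    idx = {b: i for i, b in enumerate("ACGT")}
    probs = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        probs[i, idx[b]] = p
    return PWM(probs)


class TestPWM:
    def test_meme_round_trip(self):
        pwm = peaked_pwm("ACGTAC")
        buf = io.StringIO()
        pwm.to_meme(buf)
        buf.seek(0)
        back = PWM.from_meme(buf)
        assert back.width == 6
        np.testing.assert_allclose(back.probs, pwm.probs, atol=1e-3)

    def test_position_must_sum_to_one(self):
        with pytest.raises(MotifError):
            PWM(np.array([[0.5, 0.5, 0.5, 0.5]]))

    def test_background_positive(self):
        with pytest.raises(MotifError):
            PWM(np.full((2, 4), 0.25), background=np.array([0.5, 0.5, 0.0, 0.0]))

    def test_consensus(self):
        assert peaked_pwm("TTCGA").consensus == "TTCGA"


class TestScoreWindow:
    def test_background_pwm_scores_zero(self):
        pwm = uniform_pwm(5)
        for w in ("ACGTA", "TTTTT", "GCGCG"):
            assert score_window(pwm, w) == pytest.approx(0.0)

    def test_single_letter_closed_form(self):
        pwm = PWM.from_counts_or_probs(np.array([[1.0, 0, 0, 0]]), pseudocount=1e-4)
        s = score_window(pwm, "A")
        assert s == pytest.approx(np.log(4.0), rel=1e-3)

    def test_minus_strand_equals_revcomp(self):
        pwm = peaked_pwm("ACGTTC")
        rng = np.random.default_rng(0)
        for _ in range(20):
            w = random_dna(rng, 6)
            assert score_window(pwm, w, "-") == pytest.approx(
                score_window(pwm, revcomp_dna(w), "+")
            )

    def test_ambiguous_base_skipped(self):
        assert score_window(uniform_pwm(3), "ANT") is None

    def test_wrong_length(self):
        with pytest.raises(MotifError):
            score_window(uniform_pwm(3), "ACGT")


class TestScorePvalue:
    def test_w1_best_letter(self):
        pwm = PWM.from_counts_or_probs(np.array([[1.0, 0, 0, 0]]), pseudocount=1e-4)
        best = score_window(pwm, "A")
        assert score_pvalue(pwm, best) == pytest.approx(0.25)

    def test_below_minimum_is_one(self):
        pwm = peaked_pwm("ACGT")
        assert score_pvalue(pwm, -1e9) == 1.0

    def test_non_finite_error(self):
        with pytest.raises(MotifError):
            score_pvalue(uniform_pwm(2), float("nan"))

    @pytest.mark.parametrize("width", [2, 3, 4, 5, 6])
    def test_enumeration_oracle(self, width):
        """Exhaustive 4^W enumeration; DP must agree within the probability
        mass of words whose scores sit within rounding range of the
        threshold."""
        rng = np.random.default_rng(width)
        pwm = PWM.from_counts_or_probs(rng.dirichlet([0.8] * 4, size=width))
        dist = ScoreDistribution(pwm)
        lo = pwm.log_odds
        words = list(itertools.product(range(4), repeat=width))
        scores = np.array([lo[np.arange(width), list(w)].sum() for w in words])
        probs = np.array([np.prod(pwm.background[list(w)]) for w in words])
        for q in (5, 25, 50, 75, 95, 99.9):
            thr = float(np.percentile(scores, q))
            exact = probs[scores >= thr].sum()
            approx = dist.pvalue(thr)
            slack = probs[np.abs(scores - thr) <= (width + 1) * dist.delta].sum()
            assert abs(exact - approx) <= slack + 1e-12

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_score(self, seed):
        rng = np.random.default_rng(seed)
        pwm = PWM.from_counts_or_probs(rng.dirichlet([1] * 4, size=3))
        dist = ScoreDistribution(pwm)
        grid = np.linspace(dist.min_int * dist.delta, dist.max_int * dist.delta, 25)
        ps = [dist.pvalue(s) for s in grid]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)


class TestScanGenome:
    def test_planted_hit_on_clean_background(self):
        pwm = default_hse_pwm()
        seqs, _, truth = plant_hses(pwm, n_bound=1, n_unbound=0, seed=3)
        hits = scan_genome(pwm, seqs)
        plus = [h for h in hits if h.strand == "+"]
        planted = truth.iloc[0]
        assert any(
            h.interval.start == planted.start and h.interval.end == planted.end
            for h in plus
        )
        # every + hit coincides with a planted instance on clean background
        for h in plus:
            assert h.interval.start == planted.start

    def test_zero_threshold_empty(self):
        pwm = default_hse_pwm()
        assert scan_genome(pwm, {"c": "ACGT" * 100}, p_threshold=0) == []

    def test_reverse_complement_symmetry(self):
        pwm = default_hse_pwm()
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 3000)
        seq = seq[:1500] + pwm.consensus + seq[1500:]
        fwd = scan_genome(pwm, {"c": seq})
        rev = scan_genome(pwm, {"c": revcomp_dna(seq)})
        L = len(seq)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (L - h.interval.end, L - h.interval.start, flip[h.strand]) for h in rev
        )
        assert mirrored == sorted(
            (h.interval.start, h.interval.end, h.strand) for h in fwd
        )

    def test_reported_hits_below_threshold(self):
        pwm = default_hse_pwm()
        seqs, _, _ = plant_hses(pwm, 2, 2, seed=5)
        for h in scan_genome(pwm, seqs, p_threshold=1e-4):
            assert 0 < h.p_value < 1e-4


class TestSummitRegions:
    def test_width_201(self):
        (r,) = summit_regions([("c", 5000)])
        assert (r.interval.start, r.interval.end) == (4900, 5101)
        assert r.interval.length == 201

    def test_edge_clip(self):
        (r,) = summit_regions([("c", 50)])
        assert r.clipped and r.interval.start == 0 and r.interval.end == 151

    def test_no_merging(self):
        regions = summit_regions([("c", 1000), ("c", 1100)])
        assert len(regions) == 2
        assert regions[0].interval != regions[1].interval


def hit_at(start, end, chrom="c", strand="+"):
    return MotifHit(GenomicInterval(chrom, start, end, strand), strand, 10.0, 1e-6)


class TestClassifyBound:
    def test_boundary_14(self):
        (region,) = summit_regions([("c", 5000)])  # [4900, 5101)
        hit14 = hit_at(4900 - 2, 4900 + 14)  # overlap 14
        hit13 = hit_at(4900 - 3, 4900 + 13)  # overlap 13
        calls = classify_bound([hit14, hit13], [region])
        assert calls[0].bound and calls[0].max_overlap_bp == 14
        assert not calls[1].bound and calls[1].max_overlap_bp == 13

    def test_fully_inside(self):
        (region,) = summit_regions([("c", 5000)])
        hit = hit_at(5000, 5016)
        (call,) = classify_bound([hit], [region])
        assert call.bound and call.max_overlap_bp == 16

    def test_max_over_regions(self):
        regions = summit_regions([("c", 1000), ("c", 1300)])
        hit = hit_at(1195, 1215)  # overlaps region1 by 6, region2 by 15
        (call,) = classify_bound([hit], regions)
        assert call.max_overlap_bp == 15 and call.bound

    def test_strand_ignored(self):
        (region,) = summit_regions([("c", 5000)])
        hit = hit_at(5000, 5016, strand="-")
        assert classify_bound([hit], [region])[0].bound


class TestPromoterReport:
    def test_counts_and_flags(self):
        gene = make_gene("g", chrom="c", exons=[(5000, 6000)])  # promoter [4000, 5000)
        inside = hit_at(4500, 4516)
        downstream = hit_at(5500, 5516)
        (region,) = summit_regions([("c", 4510)])
        hits = [inside, downstream]
        calls = classify_bound(hits, [region])
        rep = promoter_hse_report([gene], hits, calls).set_index("gene_id")
        assert rep.loc["g", "n_hses"] == 1
        assert rep.loc["g", "n_bound"] == 1
        assert bool(rep.loc["g", "has_bound_hse"])

    def test_downstream_only_is_zero(self):
        gene = make_gene("g", chrom="c", exons=[(5000, 6000)])
        rep = promoter_hse_report([gene], [hit_at(5500, 5516)]).set_index("gene_id")
        assert rep.loc["g", "n_hses"] == 0
        assert not bool(rep.loc["g", "has_bound_hse"])


class TestPlantedHses:
    def test_classifier_recovers_truth(self):
        pwm = default_hse_pwm()
        seqs, summits, truth = plant_hses(pwm, n_bound=5, n_unbound=5, seed=9)
        hits = scan_genome(pwm, seqs)
        regions = summit_regions(summits, {c: len(s) for c, s in seqs.items()})
        calls = classify_bound(hits, regions)
        call_by_iv = {
            (c.hit.interval.start, c.hit.interval.end): c
            for c in calls
            if c.hit.strand == "+"
        }
        for row in truth.itertuples():
            call = call_by_iv[(row.start, row.end)]
            assert call.bound == row.bound_truth, row
            assert call.max_overlap_bp == row.planned_overlap

    def test_overlap_14_is_bound_13_is_not(self):
        pwm = default_hse_pwm()
        seqs, summits, truth = plant_hses(pwm, n_bound=3, n_unbound=1, seed=2)
        by_overlap = truth.set_index("planned_overlap")
        assert bool(by_overlap.loc[14, "bound_truth"])
        assert not bool(by_overlap.loc[13, "bound_truth"])
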