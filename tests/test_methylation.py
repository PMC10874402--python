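"""Epimutation calling: site classes, Fisher exact test, gene flagging."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact

from taslrs import simulate as sim
from taslrs.methylation import (
    HYPER,
    HYPO,
    NONE,
    NORMALLY_METHYLATED,
    NORMALLY_UNMETHYLATED,
    OTHER,
    CpgCounts,
    SiteCall,
    call_site,
    classify_site,
    fisher_two_sided,
    gene_reports_frame,
    methylation_ratio,
    promoter_window,
    run_epimutation,
    score_genes,
)
from taslrs.regions import GenomicInterval, GeneModel


def fisher_enumeration_oracle(a, b, c, d):
    """Exact two-sided p by integer enumeration of all fixed-margin tables."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    lo, hi = max(0, col1 - (c + d)), min(col1, row1)
    num_obs = comb(row1, a) * comb(n - row1, col1 - a)
    total = 0
    for x in range(lo, hi + 1):
        num = comb(row1, x) * comb(n - row1, col1 - x)
        if num <= num_obs:
            total += num
    return float(Fraction(total, comb(n, col1)))


class TestRatioAndClasses:
    def test_ratio_values(self):
        assert methylation_ratio(5, 5) == 0.5
        assert methylation_ratio(0, 7) == 0.0
        assert methylation_ratio(0, 0) is None

    def test_all_controls_low_is_normally_unmethylated(self):
        counts = [(1, 9)] * 10  # ratio 0.1, coverage 10
        assert classify_site(counts) == NORMALLY_UNMETHYLATED

    def test_all_controls_high_is_normally_methylated(self):
        assert classify_site([(9, 1)] * 10) == NORMALLY_METHYLATED

    def test_one_deviant_control_breaks_the_class(self):
        counts = [(1, 9)] * 9 + [(5, 15)]  # one control at 0.25
        assert classify_site(counts) == OTHER

    def test_boundary_ratio_included(self):
        assert classify_site([(2, 8)] * 10) == NORMALLY_UNMETHYLATED  # exactly 0.2
        assert classify_site([(8, 2)] * 10) == NORMALLY_METHYLATED  # exactly 0.8

    def test_low_coverage_control_gives_other(self):
        counts = [(1, 9)] * 9 + [(0, 0)]
        assert classify_site(counts) == OTHER
        assert classify_site([(0, 4)] + [(1, 9)] * 9) == OTHER  # coverage 4 < 5


class TestFisher:
    def test_no_association_possible(self):
        assert fisher_two_sided(0, 10, 0, 90) == 1.0
        assert fisher_two_sided(0, 0, 0, 0) == 1.0

    def test_worked_example_matches_enumeration(self):
        assert fisher_two_sided(9, 1, 5, 95) == pytest.approx(
            fisher_enumeration_oracle(9, 1, 5, 95), abs=1e-12
        )

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            assert fisher_two_sided(a, b, c, d) == pytest.approx(
                fisher_two_sided(b, a, d, c), abs=1e-12
            )

    def test_random_battery_against_enumeration_and_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 101, 4))
            p = fisher_two_sided(a, b, c, d)
            assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), abs=1e-12)
            assert p == pytest.approx(fisher_exact([[a, b], [c, d]])[1], abs=1e-9)


class TestCallSite:
    def _target(self, n_meth, n_unmeth, hap=1):
        return CpgCounts("chr1", 100, hap, n_meth, n_unmeth)

    def test_hyper_requires_enumerated_significance(self):
        # p(9,1 vs 5,95) ~ 4.1e-9 <= 0.05 -> hyper (verified by the oracle)
        p = fisher_enumeration_oracle(9, 1, 5, 95)
        call = call_site(self._target(9, 1), (5, 95), NORMALLY_UNMETHYLATED)
        assert p <= 0.05
        assert call.direction == HYPER
        assert call.p_value == pytest.approx(p, abs=1e-12)

    def test_ratio_exactly_point_two_is_not_hyper(self):
        call = call_site(self._target(2, 8), (5, 95), NORMALLY_UNMETHYLATED)
        assert call.direction == NONE  # boundary is strict: "above 0.2"

    def test_other_class_never_called(self):
        assert call_site(self._target(10, 0), (5, 95), OTHER).direction == NONE

    def test_zero_coverage_target_gives_none(self):
        call = call_site(self._target(0, 0), (5, 95), NORMALLY_UNMETHYLATED)
        assert call.direction == NONE and call.p_value is None

    def test_direction_respects_site_class_on_random_battery(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            nm, nu = int(rng.integers(0, 20)), int(rng.integers(0, 20))
            pool = (int(rng.integers(0, 200)), int(rng.integers(0, 200)))
            cls = [NORMALLY_UNMETHYLATED, NORMALLY_METHYLATED, OTHER][int(rng.integers(0, 3))]
            call = call_site(self._target(nm, nu), pool, cls)
            if call.direction == HYPER:
                assert cls == NORMALLY_UNMETHYLATED
            if call.direction == HYPO:
                assert cls == NORMALLY_METHYLATED


class TestPromoterWindow:
    def _gene(self, strand, start=7_000, end=15_000):
        iv = GenomicInterval("chr1", start, end, strand)
        return GeneModel("G1", "G1", strand, iv)

    def test_plus_strand_window(self):
        g = self._gene("+", start=9_999)  # tss = 10_000 (1-based)
        w = promoter_window(g)
        assert (w.start, w.end) == (7_999, 9_999)

    def test_minus_strand_window(self):
        g = self._gene("-", end=10_000)  # tss = 10_000
        w = promoter_window(g)
        assert (w.start, w.end) == (10_000, 12_000)

    def test_clipped_at_chromosome_start(self):
        g = self._gene("+", start=499, end=5_000)  # tss 500
        w = promoter_window(g)
        assert w.start == 0 and w.end == 499


class TestScoreGenes:
    def _gene(self):
        return GeneModel("G1", "G1", "+",
                         GenomicInterval("chr1", 9_999, 20_000, "+"))

    def _call(self, pos, p, hap=1):
        return SiteCall("chr1", pos, hap, HYPER, p, 0.9, NORMALLY_UNMETHYLATED)

    def test_mean_rule(self):
        calls = [self._call(9_000, 1e-6), self._call(9_010, 1e-5),
                 self._call(9_020, 1e-4)]
        (r1, r2) = score_genes(calls, [self._gene()])
        assert r1.haplotype == 1 and r1.n_aberrant == 3
        assert r1.mean_neg_log10_p == pytest.approx(5.0)
        assert r1.flagged
        assert r2.n_aberrant == 0 and not r2.flagged

    def test_count_rule_with_weak_p_values(self):
        calls = [self._call(9_000 + i, 0.05) for i in range(10)]
        r = score_genes(calls, [self._gene()])[0]
        assert r.mean_neg_log10_p < 4.5 and r.n_aberrant == 10
        assert r.flagged

    def test_single_weak_site_not_flagged(self):
        r = score_genes([self._call(9_000, 0.04)], [self._gene()])[0]
        assert r.n_aberrant == 1 and not r.flagged

    def test_calls_outside_window_ignored(self):
        calls = [self._call(15_000, 1e-10)]  # inside gene body, not promoter
        r = score_genes(calls, [self._gene()])[0]
        assert r.n_aberrant == 0 and not r.flagged


class TestEndToEnd:
    def test_planted_epimutation_is_the_only_flag(self, genes, genome):
        fx = sim.make_methylation_dataset(
            7, genes, genome, epimutated_gene=genes[2].symbol, epimutated_haplotype=1
        )
        _, reports = run_epimutation(fx.target, fx.controls, genes)
        flagged = {(r.gene.symbol, r.haplotype) for r in reports if r.flagged}
        assert flagged == {(genes[2].symbol, 1)}

    def test_no_epimutation_dataset_yields_zero_flags(self, genes, genome):
        fx = sim.make_methylation_dataset(8, genes, genome, epimutated_gene=None)
        _, reports = run_epimutation(fx.target, fx.controls, genes)
        assert not any(r.flagged for r in reports)

    def test_increasing_methylation_never_unflags(self, genes, genome):
        # monotonicity: raising methylated counts at planted sites (coverage
        # held) can only strengthen the evidence
        fx = sim.make_methylation_dataset(
            9, genes, genome, epimutated_gene=genes[0].symbol, epimutated_haplotype=2
        )
        _, reports = run_epimutation(fx.target, fx.controls, genes)
        assert any(r.flagged for r in reports)
        boosted = fx.target.copy()
        cov = boosted["n_meth"] + boosted["n_unmeth"]
        boosted["n_meth"] = cov
        boosted["n_unmeth"] = 0
        window = promoter_window(genes[0])
        in_promoter = (
            (boosted["chrom"] == window.chrom)
            & (boosted["pos"] - 1 >= window.start)
            & (boosted["pos"] - 1 < window.end)
            & (boosted["haplotype"] == 2)
        )
        merged = fx.target.copy()
        merged.loc[in_promoter, ["n_meth", "n_unmeth"]] = \
            boosted.loc[in_promoter, ["n_meth", "n_unmeth"]]
        _, reports2 = run_epimutation(merged, fx.controls, genes)
        flagged2 = {(r.gene.symbol, r.haplotype) for r in reports2 if r.flagged}
        assert (genes[0].symbol, 2) in flagged2
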