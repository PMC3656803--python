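import itertools
import logging

import numpy as np
import pandas as pd
import pytest

import bxmap
from bxmap import Chromosome, CrossDesign, Marker, MarkerMap, finemap, simpanel
from bxmap.errors import NoConsistentIntervalError, UsageError
from bxmap.simpanel import FINE_MICROSATELLITES, FINE_SNPS, MUTANT, WILDTYPE

from _oracles import grid_localize


def toy_map(positions, chrom="1", bps=None):
    bps = bps or [None] * len(positions)
    return MarkerMap(
        [Chromosome(chrom, [Marker(f"m{i + 1}", p, b)
                            for i, (p, b) in enumerate(zip(positions, bps))])]
    )


def toy_panel(patterns, phenotypes, positions, chrom="1", trait_pos=5.0):
    """Hand-built panel: patterns are origin strings over the toy markers."""
    mm = toy_map(positions, chrom)
    ids = [f"i{k}" for k in range(len(patterns))]
    geno = pd.DataFrame(
        [list(p) for p in patterns], index=ids, columns=mm.marker_ids, dtype=object
    ).replace({"-": np.nan})
    return bxmap.BackcrossPanel(
        genotypes=geno,
        phenotypes=pd.Series(phenotypes, index=ids),
        design=CrossDesign("A-strain", "B-strain", chrom, trait_pos),
        marker_map=mm,
        provenance="real",
    )


class TestTabulateHaplotypes:
    def test_complete_linkage_gives_two_classes(self):
        panel = toy_panel(
            ["BBB"] * 4 + ["AAA"] * 3,
            [MUTANT] * 4 + [WILDTYPE] * 3,
            [1.0, 2.0, 3.0],
        )
        table = bxmap.tabulate_haplotypes(panel)
        assert len(table.classes) == 2
        assert [c.count for c in table.classes] == [4, 3]

    def test_counts_sum_to_panel_size(self, fine_panel):
        table = bxmap.tabulate_haplotypes(fine_panel, FINE_MICROSATELLITES)
        assert sum(c.count for c in table.classes) + len(table.incomplete_ids) == 374

    def test_hand_enumerated_toy_classes(self):
        # six individuals over three markers, classes enumerated by brute force
        patterns = ["ABB", "ABB", "BBB", "AAA", "ABA", "AAA"]
        phenos = [MUTANT, MUTANT, MUTANT, WILDTYPE, WILDTYPE, WILDTYPE]
        panel = toy_panel(patterns, phenos, [1.0, 4.0, 9.0])
        expected = {}
        for pat, ph in zip(patterns, phenos):
            expected[(pat, ph)] = expected.get((pat, ph), 0) + 1
        table = bxmap.tabulate_haplotypes(panel)
        got = {(c.pattern, c.phenotype): c.count for c in table.classes}
        assert got == expected
        # sorted by descending count
        counts = [c.count for c in table.classes]
        assert counts == sorted(counts, reverse=True)

    def test_incomplete_individuals_reported_not_dropped(self):
        panel = toy_panel(["AB-", "ABB"], [MUTANT, MUTANT], [1.0, 2.0, 3.0])
        table = bxmap.tabulate_haplotypes(panel)
        assert table.incomplete_ids == ["i0"]
        assert sum(c.count for c in table.classes) == 1

    def test_multi_chromosome_subset_rejected(self, scan_panel):
        with pytest.raises(UsageError):
            bxmap.tabulate_haplotypes(scan_panel, ["M1.1", "M2.1"])


class TestConstrainLocus:
    def make_class(self, pattern, phenotype, positions):
        mm = toy_map(positions)
        return (
            finemap.HaplotypeClass(
                pattern=pattern, phenotype=phenotype, count=1,
                member_ids=["x"], marker_ids=mm.marker_ids,
            ),
            mm,
        )

    def test_mutant_single_left_recombinant(self):
        # mutant carrying A at the first marker only: locus strictly below it
        hap, mm = self.make_class("ABBBB", MUTANT, [2.0, 5.0, 16.0, 20.0, 30.0])
        design = CrossDesign("a", "b", "1", 9.0)
        segs = bxmap.constrain_locus(hap, design, mm)
        assert segs == [(2.0, 30.0 + simpanel.END_MARGIN_CM)]

    def test_nonrecombinant_wildtype_uninformative(self):
        hap, mm = self.make_class("AAA", WILDTYPE, [1.0, 5.0, 9.0])
        segs = bxmap.constrain_locus(hap, CrossDesign("a", "b", "1", 2.0), mm)
        assert segs == [(0.0, 9.0 + simpanel.END_MARGIN_CM)]

    def test_double_recombinant_two_segments(self):
        hap, mm = self.make_class("BAB", MUTANT, [1.0, 5.0, 9.0])
        segs = bxmap.constrain_locus(hap, CrossDesign("a", "b", "1", 2.0), mm)
        assert segs == [(0.0, 5.0), (5.0, 9.0 + simpanel.END_MARGIN_CM)]
        # brute-force cross-check on a fine grid avoiding exact marker points
        from _oracles import _consistent_at

        for x in np.arange(0.05, 19.0, 0.1):
            in_segs = any(lo < x < hi for lo, hi in segs)
            assert in_segs == _consistent_at(x, [1.0, 5.0, 9.0], list("BAB"), "B")

    def test_contradiction_flagged_as_empty(self):
        hap, mm = self.make_class("AAA", MUTANT, [1.0, 5.0, 9.0])
        segs = bxmap.constrain_locus(hap, CrossDesign("a", "b", "1", 2.0), mm)
        assert segs == []


class TestLocalize:
    def test_zero_recombinants_spans_chromosome(self, caplog):
        panel = toy_panel(
            ["BBB"] * 3 + ["AAA"] * 3,
            [MUTANT] * 3 + [WILDTYPE] * 3,
            [1.0, 5.0, 9.0],
        )
        logging.getLogger("bxmap.finemap").setLevel(logging.WARNING)
        with caplog.at_level(logging.WARNING, logger="bxmap.finemap"):
            interval = bxmap.localize_locus(panel)
        assert interval.left_marker == "m1" and interval.right_marker == "m3"
        assert interval.unbounded_left and interval.unbounded_right
        assert interval.n_recombinant_in_interval == 0
        assert any("unbounded" in r.message for r in caplog.records)

    def test_flanking_markers_and_length(self, fine_panel):
        interval = bxmap.localize_locus(fine_panel,
                                        marker_ids=FINE_MICROSATELLITES)
        assert (interval.left_marker, interval.right_marker) == ("M2.3", "M2.4")
        k, n = interval.n_recombinant_in_interval, interval.n_typed_both
        assert interval.genetic_length_cm == pytest.approx(100 * k / n)
        p = k / n
        assert interval.se_cm == pytest.approx(100 * np.sqrt(p * (1 - p) / n))
        # physical span from flanking marker bp: 11.66 Mb in the fixture map
        assert interval.physical_span_mb == pytest.approx(11.66)

    def test_supporting_constraints_point_inward(self, fine_panel):
        interval = bxmap.localize_locus(fine_panel,
                                        marker_ids=FINE_MICROSATELLITES)
        directions = {d for _, d in interval.supporting_constraints}
        assert directions == {"locus_below_left", "locus_above_right"}

    def test_no_consistent_interval_raises(self):
        # three pairwise-disjoint constraint sets: consensus below half
        panel = toy_panel(
            ["BAAAA", "AABAA", "AAAAB"],
            [MUTANT, MUTANT, MUTANT],
            [1.0, 3.0, 5.0, 7.0, 9.0],
        )
        with pytest.raises(NoConsistentIntervalError):
            bxmap.localize_locus(panel)

    def test_interval_length_estimator_value(self):
        cm, se = bxmap.recombinant_fraction_cm(41, 374)
        assert cm == pytest.approx(10.96, abs=0.005)
        assert se == pytest.approx(100 * np.sqrt((41 / 374) * (333 / 374) / 374),
                                   abs=1e-9)


class TestSelectRecombinants:
    def test_size_matches_interval_count(self, fine_panel):
        interval = bxmap.localize_locus(fine_panel,
                                        marker_ids=FINE_MICROSATELLITES)
        rec = bxmap.select_recombinants(fine_panel, interval)
        assert rec.n == interval.n_recombinant_in_interval

    def test_size_within_binomial_band_of_map_expectation(self, fine_panel):
        interval = bxmap.localize_locus(fine_panel,
                                        marker_ids=FINE_MICROSATELLITES)
        rec = bxmap.select_recombinants(fine_panel, interval)
        r = bxmap.cm_to_recfrac(11.0)
        sigma = np.sqrt(r * (1 - r) * 374)
        assert abs(rec.n - 374 * r) < 3 * sigma

    def test_missing_flank_excluded(self):
        panel = toy_panel(
            ["AB", "-B", "AA"],
            [MUTANT, MUTANT, WILDTYPE],
            [1.0, 9.0],
        )
        interval = bxmap.localize_locus(panel)
        rec = bxmap.select_recombinants(panel, interval)
        assert rec.individual_ids == ["i0"]


class TestRefine:
    def test_crossover_counts_conserved(self, fine_panel):
        interval = bxmap.localize_locus(fine_panel,
                                        marker_ids=FINE_MICROSATELLITES)
        rec = bxmap.select_recombinants(fine_panel, interval)
        res = bxmap.refine_with_markers(rec, FINE_SNPS, interval=interval,
                                        n_total=interval.n_typed_both)
        total = sum(n for _, _, n in res.crossover_counts)
        assert total == rec.n - len(res.excluded_ids)

    def test_refined_pair_brackets_trait(self, fine_panel):
        interval = bxmap.localize_locus(fine_panel,
                                        marker_ids=FINE_MICROSATELLITES)
        rec = bxmap.select_recombinants(fine_panel, interval)
        res = bxmap.refine_with_markers(rec, FINE_SNPS, interval=interval,
                                        n_total=interval.n_typed_both)
        assert (res.interval.left_marker, res.interval.right_marker) == \
            ("SNP1", "SNP2")
        lo, hi = res.interval.span_cm
        assert lo < simpanel.FINE_TRAIT_POS_CM < hi
        assert res.interval.physical_span_mb == pytest.approx(0.55)

    def test_identical_secondary_calls_assign_terminal_gap(self):
        # recombinant between flanks, same origin at every secondary marker:
        # its single breakpoint must land in a terminal gap
        panel = toy_panel(
            ["ABBBB", "AAAAB", "BBBBB", "AAAAA"],
            [MUTANT, MUTANT, MUTANT, WILDTYPE],
            [1.0, 3.0, 5.0, 7.0, 9.0],
            trait_pos=6.0,
        )
        interval = bxmap.localize_locus(panel, marker_ids=["m1", "m5"])
        rec = bxmap.select_recombinants(panel, interval)
        res = bxmap.refine_with_markers(rec, ["m2", "m3", "m4"],
                                        interval=interval)
        gaps = {(l, r): n for l, r, n in res.crossover_counts}
        assert gaps[("m1", "m2")] == 1  # i0 switches in the first gap
        assert gaps[("m4", "m5")] == 1  # i1 switches in the last gap

    def test_double_crossover_excluded_with_warning(self, caplog):
        panel = toy_panel(
            ["ABABB", "ABBBB", "AAAAB", "AAAAA"],
            [MUTANT, MUTANT, MUTANT, WILDTYPE],
            [1.0, 3.0, 5.0, 7.0, 9.0],
            trait_pos=6.0,
        )
        interval = bxmap.localize_locus(panel, marker_ids=["m1", "m5"])
        rec = bxmap.select_recombinants(panel, interval)
        logging.getLogger("bxmap.finemap").setLevel(logging.WARNING)
        with caplog.at_level(logging.WARNING, logger="bxmap.finemap"):
            res = bxmap.refine_with_markers(rec, ["m2", "m3", "m4"],
                                            interval=interval)
        assert "i0" in res.excluded_ids
        assert any("double crossover" in r.message for r in caplog.records)

    def test_secondary_marker_outside_span_rejected(self, fine_panel):
        interval = bxmap.localize_locus(fine_panel,
                                        marker_ids=FINE_MICROSATELLITES)
        rec = bxmap.select_recombinants(fine_panel, interval)
        with pytest.raises(UsageError):
            bxmap.refine_with_markers(rec, ["M2.5"], interval=interval)


class TestStatisticalProperties:
    def test_interval_shrinks_in_expectation(self):
        """Mean interval genetic length is non-increasing as n doubles."""
        mm = simpanel.fine_fixture_map(include_snps=False)
        design = simpanel.fine_fixture_design()
        means = []
        for n in (100, 200, 400):
            lengths = []
            for seed in range(200):
                panel = bxmap.simulate_panel(design, mm, n=n, seed=seed)
                iv = bxmap.localize_locus(panel)
                lengths.append(iv.genetic_length_cm)
            means.append(np.mean(lengths))
        assert means[0] >= means[1] >= means[2]

    def test_length_estimator_recovers_recombinant_fraction(self):
        """The cM estimate converges on 100·r(gap), the recombinant fraction,
        not the map distance itself (documented behavior)."""
        mm = simpanel.fine_fixture_map(include_snps=False)
        design = simpanel.fine_fixture_design()
        lengths = []
        for seed in range(500):
            panel = bxmap.simulate_panel(design, mm, n=374, seed=10_000 + seed)
            iv = bxmap.localize_locus(panel)
            lengths.append(iv.genetic_length_cm)
        expected = 100 * bxmap.cm_to_recfrac(11.0)
        assert abs(np.mean(lengths) - expected) < 0.5


class TestGridOracleAgreement:
    def test_small_panel_matches_grid_scan(self):
        """Interval bounds equal a 0.01 cM grid consistency scan on random
        small noiseless panels."""
        rng = np.random.default_rng(777)
        for trial in range(40):
            k = rng.integers(2, 7)
            positions = np.sort(rng.uniform(0.0, 40.0, size=k))
            while np.any(np.diff(positions) < 0.5):
                positions = np.sort(rng.uniform(0.0, 40.0, size=k))
            mm = toy_map(list(np.round(positions, 2)))
            trait = float(np.round(rng.uniform(0.0, positions[-1] + 5.0), 2))
            design = CrossDesign("a", "b", "1", trait)
            n = int(rng.integers(3, 11))
            panel = bxmap.simulate_panel(design, mm, n=n,
                                         seed=int(rng.integers(2**31)))
            iv = bxmap.localize_locus(panel)
            lo_g, hi_g = grid_localize(panel, panel.marker_ids)
            lo, hi = iv.span_cm
            assert abs(lo - lo_g) <= 0.02, (trial, lo, lo_g)
            assert abs(hi - hi_g) <= 0.02, (trial, hi, hi_g)
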