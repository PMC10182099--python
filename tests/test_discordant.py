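"""Discordant-pair extraction, quadrants, boundary and region analysis."""

import numpy as np
import pytest

import dsbseq
from dsbseq.discordant import (DiscordantPair, background_fraction,
                               boundary_estimate, classify_quadrant,
                               classify_regions, discordant_coverage,
                               discordant_fraction, extract_discordant)
from dsbseq.mapping import MappedPair, PairClass, pair_reads


def aln(chrom, start, strand="+", n_hits=1):
    return dsbseq.AlignmentRecord("r", chrom, start, 75, strand, n_hits)


def mp(a1, a2):
    return MappedPair("r", a1, a2, pair_reads(a1, a2))


class TestExtract:
    def test_splits_gc_pairs_from_background(self, genome):
        pairs = [
            mp(aln("chrIII", 100), aln("chrV", 200, "-")),
            mp(aln("chrV", 300), aln("chrIII", 400, "-")),  # order-insensitive
            mp(aln("chrIII", 100), aln("chrVIII", 50, "-")),
            mp(aln("chrIII", 100), aln("chrIII", 350, "-")),  # concordant
            mp(aln("chrIII", 100), aln("chrV", 200, "-", n_hits=2)),  # multi
        ]
        gc, others = extract_discordant(pairs, genome)
        assert len(gc) == 2 and len(others) == 1
        assert gc[0].recipient_coord == 100 and gc[0].donor_coord == 200
        assert gc[1].recipient_coord == 400 and gc[1].donor_coord == 300

    def test_midpoint_convention(self, genome):
        pairs = [mp(aln("chrIII", 100), aln("chrV", 200, "-"))]
        gc, _ = extract_discordant(pairs, genome, coordinate="midpoint")
        assert gc[0].recipient_coord == 137


class TestFraction:
    def test_values(self):
        assert discordant_fraction(0, 10) == 0.0
        assert discordant_fraction(5, 10**6) == 5e-6
        with pytest.raises(ValueError):
            discordant_fraction(1, 0)


class TestQuadrants:
    def pair(self, rec_off, don_off, genome):
        return DiscordantPair(genome.ho_site + rec_off, genome.ho_inc_site + don_off,
                              "+", "-", 75)

    def test_definitions(self, genome):
        assert classify_quadrant(self.pair(-600, -500, genome),
                                 genome.ho_site, genome.ho_inc_site) == "LB"
        assert classify_quadrant(self.pair(200, -500, genome),
                                 genome.ho_site, genome.ho_inc_site) == "RB"
        assert classify_quadrant(self.pair(-600, 80, genome),
                                 genome.ho_site, genome.ho_inc_site) == "LT"
        assert classify_quadrant(self.pair(200, 80, genome),
                                 genome.ho_site, genome.ho_inc_site) == "RT"

    def test_on_axis_goes_right_top(self, genome):
        assert classify_quadrant(self.pair(0, 0, genome),
                                 genome.ho_site, genome.ho_inc_site) == "RT"

    def test_totals_conserved_on_simulation(self, wt_run, genome):
        gc, _ = extract_discordant(wt_run["mapped"][10], genome)
        quads = [classify_quadrant(p, genome.ho_site, genome.ho_inc_site) for p in gc]
        assert len(quads) == len(gc)
        assert set(quads) <= {"LB", "RB", "LT", "RT"}


class TestCoverageAndBoundary:
    def test_track_sums_conserve_reads(self, genome):
        gc = [DiscordantPair(genome.ho_site - 300, genome.ho_inc_site - 100, "+", "-", 75),
              DiscordantPair(genome.ho_site + 50, genome.ho_inc_site + 20, "+", "-", 75)]
        offs, rec, don, excl = discordant_coverage(gc, genome, span=1500)
        assert excl == 0
        assert rec.sum() == don.sum() == 2 * 75

    def test_donor_mate_outside_arms_excluded(self, genome):
        gc = [DiscordantPair(genome.ho_site - 300, 100, "+", "-", 75)]
        *_, excl = discordant_coverage(gc, genome, span=1500)
        assert excl == 1

    def test_symmetric_peaks_cross_at_centre(self):
        offs = np.arange(-1500, 1500)
        tri = np.maximum(0, 300 - np.abs(offs))
        rec = np.roll(tri, -150).astype(float)
        don = np.roll(tri, 150).astype(float)
        x = boundary_estimate(offs, rec, don, (-600, 600))
        assert x == pytest.approx(0.0, abs=2)
        # swapping the tracks returns the same coordinate
        assert boundary_estimate(offs, don, rec, (-600, 600)) == pytest.approx(x, abs=2)

    def test_no_crossing_censored(self):
        offs = np.arange(-1500, 1500)
        rec = np.full(offs.size, 5.0)
        don = np.full(offs.size, 1.0)
        assert boundary_estimate(offs, rec, don, (-600, 600)) is None


class TestRegions:
    def test_single_region_hundred_percent(self, genome):
        gc = [DiscordantPair(genome.ho_site - 700, genome.ho_inc_site - 500, "+", "-", 75)
              for _ in range(5)]
        out = classify_regions(gc, genome, [("A", -1500, 0), ("D", 0, 1500)])
        assert out["proportions"]["A"] == 1.0
        assert out["counts"]["D"] == 0
        assert sum(out["proportions"].values()) == pytest.approx(1.0)

    def test_overlapping_regions_error(self, genome):
        with pytest.raises(ValueError):
            classify_regions([], genome, [("A", -100, 50), ("B", 0, 100)])

    def test_mixture_proportions_recovered(self, genome, index):
        """A 70/30 mixture of tract classes lands 70/30 in distal vs
        proximal left bands, within three binomial standard errors."""
        import dataclasses
        base = dsbseq.SimulationParams(
            n_cells=1000, depth=50, cut_efficiency=1.0, repair_fraction=1.0,
            repair_time_mean=4.0, repair_time_sd=0.5,
            resynthesis_velocity=8000.0, seed=61)
        mix = [(dataclasses.replace(base, gc_tract_fixed=(-600, 100)), 0.7),
               (dataclasses.replace(base, gc_tract_fixed=(-100, 100), seed=62), 0.3)]
        gc_all = []
        for j, (p, w) in enumerate(mix):
            pop = dsbseq.simulate_population(p, 10, genome)
            n_pairs = int(w * p.depth * 115_000 / 150)
            reads = dsbseq.emit_read_pairs(pop, genome, p, seed=70 + j,
                                           n_pairs=n_pairs)
            mapped, _ = dsbseq.map_pairs(
                ((r.read_id, r.mate1, r.mate2) for r in reads), index)
            gc, _ = extract_discordant(mapped, genome, timepoint=10)
            gc_all.extend(gc)
        regions = [("distal_left", -900, -350), ("proximal_left", -350, -20)]
        out = classify_regions(gc_all, genome, regions)
        n = out["counts"]["distal_left"] + out["counts"]["proximal_left"]
        assert n > 50
        p_hat = out["counts"]["distal_left"] / n
        # the -600 class contributes its left boundary to the distal band and
        # the -100 class its left boundary to the proximal band
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(p_hat - 0.7) < 3 * se + 0.05


class TestBackground:
    def test_zero_without_chimeras(self, wt_run, genome):
        total = sum(c["total_reads"] for c in wt_run["counters"].values())
        _, others = extract_discordant(
            [mp for t in wt_run["mapped"] for mp in wt_run["mapped"][t]], genome)
        assert background_fraction(others, genome, "chrVIII", total) == 0.0

    def test_counts_injected_chimeras(self, genome):
        others = [mp(aln("chrIII", 100), aln("chrVIII", 50, "-"))] * 3
        assert background_fraction(others, genome, "chrVIII", 10**6) == 3e-6
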