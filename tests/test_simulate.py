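"""Population model: resection kinetics, duplex intervals, library bias, qPCR."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import dsbseq
from dsbseq.simulate import MIN_TRACT, dsdna_intervals


def det_params(**kw):
    base = dict(n_cells=200, cut_efficiency=1.0, velocity_shape=None,
                velocity_mean=2000.0, resection_delay=0.0, repair_fraction=0.0,
                seed=3)
    base.update(kw)
    return dsbseq.SimulationParams(**base)


class TestKinetics:
    def test_t0_all_uncut(self, genome):
        pop = dsbseq.simulate_population(dsbseq.SimulationParams(n_cells=100), 0, genome)
        assert not pop.cut.any()
        assert not pop.left_extent.any() and not pop.right_extent.any()

    @pytest.mark.parametrize("t,expect_left,expect_right", [
        (1.0, 2000.0, 2000.0),
        (4.0, 8000.0, 8000.0),
        (20.0, 32000.0, 25000.0),  # capped: left block at 32 kb, right chromosome end
    ])
    def test_deterministic_extents(self, genome, t, expect_left, expect_right):
        pop = dsbseq.simulate_population(det_params(), t, genome)
        assert np.allclose(pop.left_extent, expect_left)
        assert np.allclose(pop.right_extent, expect_right)

    def test_extent_mean_matches_gamma(self, genome):
        p = dsbseq.SimulationParams(n_cells=10_000, cut_efficiency=1.0,
                                    velocity_mean=3000.0, velocity_shape=4.0,
                                    repair_fraction=0.0, seed=5)
        pop = dsbseq.simulate_population(p, 2.0, genome)
        # uncapped regime: mean extent = 2 h * mean velocity
        expect = 2.0 * 3000.0
        se = 2.0 * (3000.0 / np.sqrt(4.0)) / np.sqrt(p.n_cells)
        assert abs(pop.left_extent.mean() - expect) < 3 * se
        assert abs(pop.right_extent.mean() - expect) < 3 * se

    def test_same_seed_coherent_trajectory(self, genome):
        p = dsbseq.SimulationParams(n_cells=500, seed=9)
        a = dsbseq.simulate_population(p, 2, genome)
        b = dsbseq.simulate_population(p, 6, genome)
        assert np.array_equal(a.cut, b.cut)
        assert np.array_equal(a.gc_left, b.gc_left)
        # resection is monotone in time per cell
        assert (b.left_extent >= a.left_extent - 1e-9).all()

    def test_resection_stop_on_repair(self, genome):
        p = dsbseq.SimulationParams(n_cells=2000, repair_fraction=1.0,
                                    repair_time_mean=3.0, repair_time_sd=0.1,
                                    stop_resection_on_repair=True, seed=4)
        early = dsbseq.simulate_population(p, 4, genome)
        late = dsbseq.simulate_population(p, 10, genome)
        assert np.allclose(early.left_extent, late.left_extent)
        nostop = dataclasses.replace(p, stop_resection_on_repair=False)
        late2 = dsbseq.simulate_population(nostop, 10, genome)
        assert late2.left_extent.mean() > late.left_extent.mean()


class TestDuplexIntervals:
    def test_uncut_full_chromosomes(self, genome):
        pop = dsbseq.simulate_population(dsbseq.SimulationParams(n_cells=1), 0, genome)
        ivs = dsdna_intervals(pop.cell(0), genome)
        for chrom, seq in genome.chromosomes.items():
            assert ivs[chrom] == [(0, len(seq))]

    def test_gap_matches_extents(self, genome):
        pop = dsbseq.simulate_population(det_params(velocity_mean=1000.0), 2, genome)
        cell = pop.cell(0)
        ho = genome.ho_site
        ivs = dsdna_intervals(cell, genome)[genome.recipient_name]
        assert ivs == [(0, ho - 2000), (ho + 2000, len(genome.chromosomes["chrIII"]))]

    def test_full_resynthesis_restores_chromosome(self, genome):
        p = dsbseq.SimulationParams(n_cells=50, cut_efficiency=1.0,
                                    repair_fraction=1.0, repair_time_mean=2.0,
                                    repair_time_sd=0.1,
                                    resynthesis_velocity=50_000.0, seed=6)
        pop = dsbseq.simulate_population(p, 10, genome)
        cell = pop.cell(0)
        assert cell.repaired
        ivs = dsdna_intervals(cell, genome)[genome.recipient_name]
        assert ivs == [(0, len(genome.chromosomes["chrIII"]))]


class TestReadEmission:
    def test_truth_interval_always_double_stranded(self, genome):
        p = dsbseq.SimulationParams(n_cells=100, depth=5, repair_fraction=0.5,
                                    repair_time_mean=3.0, seed=8)
        pop = dsbseq.simulate_population(p, 6, genome)
        reads = dsbseq.emit_read_pairs(pop, genome, p, seed=42)
        assert reads
        for r in reads:
            ivs = dsdna_intervals(pop.cell(r.cell), genome)[r.chromosome]
            assert any(s <= r.start and r.start + r.fragment_length <= e
                       for s, e in ivs)

    def test_uncut_population_uniform_coverage(self, genome):
        p = dsbseq.SimulationParams(n_cells=50, depth=30, seed=2)
        pop = dsbseq.simulate_population(p, 0, genome)
        reads = dsbseq.emit_read_pairs(pop, genome, p, seed=3)
        counts = np.zeros(len(genome.chromosomes["chrVIII"]))
        rl = p.read_length
        for r in reads:
            if r.chromosome != "chrVIII":
                continue
            counts[r.start: r.start + rl] += 1
            e = r.start + r.fragment_length
            counts[e - rl: e] += 1
        # chi-square on read starts per 500-nt bin, away from the ends
        inner = counts[1000:-1000]
        bins = inner[: (inner.size // 500) * 500].reshape(-1, 500).sum(axis=1)
        # bases arrive in runs of 75, so variance is ~75x Poisson-of-bases
        chi2 = ((bins - bins.mean()) ** 2 / (bins.mean() * rl)).sum()
        assert stats.chi2.sf(chi2, df=bins.size - 1) > 1e-4

    def test_repaired_fragment_matches_recombinant(self, genome):
        """Reads inside a conversion tract carry the donor haplotype."""
        p = dsbseq.SimulationParams(n_cells=20, depth=40, cut_efficiency=1.0,
                                    repair_fraction=1.0, repair_time_mean=1.0,
                                    repair_time_sd=0.01,
                                    resynthesis_velocity=50_000.0,
                                    gc_tract_fixed=(-600, 100), seed=13)
        pop = dsbseq.simulate_population(p, 8, genome)
        assert pop.repaired.all()
        reads = dsbseq.emit_read_pairs(pop, genome, p, seed=14)
        # hand-built recombinant: recipient with donor alleles in [-600, 100]
        rec = list(genome.chromosomes[genome.recipient_name])
        for s in genome.polymorphisms:
            if -600 <= s.offset_from_ho <= 100:
                rec[s.recipient_pos] = s.donor_allele
        from dsbseq.reference import HO_CUT_INDEX, HO_INC_DIFF_INDEX, HO_INC_MOTIF
        rec[genome.ho_site - HO_CUT_INDEX + HO_INC_DIFF_INDEX] = \
            HO_INC_MOTIF[HO_INC_DIFF_INDEX]
        rec = "".join(rec)
        ho = genome.ho_site
        n_checked = 0
        for r in reads:
            if r.chromosome != genome.recipient_name:
                continue
            if not (ho - 600 <= r.start and r.start + r.fragment_length <= ho + 100):
                continue
            assert r.mate1 == rec[r.start: r.start + 75]
            n_checked += 1
        assert n_checked > 0

    def test_degenerate_population_warns_and_returns_empty(self, genome):
        # a population that is pure ssDNA across every chromosome cannot
        # occur, so emulate by requesting zero pairs after full resection
        p = det_params(n_cells=3, depth=1)
        pop = dsbseq.simulate_population(p, 1, genome)
        out = dsbseq.emit_read_pairs(pop, genome, p, seed=1, n_pairs=0)
        assert out == []


class TestCoverageOracle:
    def test_matches_per_cell_brute_force(self, genome):
        p = dsbseq.SimulationParams(n_cells=60, repair_fraction=0.5,
                                    repair_time_mean=3.0, seed=17)
        pop = dsbseq.simulate_population(p, 5, genome)
        positions = np.arange(genome.ho_site - 20_000, genome.ho_site + 20_000, 997)
        fast = dsbseq.expected_relative_coverage(pop, genome.recipient_name, positions)
        slow = []
        for pos in positions:
            n_ds = 0
            for i in range(pop.n_cells):
                ivs = dsdna_intervals(pop.cell(i), genome)[genome.recipient_name]
                n_ds += any(s <= pos < e for s, e in ivs)
            slow.append(n_ds / pop.n_cells)
        assert np.allclose(fast, slow)

    def test_uncut_is_one(self, genome):
        pop = dsbseq.simulate_population(dsbseq.SimulationParams(n_cells=10), 0, genome)
        assert np.allclose(
            dsbseq.expected_relative_coverage(pop, "chrIII", [0, 10_000]), 1.0)


class TestQpcr:
    def amplicon(self, genome, offset=-1500, length=100):
        return (genome.recipient_name, genome.ho_site + offset,
                genome.ho_site + offset + length)

    def test_all_duplex_is_one(self, genome):
        pop = dsbseq.simulate_population(dsbseq.SimulationParams(n_cells=20), 0, genome)
        assert dsbseq.simulate_qpcr_signal(pop, self.amplicon(genome)) == 1.0

    def test_fully_single_stranded_is_half(self, genome):
        pop = dsbseq.simulate_population(det_params(velocity_mean=4000.0), 2, genome)
        assert dsbseq.simulate_qpcr_signal(pop, self.amplicon(genome)) == 0.5

    def test_half_duplex_half_degraded(self, genome):
        p = det_params(n_cells=1000, velocity_mean=4000.0, ssdna_degradation=1.0,
                       cut_efficiency=0.5)
        pop = dsbseq.simulate_population(p, 2, genome)
        sig = dsbseq.simulate_qpcr_signal(pop, self.amplicon(genome))
        frac_cut = pop.cut.mean()
        assert sig == pytest.approx(1.0 - frac_cut, abs=1e-9)
        assert sig == pytest.approx(0.5, abs=0.06)

    def test_degradation_only_decreases_signal(self, genome):
        base = dsbseq.SimulationParams(n_cells=800, seed=23)
        degr = dataclasses.replace(base, ssdna_degradation=0.7)
        amp = self.amplicon(genome)
        for t in (1, 3, 6):
            s0 = dsbseq.simulate_qpcr_signal(dsbseq.simulate_population(base, t, genome), amp)
            s1 = dsbseq.simulate_qpcr_signal(dsbseq.simulate_population(degr, t, genome), amp)
            assert s1 <= s0 + 1e-12
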