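"""Coverage stacking, RPGC scaling, T0 masking, ratio and section profiles."""

import numpy as np
import pytest

import dsbseq
from dsbseq.coverage import (CoverageTrack, colormap_matrix, per_base_coverage,
                             ratio_profile, rpgc_scale, section_normalize,
                             t0_mask)


def aln(chrom, start, length=75, n_hits=1):
    return dsbseq.AlignmentRecord("r", chrom, start, length, "+", n_hits)


def track(scaled=False, **arrays):
    return CoverageTrack({c: np.asarray(v, dtype=float) for c, v in arrays.items()},
                         scaled=scaled)


class TestPerBase:
    def test_single_read(self):
        t = per_base_coverage([aln("c", 10)], {"c": 200})
        assert t.counts["c"][10:85].sum() == 75
        assert t.counts["c"].sum() == 75

    def test_overlapping_reads_stack(self):
        t = per_base_coverage([aln("c", 10), aln("c", 10)], {"c": 200})
        assert (t.counts["c"][10:85] == 2).all()

    def test_non_unique_dropped(self):
        t = per_base_coverage([aln("c", 10, n_hits=3)], {"c": 200})
        assert t.counts["c"].sum() == 0

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            per_base_coverage([aln("c", 150)], {"c": 200})

    def test_simulated_depth(self, genome, index):
        p = dsbseq.SimulationParams(n_cells=30, depth=20, seed=41)
        pop = dsbseq.simulate_population(p, 0, genome)
        reads = dsbseq.emit_read_pairs(pop, genome, p, seed=42)
        mapped, _ = dsbseq.map_pairs(((r.read_id, r.mate1, r.mate2) for r in reads),
                                     index)
        t = per_base_coverage([a for mp in mapped for a in (mp.aln1, mp.aln2)],
                              genome.chromosome_lengths)
        # binomial-scale agreement with the configured depth
        assert t.genome_mean() == pytest.approx(20, rel=0.02)


class TestScaling:
    def test_constant_becomes_one(self):
        s = rpgc_scale(track(c=np.full(100, 10.0)))
        assert np.allclose(s.counts["c"], 1.0)
        assert s.scaled

    def test_mean_is_one(self):
        rng = np.random.default_rng(1)
        s = rpgc_scale(track(a=rng.poisson(30, 500), b=rng.poisson(5, 300)))
        total = np.concatenate(list(s.counts.values()))
        assert total.mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_coverage_error(self):
        with pytest.raises(ValueError):
            rpgc_scale(track(c=np.zeros(10)))

    def test_double_scaling_error(self):
        with pytest.raises(ValueError):
            rpgc_scale(rpgc_scale(track(c=np.ones(10))))


class TestMask:
    def test_threshold(self):
        t0 = track(scaled=True, c=[1.0, 0.1, 0.19, 0.2, 0.5])
        m = t0_mask(t0, 0.2)
        assert m["c"].tolist() == [False, True, True, False, False]

    def test_fraction_matches_brute_force(self):
        rng = np.random.default_rng(2)
        v = rng.exponential(1.0, 2000)
        m = t0_mask(track(scaled=True, c=v), 0.2)
        assert m["c"].sum() == (v < 0.2).sum()


class TestRatioProfile:
    def test_identical_tracks_all_ones(self):
        t0 = rpgc_scale(track(c=np.full(1000, 8.0)))
        prof = ratio_profile(t0, t0, t0_mask(t0, 0.2), bin_size=100)["c"]
        assert np.allclose(prof.values, 1.0)

    def test_halved_coverage(self):
        base = np.full(1000, 8.0)
        t0 = CoverageTrack({"c": np.ones(1000)}, scaled=True)
        tx = CoverageTrack({"c": np.full(1000, 0.5)}, scaled=True)
        prof = ratio_profile(tx, t0, {"c": np.zeros(1000, bool)})["c"]
        assert np.allclose(prof.values, 0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        raw0 = rng.poisson(40, 2000).astype(float) + 1
        rawx = rng.poisson(25, 2000).astype(float) + 1
        def prof(a, b):
            s0, sx = rpgc_scale(track(c=a)), rpgc_scale(track(c=b))
            return ratio_profile(sx, s0, t0_mask(s0, 0.2))["c"].values
        assert np.allclose(prof(raw0, rawx), prof(raw0 * 7.3, rawx * 0.21))

    def test_anchor_splits_at_cut(self):
        t0 = CoverageTrack({"c": np.ones(1000)}, scaled=True)
        prof = ratio_profile(t0, t0, {"c": np.zeros(1000, bool)}, anchor=250)["c"]
        assert 250 in prof.starts
        left_d, _ = prof.side_values(250, "left")
        right_d, _ = prof.side_values(250, "right")
        assert left_d[0] == right_d[0] == 50.0

    def test_masked_bin_is_nan(self):
        t0 = CoverageTrack({"c": np.ones(500)}, scaled=True)
        mask = {"c": np.zeros(500, bool)}
        mask["c"][200:300] = True
        prof = ratio_profile(t0, t0, mask)["c"]
        assert np.isnan(prof.values[2])
        assert np.isfinite(prof.values[[0, 1, 3, 4]]).all()


class TestSections:
    def two_chrom_tracks(self, factor_ctrl=1.0, factor_rest=1.0):
        t0 = CoverageTrack({"III": np.ones(8000), "V": np.ones(8000)}, scaled=True)
        tx = CoverageTrack({"III": np.full(8000, factor_rest),
                            "V": np.full(8000, factor_rest)}, scaled=True)
        tx.counts["V"][4000:8000] = factor_ctrl
        return tx, t0

    def test_identity(self):
        tx, t0 = self.two_chrom_tracks()
        sp = section_normalize(tx, t0, ("V", 4000, 8000))
        for chrom, (_, cn) in sp.sections.items():
            assert np.allclose(cn, 1.0)

    def test_control_doubled_halves_everything_else(self):
        tx, t0 = self.two_chrom_tracks(factor_ctrl=2.0, factor_rest=1.0)
        sp = section_normalize(tx, t0, ("V", 4000, 8000))
        assert np.allclose(sp.sections["III"][1], 0.5)
        assert sp.control_factor == pytest.approx(2.0)

    def test_control_region_is_one_by_construction(self, wt_run, genome):
        an = wt_run["analysis"]
        for t, tr in wt_run["scaled"].items():
            sp = section_normalize(tr, wt_run["scaled"][0], genome.control_region,
                                   an.section_size, mask=wt_run["mask"], timepoint=t)
            c, s, e = genome.control_region
            starts, cn = sp.sections[c]
            inside = (starts >= s) & (starts + an.section_size <= e)
            assert np.nanmean(cn[inside]) == pytest.approx(1.0, abs=0.05)

    def test_zero_t0_control_error(self):
        tx, t0 = self.two_chrom_tracks()
        t0.counts["V"][4000:8000] = 0.0
        with pytest.raises(ValueError):
            section_normalize(tx, t0, ("V", 4000, 8000))


class TestColormap:
    def test_matrix_mirrors_profiles(self):
        tx, t0 = TestSections().two_chrom_tracks()
        rows = [section_normalize(tx, t0, ("V", 4000, 8000), timepoint=t)
                for t in (0, 2, 4)]
        times, starts, m = colormap_matrix(rows, "III")
        assert m.shape == (3, starts.size)
        assert np.allclose(m[0], rows[0].sections["III"][1])
        assert times.tolist() == [0, 2, 4]
        assert np.allclose(m, 1.0)

    def test_resection_minima_decrease_over_time(self, wt_run, genome):
        an = wt_run["analysis"]
        sps = [section_normalize(tr, wt_run["scaled"][0], genome.control_region,
                                 an.section_size, mask=wt_run["mask"], timepoint=t)
               for t, tr in wt_run["scaled"].items() if t <= 4]
        _, starts, m = colormap_matrix(sps, genome.recipient_name)
        near = np.abs(starts + an.section_size / 2 - genome.ho_site) < 8000
        minima = np.nanmin(m[:, near], axis=1)
        assert (np.diff(minima) < 0.15).all()  # monotone decay up to noise
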