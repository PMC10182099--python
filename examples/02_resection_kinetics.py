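"""Measure end-resection kinetics from simulated sequencing coverage.

Simulates a cell population after HO induction (resection at a mean 4 kb/h
per side), emits a tagmentation library in which single-stranded DNA yields
no fragments, maps the reads with the 0-mismatch mapper, and reads the
resection front off the T0-normalised coverage profiles: the distance where
coverage recovers through 0.5, regressed against time over 1-4 h, is the
long-range resection rate R.
"""

import dsbseq
from dsbseq import coverage as cov
from dsbseq import metrics

genome = dsbseq.build_reference(seed=1)
index = dsbseq.ExactMatchIndex(genome, k=75)
params = dsbseq.SimulationParams(n_cells=1000, depth=30, seed=7)
analysis = cov.AnalysisConfig()

tracks = {}
for i, t in enumerate((0, 1, 2, 3, 4)):
    pop = dsbseq.simulate_population(params, t, genome)
    reads = dsbseq.emit_read_pairs(pop, genome, params, seed=100 + i)
    mapped, counters = dsbseq.map_pairs(
        ((r.read_id, r.mate1, r.mate2) for r in reads), index)
    alns = [a for mp in mapped for a in (mp.aln1, mp.aln2)]
    tracks[t] = cov.per_base_coverage(alns, genome.chromosome_lengths)
    print(f"t={t} h: {counters['mapped']} reads mapped")

scaled = {t: cov.rpgc_scale(tr) for t, tr in tracks.items()}
mask = cov.t0_mask(scaled[0], analysis.t0_threshold)
profiles = metrics.break_profiles(scaled, scaled[0], mask, genome.recipient_name,
                                  genome.ho_site, analysis,
                                  control_region=genome.control_region)

sr = metrics.short_range_resection(profiles[1], genome.ho_site)
print(f"\nshort-range decline at 1 h: left {sr['left']['decline']:.2f}, "
      f"right {sr['right']['decline']:.2f} (asymmetry {sr['asymmetry']:.2f})")

for side, bound in (("left", 32_000.0), ("right", 25_000.0)):
    for t in (1, 2, 3, 4):
        c = metrics.distance_at_level(profiles[t], genome.ho_site, side,
                                      censor_bound=bound)
        print(f"  {side} 0.5-coverage distance at {t} h: {c.distance / 1000:.1f} kb")
    fit = metrics.long_range_rate(profiles, genome.ho_site, side, censor_bound=bound)
    print(f"long-range resection rate R ({side}): {fit.rate / 1000:.2f} kb/h")
print("\n(per-cell velocities are gamma-distributed with mean 4 kb/h; the")
print(" 0.5-crossing tracks the population median, and the two sides draw")
print(" independent velocities, so per-side R scatters around ~3.7 kb/h)")
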