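"""DNA re-synthesis rates and the ssDNA qPCR expectation.

After repair, duplex DNA is restored from the break outward and sequencing
coverage recovers.  The coverage-vs-time trend at 0.5 kb from the cut gives
the synthesis rate S (slope) and the re-synthesis initiation rate
v = 0.5 kb / Δt, where Δt is the time the trend line needs to climb from
coverage 0 to 0.5.  The same population model predicts quantitative PCR:
a resected (single-stranded) amplicon retains one template strand, i.e. 50%
signal, and less if the ssDNA is degraded.
"""

import dsbseq
from dsbseq import coverage as cov
from dsbseq import metrics

genome = dsbseq.build_reference(seed=1)
index = dsbseq.ExactMatchIndex(genome, k=75)
params = dsbseq.SimulationParams(n_cells=1000, depth=30, seed=7)
analysis = cov.AnalysisConfig()

times = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
tracks, pops = {}, {}
for i, t in enumerate(times):
    pop = dsbseq.simulate_population(params, t, genome)
    reads = dsbseq.emit_read_pairs(pop, genome, params, seed=200 + i)
    mapped, _ = dsbseq.map_pairs(((r.read_id, r.mate1, r.mate2) for r in reads),
                                 index)
    alns = [a for mp in mapped for a in (mp.aln1, mp.aln2)]
    tracks[t] = cov.per_base_coverage(alns, genome.chromosome_lengths)
    pops[t] = pop

scaled = {t: cov.rpgc_scale(tr) for t, tr in tracks.items()}
mask = cov.t0_mask(scaled[0], analysis.t0_threshold)
profiles = metrics.break_profiles(scaled, scaled[0], mask, genome.recipient_name,
                                  genome.ho_site, analysis,
                                  control_region=genome.control_region)

for side in ("left", "right"):
    ts, vals = metrics.coverage_time_series(profiles, genome.ho_site, 500, side)
    series = ", ".join(f"{t}h:{v:.2f}" for t, v in zip(ts, vals) if t >= 4)
    trend = metrics.synthesis_rate(ts, vals, analysis.synthesis_interval)
    v = metrics.initiation_rate(trend)
    print(f"{side} @0.5 kb: {series}")
    print(f"  synthesis rate S = {trend.slope:.3f}/h, initiation rate v = {v:.2f} kb/h")

print("\nqPCR at -1.5 kb from the cut (normalised to T0):")
amplicon = (genome.recipient_name, genome.ho_site - 1550, genome.ho_site - 1450)
for t in (0, 2, 4, 6, 8, 10):
    sig = dsbseq.simulate_qpcr_signal(pops[t], amplicon)
    print(f"  t={t:>2} h: {100 * sig:.0f}%")
print("(the floor near 50% is the ssDNA expectation: one strand resected,")
print(" one template strand left; values below 50% would indicate ssDNA")
print(" degradation, reproducible with ssdna_degradation > 0)")
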