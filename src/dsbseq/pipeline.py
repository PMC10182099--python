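"""End-to-end orchestration: reference -> simulate -> map -> normalise -> reports.

Every stage writes its artifacts (FASTA, FASTQ, SAM, BedGraph, TSV, JSON)
under the run's output directory and hands its in-memory products to the
next stage.  A run is deterministic for a given (config, seed): sub-seeds
for the population and each time point's library are spawned from the master
seed, and the seed is recorded in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import coverage as cov
from . import discordant as disc
from . import geneconv, metrics
from .io import read_sam, write_bedgraph, write_fastq_pairs, write_sam
from .mapping import ExactMatchIndex, map_pairs
from .reference import GenomeConfig, GenomeMap, build_reference, read_reference, write_reference
from .simulate import SimulationParams, emit_read_pairs, simulate_population

__all__ = ["RunConfig", "run_pipeline", "ingest_external", "ALL_STAGES"]

log = logging.getLogger("dsbseq")

ALL_STAGES = ("reference", "simulate", "map", "coverage", "resection",
              "synthesis", "gc", "discordant")


@dataclass
class RunConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    sim: SimulationParams = field(default_factory=SimulationParams)
    analysis: cov.AnalysisConfig = field(default_factory=cov.AnalysisConfig)
    outdir: str | Path = "dsbseq_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    write_fastq: bool = True

    def validate(self):
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")


def _sub_seed(seed: int, *path: int) -> int:
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0] % (2**31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, np.integer):
        return int(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _left_censor(genome: GenomeMap) -> float | None:
    ho = genome.ho_site
    lefts = [ho - pos for c, pos, _ in genome.block_elements
             if c == genome.recipient_name and pos < ho]
    return float(min(lefts)) if lefts else None


def _censor(genome: GenomeMap, side: str) -> float | None:
    if side == "left":
        return _left_censor(genome)
    return float(len(genome.chromosomes[genome.recipient_name]) - genome.ho_site)


def _coverage_stage(tracks_by_time, genome, analysis, outdir=None):
    """Scale tracks, derive the T0 mask and all normalised profiles."""
    if 0 not in tracks_by_time and 0.0 not in tracks_by_time:
        raise ValueError("stage 'coverage' needs a 0 h sample for normalisation")
    scaled = {t: cov.rpgc_scale(tr) for t, tr in tracks_by_time.items()}
    t0 = scaled[min(scaled)]
    mask = cov.t0_mask(t0, analysis.t0_threshold)
    control = genome.control_region or analysis.control_region
    profiles = metrics.break_profiles(
        scaled, t0, mask, genome.recipient_name, genome.ho_site, analysis,
        control_region=control,
    )
    sections = {
        t: cov.section_normalize(tr, t0, control, analysis.section_size,
                                 mask=mask, timepoint=t)
        for t, tr in scaled.items()
    }
    if outdir is not None:
        for t, tr in scaled.items():
            write_bedgraph(tr.counts, outdir / f"coverage_t{t}.bedgraph")
        times, starts, matrix = cov.colormap_matrix(
            list(sections.values()), genome.recipient_name
        )
        header = "time\t" + "\t".join(str(s) for s in starts)
        rows = [header] + [
            "\t".join([str(t)] + [f"{v:.4g}" for v in row]) for t, row in zip(times, matrix)
        ]
        (outdir / "colormap_recipient.tsv").write_text("\n".join(rows) + "\n")
    return scaled, t0, mask, profiles, sections


def _resection_stage(scaled, mask, profiles, genome, analysis):
    ho = genome.ho_site
    report = {"short_range": None, "half_distance": {}, "rate": {}, "max_extent": {}}
    if 1 in profiles or 1.0 in profiles:
        report["short_range"] = metrics.short_range_resection(
            profiles[1], ho, window=analysis.short_range_window
        )
    for side in ("left", "right"):
        bound = _censor(genome, side)
        report["half_distance"][side] = {
            t: metrics.distance_at_level(
                p, ho, side, level=analysis.half_coverage_level,
                smooth=analysis.smoothing_bins, censor_bound=bound)
            for t, p in profiles.items() if t > 0
        }
        try:
            report["rate"][side] = metrics.long_range_rate(
                profiles, ho, side, level=analysis.half_coverage_level,
                interval=analysis.resection_interval,
                smooth=analysis.smoothing_bins, censor_bound=bound)
        except ValueError as exc:
            report["rate"][side] = None
            log.warning("long-range rate (%s): %s", side, exc)
        report["max_extent"][side] = {
            t: metrics.max_resection_extent(
                tr, mask, genome.recipient_name, ho, side,
                cutoff=analysis.max_extent_cutoff, bin_size=analysis.bin_size,
                smooth=analysis.smoothing_bins, censor_bound=bound)
            for t, tr in scaled.items() if t > 0
        }
    return report


def _synthesis_stage(profiles, genome, analysis):
    ho = genome.ho_site
    report = {"series": {}, "trend": {}, "rate": {}, "initiation_rate": {}}
    for distance in analysis.synthesis_distances:
        for side in ("left", "right"):
            key = f"{side}_{distance}"
            try:
                times, values = metrics.coverage_time_series(profiles, ho, distance, side)
            except ValueError as exc:
                log.warning("synthesis series %s: %s", key, exc)
                continue
            report["series"][key] = {"times": times, "values": values}
            try:
                trend = metrics.synthesis_rate(times, values, analysis.synthesis_interval)
            except ValueError:
                continue
            report["trend"][key] = trend
            report["rate"][key] = trend.slope
            if distance == 500:
                report["initiation_rate"][side] = metrics.initiation_rate(trend)
    return report


def _discordant_stage(mapped_by_time, genome, analysis, counters_by_time,
                      outdir=None):
    all_pairs, all_others = [], []
    fraction_by_time = {}
    for t, mapped in sorted(mapped_by_time.items()):
        pairs, others = disc.extract_discordant(
            mapped, genome, timepoint=t, read_length=analysis.read_length
        )
        total = counters_by_time[t]["total_reads"]
        fraction_by_time[t] = disc.discordant_fraction(len(pairs), total)
        all_pairs.extend(pairs)
        all_others.extend(others)
    quad = {}
    for p in all_pairs:
        q = disc.classify_quadrant(p, genome.ho_site, genome.ho_inc_site)
        quad[q] = quad.get(q, 0) + 1
    offsets, rec_tr, don_tr, n_excluded = disc.discordant_coverage(all_pairs, genome)
    boundaries = {
        "left": disc.boundary_estimate(offsets, rec_tr, don_tr, (-1300, -50)),
        "right": disc.boundary_estimate(offsets, rec_tr, don_tr, (50, 1300)),
    }
    regions = disc.default_regions(offsets, rec_tr, don_tr)
    region_report = disc.classify_regions(all_pairs, genome, regions)
    control = next(
        (c for c in genome.chromosomes
         if c not in (genome.recipient_name, genome.donor_name)), None)
    total_reads = sum(c["total_reads"] for c in counters_by_time.values())
    background = (
        disc.background_fraction(all_others, genome, control, total_reads)
        if control else None
    )
    if outdir is not None:
        rows = ["recipient_coord\tdonor_coord\tquadrant\ttimepoint"]
        for p in all_pairs:
            q = disc.classify_quadrant(p, genome.ho_site, genome.ho_inc_site)
            rows.append(f"{p.recipient_coord}\t{p.donor_coord}\t{q}\t{p.timepoint}")
        (outdir / "discordant_pairs.tsv").write_text("\n".join(rows) + "\n")
        write_bedgraph({"frame_recipient": rec_tr}, outdir / "discordant_recipient.bedgraph")
        write_bedgraph({"frame_donor": don_tr}, outdir / "discordant_donor.bedgraph")
    return disc.DiscordantReport(
        fraction_by_time=fraction_by_time,
        quadrant_counts=quad,
        regions=region_report,
        boundaries=boundaries,
        background=background,
        n_pairs=len(all_pairs),
    ), n_excluded


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the report dict (also written to
    ``report.json``).  Later stages require the products of earlier ones and
    fail with the missing stage's name otherwise."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages),
                    "params": {"sim": dataclasses.asdict(config.sim),
                               "genome": dataclasses.asdict(config.genome)}}
    stages = set(config.stages)
    genome = None
    reads_by_time: dict = {}
    mapped_by_time: dict = {}
    counters_by_time: dict = {}
    tracks_by_time: dict = {}

    def require(stage, product, what):
        if product is None or product == {}:
            raise RuntimeError(f"stage '{stage}' requires output of stage '{what}'")

    if "reference" in stages:
        genome = build_reference(config.genome, seed=_sub_seed(config.seed, 1))
        write_reference(genome, outdir / "reference.fasta", outdir / "sites.tsv")
        report["reference"] = {
            "n_polymorphisms": len(genome.polymorphisms),
            "donor_region_length": genome.donor_region[2] - genome.donor_region[1],
        }

    if "simulate" in stages:
        require("simulate", genome, "reference")
        sim = replace(config.sim, seed=_sub_seed(config.seed, 2))
        truth_rows = ["timepoint\tcell\tcut\tleft_extent\tright_extent\t"
                      "resynth_left\tresynth_right\trepaired\tgc_left\tgc_right"]
        for i, t in enumerate(sim.timepoints):
            pop = simulate_population(sim, t, genome)
            reads = emit_read_pairs(pop, genome, sim, seed=_sub_seed(config.seed, 3, i))
            reads_by_time[t] = reads
            for c in range(pop.n_cells):
                s = pop.cell(c)
                truth_rows.append(
                    f"{t}\t{c}\t{int(s.cut)}\t{s.left_extent:.0f}\t{s.right_extent:.0f}"
                    f"\t{s.resynth_left:.0f}\t{s.resynth_right:.0f}\t{int(s.repaired)}"
                    f"\t{s.gc_left_boundary}\t{s.gc_right_boundary}"
                )
            if config.write_fastq:
                write_fastq_pairs(reads, outdir / f"reads_t{t}_R1.fastq",
                                  outdir / f"reads_t{t}_R2.fastq")
        (outdir / "truth.tsv").write_text("\n".join(truth_rows) + "\n")
        report["simulate"] = {t: len(r) for t, r in reads_by_time.items()}

    if "map" in stages:
        require("map", reads_by_time or None, "simulate")
        index = ExactMatchIndex(genome, k=config.sim.read_length)
        for t, reads in reads_by_time.items():
            mapped, counters = map_pairs(
                ((r.read_id, r.mate1, r.mate2) for r in reads), index,
                insert_bounds=config.analysis.insert_bounds)
            mapped_by_time[t] = mapped
            counters_by_time[t] = counters
            write_sam(mapped, genome.chromosome_lengths, outdir / f"aligned_t{t}.sam")
            log.info("t=%s: %s", t, counters)
        report["map"] = counters_by_time

    if "coverage" in stages:
        require("coverage", mapped_by_time or None, "map")
        for t, mapped in mapped_by_time.items():
            alns = [a for mp in mapped for a in (mp.aln1, mp.aln2)]
            tracks_by_time[t] = cov.per_base_coverage(alns, genome.chromosome_lengths)
        scaled, t0, mask, profiles, sections = _coverage_stage(
            tracks_by_time, genome, config.analysis, outdir)
        report["coverage"] = {
            "masked_fraction": {c: float(m.mean()) for c, m in mask.items()},
            "control_factor": {t: s.control_factor for t, s in sections.items()},
        }

        if "resection" in stages:
            report["resection"] = _resection_stage(scaled, mask, profiles, genome,
                                                   config.analysis)
        if "synthesis" in stages:
            report["synthesis"] = _synthesis_stage(profiles, genome, config.analysis)
        if "gc" in stages:
            t_final = max(tracks_by_time)
            gcr = geneconv.gc_report(scaled[t_final], t0, genome, profiles)
            gcr.sites.to_csv(outdir / "gc_sites.tsv", sep="\t", index=False)
            report["gc"] = {
                "correction_factor": gcr.correction_factor,
                "sites": gcr.sites.to_dict(orient="list"),
            }
        if "discordant" in stages:
            dreport, n_excl = _discordant_stage(
                mapped_by_time, genome, config.analysis, counters_by_time, outdir)
            report["discordant"] = dataclasses.asdict(dreport)
            report["discordant"]["frame_excluded"] = n_excl
    else:
        for s in ("resection", "synthesis", "gc", "discordant"):
            if s in stages:
                raise RuntimeError(f"stage '{s}' requires output of stage 'coverage'")

    report = _jsonable(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def ingest_external(sam_by_time: dict, fasta_path, sites_path, outdir,
                    analysis: cov.AnalysisConfig | None = None) -> dict:
    """Run the pipeline from user-supplied alignments (SAM) onward.

    ``sam_by_time`` maps hours to SAM paths.  Reads whose length differs
    from the configured read length are rejected and counted.  The reference
    FASTA and its site annotation define the genome frame.
    """
    analysis = analysis or cov.AnalysisConfig()
    genome = read_reference(fasta_path, sites_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mapped_by_time, counters_by_time, tracks_by_time = {}, {}, {}
    for t, path in sam_by_time.items():
        mapped, _lengths = read_sam(path)
        rejected = 0
        kept = []
        for mp in mapped:
            ok = all(a is None or a.length == analysis.read_length
                     for a in (mp.aln1, mp.aln2))
            if ok:
                kept.append(mp)
            else:
                rejected += 1
        if rejected:
            log.warning("t=%s: rejected %d pairs with read length != %d",
                        t, rejected, analysis.read_length)
        mapped_by_time[t] = kept
        counters_by_time[t] = {
            "total_reads": 2 * len(mapped), "rejected_pairs": rejected}
        alns = [a for mp in kept for a in (mp.aln1, mp.aln2)]
        tracks_by_time[t] = cov.per_base_coverage(alns, genome.chromosome_lengths)
    scaled, t0, mask, profiles, sections = _coverage_stage(
        tracks_by_time, genome, analysis, outdir)
    report = {
        "coverage": {
            "masked_fraction": {c: float(m.mean()) for c, m in mask.items()},
            "control_factor": {t: s.control_factor for t, s in sections.items()},
        },
        "resection": _resection_stage(scaled, mask, profiles, genome, analysis),
        "synthesis": _synthesis_stage(profiles, genome, analysis),
    }
    t_final = max(tracks_by_time)
    gcr = geneconv.gc_report(scaled[t_final], t0, genome, profiles)
    report["gc"] = {"correction_factor": gcr.correction_factor,
                    "sites": gcr.sites.to_dict(orient="list")}
    dreport, n_excl = _discordant_stage(mapped_by_time, genome, analysis,
                                        counters_by_time, outdir)
    report["discordant"] = dataclasses.asdict(dreport)
    report = _jsonable(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
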