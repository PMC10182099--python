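"""Cell-population simulator of HO cutting, resection, repair and re-synthesis.

The model behind every estimator in this package:

* At induction (t = 0) each cell is cut with probability ``cut_efficiency``.
* Each cut cell resects bidirectionally 5'->3' at a per-cell, per-side
  velocity drawn once from a gamma distribution, after an optional delay.
  Left-ward resection halts at a blocking element (LTR analogue); right-ward
  resection is capped by the chromosome end.
* A fraction of cells (``repair_fraction``) repairs the break at a per-cell
  repair time.  A repaired cell carries a gene-conversion tract around the
  cut: donor polymorphisms (and the uncleavable HO-inc core) replace the
  recipient sequence between the tract boundaries.  If
  ``stop_resection_on_repair`` (wild-type behaviour) resection halts at the
  repair time; otherwise it continues, emulating a cdc14-deficient mutant.
  After repair, duplex DNA is restored from the break outward at
  ``resynthesis_velocity``.
* Sequencing emulates a tagmentation library: only fragments that lie
  entirely in double-stranded DNA are sampled, so resected (single-stranded)
  regions lose coverage.  Reads are error-free 75-mers; mate 2 is
  reverse-complemented.

Per-cell latent variables are drawn once from the master seed, so states
queried at different time points describe the same population trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .reference import GenomeMap, revcomp

__all__ = [
    "SimulationParams",
    "CellState",
    "PopulationState",
    "ReadPairRecord",
    "simulate_population",
    "dsdna_intervals",
    "emit_read_pairs",
    "expected_relative_coverage",
    "simulate_qpcr_signal",
    "wildtype_params",
    "cdc14_like_params",
]

MIN_TRACT = 12  # nt; a conversion tract always spans the HO core it replaces


@dataclass
class SimulationParams:
    """Population and library parameters.

    Velocities are nt/h.  ``velocity_shape`` is the gamma shape of the
    across-cell velocity distribution (None = identical velocity in every
    cell).  ``gc_tract_left/right`` are the means of the exponential tract
    half-lengths beyond the 12-nt HO core.  ``depth`` is the mean sequenced
    per-base coverage of an undamaged sample.
    """

    n_cells: int = 2000
    timepoints: tuple = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    cut_efficiency: float = 0.98
    resection_delay: float = 0.0
    velocity_mean: float = 4000.0
    velocity_shape: float | None = 4.0
    repair_fraction: float = 0.8
    repair_time_mean: float = 6.0
    repair_time_sd: float = 1.0
    stop_resection_on_repair: bool = True
    gc_tract_left: float = 400.0
    gc_tract_right: float = 150.0
    # degenerate tract (left_offset, right_offset) overriding the random
    # tract distributions, e.g. (-600, 100); None = draw per cell
    gc_tract_fixed: tuple | None = None
    resynthesis_velocity: float = 4000.0
    ssdna_degradation: float = 0.0
    read_length: int = 75
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    depth: float = 30.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.cut_efficiency, self.repair_fraction, self.ssdna_degradation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.velocity_mean, self.resynthesis_velocity) < 0:
            raise ValueError("velocities must be non-negative")
        if self.read_length > self.insert_mean:
            raise ValueError("read length exceeds the mean insert size")


def wildtype_params(**overrides) -> SimulationParams:
    """Repair-proficient scenario: most cells repair and resection stops."""
    return replace(SimulationParams(), **overrides)


def cdc14_like_params(**overrides) -> SimulationParams:
    """Repair-compromised scenario: few repairing cells, resection never
    stops, re-synthesis slow — emulating loss of Cdc14 phosphatase."""
    base = SimulationParams(
        repair_fraction=0.26,
        stop_resection_on_repair=False,
        repair_time_mean=8.0,
        resynthesis_velocity=1500.0,
        ssdna_degradation=0.3,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class CellState:
    cut: bool
    left_extent: float
    right_extent: float
    resynth_left: float
    resynth_right: float
    repaired: bool
    gc_left_boundary: int | None  # signed nt offset from the HO cut
    gc_right_boundary: int | None
    degraded: bool = False


@dataclass
class PopulationState:
    """Vectorised per-cell state of the population at one time point."""

    t: float
    genome: GenomeMap
    cut: np.ndarray
    left_extent: np.ndarray
    right_extent: np.ndarray
    resynth_left: np.ndarray
    resynth_right: np.ndarray
    repaired: np.ndarray
    gc_left: np.ndarray  # signed offsets; meaningful only where repaired
    gc_right: np.ndarray
    degraded: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.cut.size

    def cell(self, i: int) -> CellState:
        rep = bool(self.repaired[i])
        return CellState(
            cut=bool(self.cut[i]),
            left_extent=float(self.left_extent[i]),
            right_extent=float(self.right_extent[i]),
            resynth_left=float(self.resynth_left[i]),
            resynth_right=float(self.resynth_right[i]),
            repaired=rep,
            gc_left_boundary=int(self.gc_left[i]) if rep else None,
            gc_right_boundary=int(self.gc_right[i]) if rep else None,
            degraded=bool(self.degraded[i]),
        )

    def cells(self):
        return (self.cell(i) for i in range(self.n_cells))


def _latents(params: SimulationParams, genome: GenomeMap):
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xCE11]))
    n = params.n_cells
    cut = rng.random(n) < params.cut_efficiency
    if params.velocity_shape is None:
        v_left = np.full(n, params.velocity_mean)
        v_right = np.full(n, params.velocity_mean)
    else:
        k = params.velocity_shape
        v_left = rng.gamma(k, params.velocity_mean / k, size=n)
        v_right = rng.gamma(k, params.velocity_mean / k, size=n)
    repairs = rng.random(n) < params.repair_fraction
    repair_time = np.clip(
        rng.normal(params.repair_time_mean, params.repair_time_sd, size=n), 0.5, None
    )
    if params.gc_tract_fixed is not None:
        gl, gr = params.gc_tract_fixed
        if not gl <= -MIN_TRACT <= MIN_TRACT <= gr:
            raise ValueError(f"fixed tract must span the {MIN_TRACT}-nt HO core")
        gc_left = np.full(n, int(gl))
        gc_right = np.full(n, int(gr))
    else:
        gc_left = -(MIN_TRACT + rng.exponential(params.gc_tract_left, size=n)).astype(int)
        gc_right = (MIN_TRACT + rng.exponential(params.gc_tract_right, size=n)).astype(int)
    degraded = rng.random(n) < params.ssdna_degradation
    return cut, v_left, v_right, repairs, repair_time, gc_left, gc_right, degraded


def simulate_population(params: SimulationParams, t: float, genome: GenomeMap,
                        seed: int | None = None) -> PopulationState:
    """State of the population ``t`` hours after HO induction.

    Latents are a deterministic function of the seed, so calling with several
    values of ``t`` yields a consistent time course for the same cells.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if seed is not None:
        params = replace(params, seed=seed)
    cut, v_left, v_right, repairs, repair_time, gc_left, gc_right, degraded = _latents(
        params, genome
    )
    n = params.n_cells
    ho = genome.ho_site
    rec_len = len(genome.chromosomes[genome.recipient_name])
    blocks_left = [ho - pos for c, pos, _ in genome.block_elements
                   if c == genome.recipient_name and pos < ho]
    left_cap = min(blocks_left) if blocks_left else ho
    left_cap = min(left_cap, ho)

    if t == 0:
        zeros = np.zeros(n)
        return PopulationState(
            t=0.0, genome=genome, cut=np.zeros(n, dtype=bool),
            left_extent=zeros.copy(), right_extent=zeros.copy(),
            resynth_left=zeros.copy(), resynth_right=zeros.copy(),
            repaired=np.zeros(n, dtype=bool), gc_left=gc_left, gc_right=gc_right,
            degraded=degraded,
        )

    # resection stops at repair time for repair-proficient kinetics
    t_stop = np.where(repairs & np.full(n, params.stop_resection_on_repair),
                      repair_time, np.inf)
    t_res = np.clip(np.minimum(t, t_stop) - params.resection_delay, 0.0, None)
    left = np.where(cut, np.minimum(v_left * t_res, left_cap), 0.0)
    right = np.where(cut, np.minimum(v_right * t_res, rec_len - ho), 0.0)

    repaired_now = cut & repairs & (t >= repair_time)
    dt_rep = np.clip(t - repair_time, 0.0, None)
    resynth_l = np.where(repaired_now, np.minimum(left, params.resynthesis_velocity * dt_rep), 0.0)
    resynth_r = np.where(repaired_now, np.minimum(right, params.resynthesis_velocity * dt_rep), 0.0)

    return PopulationState(
        t=float(t), genome=genome, cut=cut, left_extent=left, right_extent=right,
        resynth_left=resynth_l, resynth_right=resynth_r, repaired=repaired_now,
        gc_left=gc_left, gc_right=gc_right, degraded=degraded,
    )


def dsdna_intervals(cell: CellState, genome: GenomeMap) -> dict:
    """Double-stranded intervals per chromosome for one cell.

    Resection leaves single-stranded DNA on ``[ho - left_extent, ho)`` and
    ``[ho, ho + right_extent)``; re-synthesis restores duplex from the break
    outward, so the remaining gaps are
    ``[ho - left_extent, ho - resynth_left)`` and
    ``[ho + resynth_right, ho + right_extent)``.  An uncut (or fully
    re-synthesised, repaired) cell is duplex end to end; an unrepaired cut
    cell is additionally split at the break itself.
    """
    out = {}
    ho = genome.ho_site
    for name, seq in genome.chromosomes.items():
        L = len(seq)
        if name != genome.recipient_name or not cell.cut:
            out[name] = [(0, L)]
            continue
        lo = ho - int(round(cell.left_extent))
        hi = ho + int(round(cell.right_extent))
        mid_lo = ho - int(round(cell.resynth_left))
        mid_hi = ho + int(round(cell.resynth_right))
        ivs = []
        if lo > 0:
            ivs.append((0, lo))
        if cell.repaired and mid_hi > mid_lo:
            ivs.append((mid_lo, mid_hi))
        if hi < L:
            ivs.append((hi, L))
        # merge abutting intervals only across a rejoined (repaired) break;
        # an unrepaired cut keeps the two duplex pieces physically separate
        merged = []
        for s, e in ivs:
            if merged and (s < merged[-1][1] or (s == merged[-1][1] and cell.repaired)):
                merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
            else:
                merged.append((s, e))
        out[name] = merged
    return out


@dataclass(frozen=True)
class ReadPairRecord:
    read_id: str
    mate1: str
    mate2: str
    cell: int
    chromosome: str
    start: int
    fragment_length: int
    donor_alleles: tuple  # offsets of polymorphisms carried with donor allele


def _recombinant_substitutions(pop: PopulationState, i: int, genome: GenomeMap):
    """(position -> base) edits on the recipient chromosome of repaired cell i."""
    subs = {}
    gl, gr = int(pop.gc_left[i]), int(pop.gc_right[i])
    for p in genome.polymorphisms:
        if gl <= p.offset_from_ho <= gr:
            subs[p.recipient_pos] = p.donor_allele
    # the HO core is replaced by the uncleavable HO-inc core
    from .reference import HO_CUT_INDEX, HO_INC_DIFF_INDEX, HO_INC_MOTIF
    subs[genome.ho_site - HO_CUT_INDEX + HO_INC_DIFF_INDEX] = HO_INC_MOTIF[HO_INC_DIFF_INDEX]
    return subs


def emit_read_pairs(pop: PopulationState, genome: GenomeMap, params: SimulationParams,
                    seed: int, n_pairs: int | None = None) -> list:
    """Sample error-free paired-end reads from double-stranded DNA only.

    Fragments are uniform over (cell, duplex position); a cell therefore
    contributes in proportion to its duplex content.  Reads from a repaired
    cell's recipient chromosome carry donor alleles inside the conversion
    tract.  Returns a list of :class:`ReadPairRecord`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EAD]))
    rl = params.read_length
    genome_len = sum(len(s) for s in genome.chromosomes.values())
    if n_pairs is None:
        n_pairs = int(round(params.depth * genome_len / (2 * rl)))

    # per-cell duplex intervals and sampling weights
    cell_ivs = [dsdna_intervals(pop.cell(i), genome) for i in range(pop.n_cells)]
    flat = []  # per cell: list of (chrom, start, end)
    weights = np.empty(pop.n_cells)
    for i, ivs in enumerate(cell_ivs):
        f = [(c, s, e) for c, lst in ivs.items() for s, e in lst]
        flat.append(f)
        weights[i] = sum(e - s for _, s, e in f)
    if weights.sum() == 0:
        warnings.warn("population has no double-stranded DNA; no reads emitted")
        return []
    probs = weights / weights.sum()

    cells = rng.choice(pop.n_cells, size=n_pairs, p=probs)
    frag_lens = np.clip(
        np.round(rng.normal(params.insert_mean, params.insert_sd, size=n_pairs)),
        rl, None,
    ).astype(int)
    u_iv = rng.random(n_pairs)
    u_pos = rng.random(n_pairs)

    seqs = genome.chromosomes
    sub_cache: dict[int, dict] = {}
    out = []
    for j in range(n_pairs):
        i = int(cells[j])
        ell = int(frag_lens[j])
        choices = [(c, s, e) for c, s, e in flat[i] if e - s >= ell]
        if not choices:
            continue
        w = np.array([e - s - ell + 1 for _, s, e in choices], dtype=float)
        k = int(np.searchsorted(np.cumsum(w / w.sum()), u_iv[j], side="right"))
        k = min(k, len(choices) - 1)
        chrom, s, e = choices[k]
        start = s + int(u_pos[j] * (e - s - ell + 1))
        frag = seqs[chrom][start: start + ell]
        carried = ()
        if chrom == genome.recipient_name and pop.repaired[i]:
            if i not in sub_cache:
                sub_cache[i] = _recombinant_substitutions(pop, i, genome)
            subs = sub_cache[i]
            hits = [(p, b) for p, b in subs.items() if start <= p < start + ell]
            if hits:
                lf = list(frag)
                for p, b in hits:
                    lf[p - start] = b
                frag = "".join(lf)
                carried = tuple(
                    p.offset_from_ho for p in genome.polymorphisms
                    if start <= p.recipient_pos < start + ell
                    and subs.get(p.recipient_pos) == p.donor_allele
                )
        out.append(
            ReadPairRecord(
                read_id=f"sim:{j}:{i}:{chrom}:{start}:{ell}",
                mate1=frag[:rl],
                mate2=revcomp(frag[ell - rl:]),
                cell=i,
                chromosome=chrom,
                start=start,
                fragment_length=ell,
                donor_alleles=carried,
            )
        )
    return out


def expected_relative_coverage(pop: PopulationState, chromosome: str,
                               positions) -> np.ndarray:
    """Fraction of cells in which each position is double-stranded.

    This is the analytic oracle for T0-normalised coverage profiles: the
    tagmentation library samples duplex DNA only, so after depth scaling the
    expected coverage ratio at a position equals the duplex fraction.
    """
    positions = np.atleast_1d(np.asarray(positions))
    if chromosome != pop.genome.recipient_name:
        return np.ones(positions.shape)
    ho = pop.genome.ho_site
    p = positions[:, None]
    ss_left = (p >= ho - pop.left_extent[None, :]) & (p < ho - pop.resynth_left[None, :])
    ss_right = (p >= ho + pop.resynth_right[None, :]) & (p < ho + pop.right_extent[None, :])
    ss = (ss_left | ss_right) & pop.cut[None, :]
    return 1.0 - ss.mean(axis=1)


def _amplicon_states(pop: PopulationState, amplicon: tuple) -> np.ndarray:
    """Per-cell signal of a qPCR amplicon: 1 duplex, 0.5 single-stranded
    (one template strand survives), 0 degraded."""
    chrom, start, end = amplicon
    if chrom != pop.genome.recipient_name:
        return np.ones(pop.n_cells)
    ho = pop.genome.ho_site
    ss_left = (end > ho - pop.left_extent) & (start < ho - pop.resynth_left) \
        & (start < ho)
    ss_right = (end > ho + pop.resynth_right) & (start < ho + pop.right_extent) \
        & (end > ho)
    touched = (ss_left | ss_right) & pop.cut
    signal = np.ones(pop.n_cells)
    signal[touched] = 0.5
    signal[touched & pop.degraded] = 0.0
    return signal


def simulate_qpcr_signal(pop: PopulationState, amplicon: tuple) -> float:
    """Relative qPCR signal of an amplicon, normalised to the undamaged state.

    A fully single-stranded population returns 0.5 — the textbook expectation
    for ssDNA, since one of the two template strands has been resected away.
    """
    chrom, start, end = amplicon
    if not 0 <= start < end <= len(pop.genome.chromosomes[chrom]):
        raise ValueError("amplicon out of bounds")
    return float(_amplicon_states(pop, amplicon).mean())
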