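"""Gene-conversion boundary mapping from inter-chromosomal discordant pairs.

A fragment from a repaired cell that straddles a conversion-tract boundary
has one 75-mer mate matching the donor haplotype (it aligns only to the
donor chromosome) and one matching the recipient haplotype (it aligns only
to the recipient chromosome).  Such a pair is *discordant*: its two mates
map to different chromosomes, and its fragment brackets a tract boundary.
Collecting discordant recipient/donor pairs therefore maps every individual
conversion event: quadrants of the (recipient, donor) coordinate scatter
separate left-side from right-side events and left from right boundaries,
and the crossing point of the recipient-mate and donor-mate coverage peaks
pins each boundary coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import PairClass
from .reference import GenomeMap

__all__ = [
    "DiscordantPair",
    "DiscordantReport",
    "extract_discordant",
    "discordant_fraction",
    "classify_quadrant",
    "discordant_coverage",
    "boundary_estimate",
    "classify_regions",
    "default_regions",
    "background_fraction",
]


@dataclass(frozen=True)
class DiscordantPair:
    recipient_coord: int  # leftmost mapped base of the recipient-chromosome mate
    donor_coord: int  # leftmost mapped base of the donor-chromosome mate
    recipient_strand: str
    donor_strand: str
    read_length: int
    timepoint: float | None = None


def extract_discordant(mapped_pairs, genome: GenomeMap,
                       timepoint: float | None = None,
                       read_length: int = 75,
                       coordinate: str = "leftmost") -> tuple:
    """Split discordant pairs into (recipient x donor) pairs and the rest.

    Only pairs in which both mates are uniquely mapped on different
    chromosomes qualify; the recipient/donor subset drives the GC analysis
    while other inter-chromosomal pairs are kept for background estimation.
    ``coordinate`` selects the per-mate coordinate convention: the leftmost
    aligned base (default, matching the scatter axes of the assay) or the
    mate midpoint.
    """
    if coordinate not in ("leftmost", "midpoint"):
        raise ValueError("coordinate must be 'leftmost' or 'midpoint'")
    shift = 0 if coordinate == "leftmost" else read_length // 2
    gc_pairs, others = [], []
    rec, don = genome.recipient_name, genome.donor_name
    for mp in mapped_pairs:
        if mp.pair_class is not PairClass.DISCORDANT:
            continue
        chroms = {mp.aln1.chromosome, mp.aln2.chromosome}
        if chroms == {rec, don}:
            a_rec, a_don = ((mp.aln1, mp.aln2) if mp.aln1.chromosome == rec
                            else (mp.aln2, mp.aln1))
            gc_pairs.append(
                DiscordantPair(
                    recipient_coord=a_rec.start + shift,
                    donor_coord=a_don.start + shift,
                    recipient_strand=a_rec.strand,
                    donor_strand=a_don.strand,
                    read_length=read_length,
                    timepoint=timepoint,
                )
            )
        else:
            others.append(mp)
    return gc_pairs, others


def discordant_fraction(n_pairs: int, total_reads: int) -> float:
    """Discordant recipient/donor pairs per read analysed."""
    if total_reads <= 0:
        raise ValueError("total read count must be positive")
    return n_pairs / total_reads


def classify_quadrant(pair: DiscordantPair, ho_site: int, ho_inc_site: int) -> str:
    """Quadrant of the (recipient, donor) scatter.

    Bottom quadrants (donor coordinate left of HO-inc) hold boundaries of
    conversion events on the left side of the break; top quadrants hold
    right-side events.  LB/RB further split left from right boundaries.
    On-axis pairs go right/top by the >= convention.
    """
    horiz = "L" if pair.recipient_coord < ho_site else "R"
    vert = "B" if pair.donor_coord < ho_inc_site else "T"
    return horiz + vert


def discordant_coverage(pairs, genome: GenomeMap, span: int = 1500) -> tuple:
    """Per-base coverage of recipient mates and donor mates in a common
    break-centred frame of +/- span nt.

    Donor-mate coordinates are mapped into the recipient frame through the
    homology arms; pairs whose donor mate falls outside the arms are
    excluded from the frame (returned as the third element).
    Returns (offsets, recipient_track, donor_track, n_excluded).
    """
    offsets = np.arange(-span, span)
    rec_track = np.zeros(offsets.size)
    don_track = np.zeros(offsets.size)
    excluded = 0
    ho = genome.ho_site
    for p in pairs:
        frame_don = genome.donor_to_recipient(p.donor_coord)
        frame_don_end = genome.donor_to_recipient(p.donor_coord + p.read_length - 1)
        if frame_don is None or frame_don_end is None:
            excluded += 1
            continue
        for track, start in ((rec_track, p.recipient_coord - ho),
                             (don_track, frame_don - ho)):
            lo = max(start, -span)
            hi = min(start + p.read_length, span)
            if lo < hi:
                track[lo + span: hi + span] += 1
    return offsets, rec_track, don_track, excluded


def boundary_estimate(offsets: np.ndarray, rec_track: np.ndarray,
                      don_track: np.ndarray, window: tuple,
                      smooth: int = 51) -> float | None:
    """Coordinate where the recipient and donor coverage peaks intersect.

    Within the window, finds the sign changes of the smoothed
    (recipient - donor) difference and returns the linearly interpolated
    crossing at which both tracks are highest — the peak intersection.
    None (censored) when the tracks never cross in the window.
    """
    sel = (offsets >= window[0]) & (offsets < window[1])
    if not sel.any():
        raise ValueError("empty window")
    x = offsets[sel]
    r = rec_track[sel].astype(float)
    d = don_track[sel].astype(float)
    if r.sum() == 0 or d.sum() == 0:
        return None
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        r = np.convolve(r, kernel, mode="same")
        d = np.convolve(d, kernel, mode="same")
    diff = r - d
    cross = np.nonzero(diff[:-1] * diff[1:] < 0)[0]
    if cross.size == 0:
        return None
    best, best_height = None, -np.inf
    for i in cross:
        height = min(r[i], d[i])
        if height > best_height:
            best_height = height
            frac = abs(diff[i]) / (abs(diff[i]) + abs(diff[i + 1]))
            best = float(x[i] + frac * (x[i + 1] - x[i]))
    return best


def _pair_boundary_offset(pair: DiscordantPair, genome: GenomeMap) -> float | None:
    """Break-centred coordinate of the tract boundary a pair brackets: the
    midpoint between the inner ends of its two mates in the common frame."""
    frame_don = genome.donor_to_recipient(pair.donor_coord)
    if frame_don is None:
        return None
    ho = genome.ho_site
    a = pair.recipient_coord - ho
    b = frame_don - ho
    left, right = (a, b) if a <= b else (b, a)
    return (left + pair.read_length + right) / 2.0


def default_regions(offsets, rec_track, don_track,
                    left_window: tuple = (-1300, -50),
                    right_window: tuple = (50, 1300)) -> list:
    """Derive the five canonical boundary bands from the coverage peaks.

    The distal-left (A) and distal-right (E) edges sit one read length
    outside the estimated left/right peak intersections; B/C split the
    remaining left flank at -150 nt and D covers the proximal right flank.
    These bands are conventionally defined graphically, so this is an
    explicit, overridable interpretation.
    """
    bl = boundary_estimate(offsets, rec_track, don_track, left_window)
    br = boundary_estimate(offsets, rec_track, don_track, right_window)
    if bl is None:
        bl = -600.0
    if br is None:
        br = 150.0
    lo, hi = float(offsets[0]), float(offsets[-1] + 1)
    # clamp so the bands stay ordered even for very proximal boundaries
    left_edge = min(bl + 75, -150.0)
    right_edge = max(br + 75, 75.0)
    return [
        ("A", lo, left_edge),
        ("B", left_edge, -150.0),
        ("C", -150.0, 0.0),
        ("D", 0.0, right_edge),
        ("E", right_edge, hi),
    ]


def classify_regions(pairs, genome: GenomeMap, regions: list) -> dict:
    """Assign each pair's boundary coordinate to one region band.

    ``regions`` is a list of (name, lo, hi) half-open bands in the
    break-centred frame; overlapping bands are an error.  Returns region
    proportions over classified pairs, counts, and per-region boundary
    coordinates.
    """
    bands = sorted(regions, key=lambda r: r[1])
    for (n1, lo1, hi1), (n2, lo2, hi2) in zip(bands[:-1], bands[1:]):
        if hi1 > lo2:
            raise ValueError(f"regions {n1} and {n2} overlap")
    counts = {name: 0 for name, _, _ in regions}
    coords = {name: [] for name, _, _ in regions}
    unclassified = 0
    for p in pairs:
        x = _pair_boundary_offset(p, genome)
        if x is None:
            unclassified += 1
            continue
        for name, lo, hi in regions:
            if lo <= x < hi:
                counts[name] += 1
                coords[name].append(x)
                break
        else:
            unclassified += 1
    total = sum(counts.values())
    proportions = {n: (c / total if total else np.nan) for n, c in counts.items()}
    extents = {n: (float(np.mean(v)) if v else None) for n, v in coords.items()}
    return {
        "counts": counts,
        "proportions": proportions,
        "extents": extents,
        "unclassified": unclassified,
        "total": total,
    }


def background_fraction(other_pairs, genome: GenomeMap, control_chromosome: str,
                        total_reads: int) -> float:
    """Fraction of recipient x control-chromosome discordant pairs per read —
    the chimera background against which the donor signal is judged."""
    if total_reads <= 0:
        raise ValueError("total read count must be positive")
    rec = genome.recipient_name
    n = sum(
        1 for mp in other_pairs
        if {mp.aln1.chromosome, mp.aln2.chromosome} == {rec, control_chromosome}
    )
    return n / total_reads


@dataclass
class DiscordantReport:
    """Summary of the discordant-pair GC analysis for one time course."""

    fraction_by_time: dict
    quadrant_counts: dict
    regions: dict
    boundaries: dict  # window name -> coordinate or None
    background: float | None = None
    n_pairs: int = 0
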