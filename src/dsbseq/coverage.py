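"""Coverage tracks and the normalised profiles every estimator consumes.

The normalisation pipeline mirrors the genome-wide resection assay:

1. per-base coverage from uniquely mapped reads;
2. RPGC-style scaling (genome-wide mean coverage becomes 1);
3. a T0 mask removing positions whose scaled undamaged coverage falls below
   a threshold (0.2), applied to every later time point;
4. per-position ratio against the T0 sample, averaged in 100-nt bins;
5. 2-kb section profiles C_N = (CIII_Tx/CIII_T0) / (CV_Tx/CV_T0), where the
   CV term is the mean over a control region on the donor chromosome,
   making different experiments comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AnalysisConfig",
    "CoverageTrack",
    "NormalizedProfile",
    "SectionProfile",
    "per_base_coverage",
    "rpgc_scale",
    "t0_mask",
    "ratio_profile",
    "section_normalize",
    "colormap_matrix",
]


@dataclass
class AnalysisConfig:
    """Every numeric constant of the analysis, at its standard default."""

    t0_threshold: float = 0.2
    half_coverage_level: float = 0.5
    max_extent_cutoff: float = 0.9
    bin_size: int = 100
    section_size: int = 2000
    short_range_window: int = 100
    resection_interval: tuple = (1.0, 4.0)
    synthesis_distances: tuple = (500, 15000)
    synthesis_interval: tuple = (4.0, 10.0)
    # control interval for the real chromosome-V donor reference; pipelines
    # running on a synthetic reference pass the genome's own annotated region
    control_region: tuple = ("chrV", 210_000, 330_000)
    read_length: int = 75
    smoothing_bins: int = 3
    insert_bounds: tuple = (50, 2000)


@dataclass
class CoverageTrack:
    """Per-base read coverage per chromosome."""

    counts: dict  # chrom -> float64 array
    scaled: bool = False

    @property
    def chromosome_lengths(self) -> dict:
        return {c: v.size for c, v in self.counts.items()}

    def genome_mean(self) -> float:
        total = sum(v.sum() for v in self.counts.values())
        n = sum(v.size for v in self.counts.values())
        return total / n


def per_base_coverage(alignments, chromosome_lengths: dict) -> CoverageTrack:
    """Stack uniquely mapped alignments into per-base counts.

    Accepts an iterable of AlignmentRecord (non-unique records are skipped;
    the 0-mismatch contract drops multi-mapped reads from coverage).
    """
    diffs = {c: np.zeros(l + 1) for c, l in chromosome_lengths.items()}
    for aln in alignments:
        if aln is None or not aln.unique:
            continue
        if aln.end > chromosome_lengths[aln.chromosome]:
            raise ValueError("alignment beyond chromosome bounds")
        d = diffs[aln.chromosome]
        d[aln.start] += 1
        d[aln.end] -= 1
    return CoverageTrack(
        counts={c: np.cumsum(d[:-1]) for c, d in diffs.items()}, scaled=False
    )


def rpgc_scale(track: CoverageTrack) -> CoverageTrack:
    """Scale so the genome-wide mean coverage equals 1 (RPGC)."""
    if track.scaled:
        raise ValueError("track already scaled")
    mean = track.genome_mean()
    if mean == 0:
        raise ValueError("cannot scale a track with zero total coverage")
    return CoverageTrack(
        counts={c: v / mean for c, v in track.counts.items()}, scaled=True
    )


def t0_mask(track_t0: CoverageTrack, threshold: float = 0.2) -> dict:
    """Boolean mask (True = excluded) of low-intrinsic-coverage positions.

    Derived once from the scaled undamaged sample and applied to the whole
    time course.
    """
    if not track_t0.scaled:
        raise ValueError("mask is defined on the scaled T0 track")
    return {c: v < threshold for c, v in track_t0.counts.items()}


@dataclass
class NormalizedProfile:
    """Binned Tx/T0 coverage ratio for one chromosome.

    Bin edges sit at ``anchor + k * bin_size``; with the anchor at the HO cut
    the bin grid splits exactly at the break, so left/right side metrics
    never mix across it.  Fully masked bins hold NaN.
    """

    chromosome: str
    bin_size: int
    starts: np.ndarray
    values: np.ndarray  # NaN where masked
    timepoint: float | None = None
    anchor: int = 0

    def value_at(self, position: int) -> float:
        i = int(np.searchsorted(self.starts, position, side="right")) - 1
        if i < 0 or position >= self.starts[i] + self.bin_size:
            raise ValueError("position outside profile")
        return float(self.values[i])

    def side_values(self, ho_site: int, side: str):
        """(distances from the cut at bin centres, values), ordered outward."""
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if (ho_site - self.anchor) % self.bin_size:
            raise ValueError("bin grid is not anchored at the cut")
        if side == "right":
            sel = self.starts >= ho_site
            d = self.starts[sel] - ho_site + self.bin_size / 2
            return d, self.values[sel]
        sel = self.starts + self.bin_size <= ho_site
        d = ho_site - (self.starts[sel] + self.bin_size / 2)
        return d[::-1], self.values[sel][::-1]


def _bin_grid(length: int, bin_size: int, anchor: int) -> np.ndarray:
    first = anchor % bin_size - bin_size if anchor % bin_size else 0
    return np.arange(first, length, bin_size)


def ratio_profile(track_tx: CoverageTrack, track_t0: CoverageTrack, mask: dict,
                  bin_size: int = 100, anchor: int = 0,
                  timepoint: float | None = None,
                  control_region: tuple | None = None) -> dict:
    """Per-position Tx/T0 ratio, averaged per bin over unmasked positions.

    Returns {chromosome: NormalizedProfile}.  Division by zero cannot occur
    after masking (the threshold is positive).

    With ``control_region`` the profile is additionally divided by the mean
    Tx/T0 ratio of that (donor-chromosome) region — the same correction the
    2-kb section formula applies.  On a compact reference this matters:
    RPGC rescaling inflates every unaffected position when a sizeable part
    of the genome turns single-stranded, and the control region restores an
    absolute duplex-fraction scale.
    """
    if not (track_tx.scaled and track_t0.scaled):
        raise ValueError("ratio profiles are computed on scaled tracks")
    factor = 1.0
    if control_region is not None:
        cc, cs, ce = control_region
        keep = ~mask[cc][cs:ce]
        t0c = track_t0.counts[cc][cs:ce][keep]
        txc = track_tx.counts[cc][cs:ce][keep]
        if t0c.size == 0 or t0c.mean() == 0 or txc.mean() == 0:
            raise ValueError("control region unusable for ratio correction")
        factor = txc.mean() / t0c.mean()
    out = {}
    for chrom, tx in track_tx.counts.items():
        t0 = track_t0.counts[chrom]
        m = mask[chrom]
        starts = _bin_grid(tx.size, bin_size, anchor)
        ratio = np.where(~m, tx / np.where(m, 1.0, np.maximum(t0, 1e-300)), np.nan)
        idx = np.clip((np.arange(tx.size) - starts[0]) // bin_size, 0, starts.size - 1)
        ok = ~m
        sums = np.bincount(idx[ok], weights=ratio[ok], minlength=starts.size)
        cnts = np.bincount(idx[ok], minlength=starts.size)
        with np.errstate(invalid="ignore"):
            vals = np.where(cnts > 0, sums / np.maximum(cnts, 1) / factor, np.nan)
        out[chrom] = NormalizedProfile(
            chromosome=chrom, bin_size=bin_size, starts=starts, values=vals,
            timepoint=timepoint, anchor=anchor,
        )
    return out


@dataclass
class SectionProfile:
    """Control-region-corrected 2-kb section coverage C_N for one sample."""

    section_size: int
    sections: dict  # chrom -> (starts, C_N values)
    control_region: tuple
    control_factor: float
    timepoint: float | None = None


def _region_mean(track: CoverageTrack, region: tuple, mask: dict | None) -> float:
    chrom, s, e = region
    v = track.counts[chrom][s:e]
    if mask is not None:
        keep = ~mask[chrom][s:e]
        if not keep.any():
            raise ValueError("control region entirely masked")
        v = v[keep]
    return float(v.mean())


def section_normalize(track_tx: CoverageTrack, track_t0: CoverageTrack,
                      control_region: tuple, section_size: int = 2000,
                      mask: dict | None = None,
                      timepoint: float | None = None) -> SectionProfile:
    """C_N = (CIII_Tx / CIII_T0) / (CV_Tx / CV_T0) per 2-kb section.

    The denominator is the mean coverage ratio of the control region on the
    donor chromosome, so the control region itself normalises to 1.
    """
    ctl_t0 = _region_mean(track_t0, control_region, mask)
    if ctl_t0 == 0:
        raise ValueError("control region has zero T0 coverage")
    control_factor = _region_mean(track_tx, control_region, mask) / ctl_t0
    if control_factor == 0:
        raise ValueError("control region has zero coverage at this time point")
    sections = {}
    for chrom, tx in track_tx.counts.items():
        t0 = track_t0.counts[chrom]
        starts = np.arange(0, tx.size, section_size)
        cn = np.empty(starts.size)
        for i, s in enumerate(starts):
            e = min(s + section_size, tx.size)
            sl_tx, sl_t0 = tx[s:e], t0[s:e]
            if mask is not None:
                keep = ~mask[chrom][s:e]
                sl_tx, sl_t0 = sl_tx[keep], sl_t0[keep]
            if sl_t0.size == 0 or sl_t0.mean() == 0:
                cn[i] = np.nan
            else:
                cn[i] = (sl_tx.mean() / sl_t0.mean()) / control_factor
        sections[chrom] = (starts, cn)
    return SectionProfile(
        section_size=section_size, sections=sections,
        control_region=control_region, control_factor=control_factor,
        timepoint=timepoint,
    )


def colormap_matrix(profiles: list, chromosome: str):
    """Stack section C_N values into a (time x section) matrix.

    Rows are ordered by time point; rendering into colours is left to the
    caller.  Returns (times, section_starts, matrix).
    """
    profiles = sorted(profiles, key=lambda p: (p.timepoint is None, p.timepoint))
    starts0 = profiles[0].sections[chromosome][0]
    rows = []
    for p in profiles:
        starts, cn = p.sections[chromosome]
        if not np.array_equal(starts, starts0):
            raise ValueError("section profiles do not share a section grid")
        rows.append(cn)
    times = np.array([p.timepoint if p.timepoint is not None else np.nan for p in profiles])
    return times, starts0, np.vstack(rows)
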