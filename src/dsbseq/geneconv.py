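"""Per-polymorphism gene-conversion quantification with repair correction.

Because a 0-mismatch read overlapping a polymorphic site is always
allele-informative, a converted recipient locus sheds its reads onto the
donor chromosome: donor coverage at the site rises while recipient coverage
falls.  With each locus normalised by its own undamaged (T0) coverage and
by the control region, the donor-site ratio is

    Cdonor' = 1 + q * r

where r is the fraction of cells that repaired and q the probability that a
repaired cell's conversion tract covers the site; the recipient-site ratio
is (1 - q) * r plus the uncut-cell fraction, because unrepaired cells hold
the locus single-stranded.  Two quantities follow:

* the *donor share* Cdonor' / (Cdonor' + Crecipient') — the descriptive
  per-site fraction of donor-allele representation (0.5 at baseline);
* the *donor excess* Cdonor' - 1 = q * r, which divided by the repair
  correction factor (the maximum 0.5-kb coverage recovery, itself an
  estimate of r) yields the corrected per-repaired-cell conversion
  probability q, independent of how many cells repaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .metrics import coverage_time_series
from .reference import GenomeMap

__all__ = ["GCReport", "site_fractions", "correction_factor", "gc_report"]


@dataclass
class GCReport:
    sites: pd.DataFrame  # offset, ratios, raw_fraction, donor_excess, corrected
    correction_factor: dict  # side -> factor
    pooled_factor: float


def _site_coverage(track: CoverageTrack, chrom: str, pos: int, window: int) -> float:
    half = window // 2
    v = track.counts[chrom]
    lo, hi = max(0, pos - half), min(v.size, pos - half + window)
    return float(v[lo:hi].mean())


def _control_factor(track_tx, track_t0, control_region) -> float:
    chrom, s, e = control_region
    t0 = track_t0.counts[chrom][s:e].mean()
    tx = track_tx.counts[chrom][s:e].mean()
    if t0 == 0 or tx == 0:
        raise ValueError("control region unusable")
    return tx / t0


def site_fractions(track_tx: CoverageTrack, track_t0: CoverageTrack,
                   genome: GenomeMap, window: int = 75,
                   control_region: tuple | None = None) -> pd.DataFrame:
    """Per-site T0-normalised coverage ratios, donor share and donor excess.

    Site coverage is the mean over a read-length window centred on the site
    (any overlapping 0-mismatch read is allele-informative).  Sites with
    zero T0 coverage on either locus are flagged unusable.
    """
    if not (track_tx.scaled and track_t0.scaled):
        raise ValueError("site fractions are computed on scaled tracks")
    if control_region is None:
        control_region = genome.control_region
    gfac = _control_factor(track_tx, track_t0, control_region) if control_region else 1.0
    rows = []
    for p in genome.polymorphisms:
        cr0 = _site_coverage(track_t0, genome.recipient_name, p.recipient_pos, window)
        cd0 = _site_coverage(track_t0, genome.donor_name, p.donor_pos, window)
        if cr0 == 0 or cd0 == 0:
            rows.append((p.offset_from_ho, np.nan, np.nan, np.nan, np.nan, False))
            continue
        cr = _site_coverage(track_tx, genome.recipient_name, p.recipient_pos, window) / cr0 / gfac
        cd = _site_coverage(track_tx, genome.donor_name, p.donor_pos, window) / cd0 / gfac
        if cr + cd == 0:
            rows.append((p.offset_from_ho, cd, cr, np.nan, np.nan, False))
            continue
        frac = cd / (cd + cr)
        rows.append((p.offset_from_ho, cd, cr, frac, max(0.0, cd - 1.0), True))
    return pd.DataFrame(
        rows,
        columns=["offset", "donor_ratio", "recipient_ratio", "raw_fraction",
                 "donor_excess", "usable"],
    )


def correction_factor(profiles_by_time: dict, ho_site: int,
                      distance: int = 500) -> dict:
    """Per-side repair-efficiency correction: the maximum over time of the
    coverage recovery at 0.5 kb from the cut.

    The undamaged reference sample (t <= 0, ratio 1 by construction) is not
    part of the recovery series.
    """
    out = {}
    for side in ("left", "right"):
        times, vals = coverage_time_series(profiles_by_time, ho_site, distance, side)
        vals = vals[times > 0]
        if vals.size == 0:
            raise ValueError("empty coverage series")
        out[side] = float(np.nanmax(vals))
    return out


def gc_report(track_tx: CoverageTrack, track_t0: CoverageTrack, genome: GenomeMap,
              profiles_by_time: dict, window: int = 75,
              pooled: bool = False) -> GCReport:
    """Assemble corrected per-site conversion probabilities.

    Left-of-break sites are corrected with the left 0.5-kb recovery factor
    and right sites with the right one (``pooled=True`` uses the mean of the
    two instead).  Corrected values are capped at 1.
    """
    df = site_fractions(track_tx, track_t0, genome, window=window)
    factors = correction_factor(profiles_by_time, genome.ho_site)
    pooled_factor = float(np.mean([factors["left"], factors["right"]]))

    def corr(row):
        if not row.usable:
            return np.nan
        f = pooled_factor if pooled else factors["left" if row.offset < 0 else "right"]
        if f <= 0:
            return np.nan
        return min(1.0, row.donor_excess / f)

    df["corrected"] = df.apply(corr, axis=1)
    return GCReport(sites=df, correction_factor=factors, pooled_factor=pooled_factor)
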