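"""Resection and re-synthesis estimators on normalised coverage profiles.

All distances are nucleotides from the HO cut; rates come out in nt/h
(long-range resection) or coverage units per hour (synthesis slope).  The
resection front at a level L is located by scanning the binned T0-ratio
profile outward from the cut and taking the *outermost* upward crossing of L
after a 3-bin median filter — raw binomial noise creates spurious inner
crossings, and the outermost one tracks the farthest cells.  Crossings are
linearly interpolated between bin centres; ties break toward the break
(shorter, conservative distances).  Estimates limited by a blocking element
or a chromosome end are reported censored at that boundary and excluded from
rate regressions rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.stats import linregress

from .coverage import AnalysisConfig, CoverageTrack, NormalizedProfile, ratio_profile

__all__ = [
    "Crossing",
    "TrendLine",
    "ResectionReport",
    "SynthesisReport",
    "short_range_resection",
    "distance_at_level",
    "long_range_rate",
    "max_resection_extent",
    "coverage_time_series",
    "synthesis_rate",
    "initiation_rate",
    "break_profiles",
]


@dataclass(frozen=True)
class Crossing:
    distance: float
    censored: bool
    bound: float | None = None  # the censoring boundary, when censored


@dataclass(frozen=True)
class TrendLine:
    slope: float
    intercept: float
    times: tuple
    values: tuple

    def at(self, t: float) -> float:
        return self.slope * t + self.intercept


def break_profiles(tracks_by_time: dict, track_t0: CoverageTrack, mask: dict,
                   recipient: str, ho_site: int, config: AnalysisConfig,
                   control_region: tuple | None = None) -> dict:
    """Binned T0-ratio profiles of the recipient chromosome, with the bin
    grid anchored at the cut and (when a control region is given) the
    control-region correction applied.  Returns {hour: NormalizedProfile}."""
    out = {}
    for t, track in tracks_by_time.items():
        prof = ratio_profile(track, track_t0, mask, bin_size=config.bin_size,
                             anchor=ho_site, timepoint=t,
                             control_region=control_region)
        out[t] = prof[recipient]
    return out


def _smoothed_side(profile: NormalizedProfile, ho_site: int, side: str,
                   smooth: int):
    d, v = profile.side_values(ho_site, side)
    if np.all(np.isnan(v)):
        raise ValueError(f"profile entirely masked on the {side} side")
    if smooth > 1:
        filled = np.where(np.isnan(v), np.nanmedian(v), v)
        v = median_filter(filled, size=smooth, mode="nearest")
    return d, v


def short_range_resection(profile_1h: NormalizedProfile, ho_site: int,
                          window: int = 100) -> dict:
    """Coverage decline within +/- window nt of the cut at 1 h.

    Returns mean ratio, decline (1 - mean ratio) per side and the
    left/right decline asymmetry.
    """
    res = {}
    for side in ("left", "right"):
        d, v = profile_1h.side_values(ho_site, side)
        sel = d <= window
        vals = v[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"short-range window fully masked on the {side} side")
        res[side] = {"mean_ratio": float(vals.mean()),
                     "decline": float(1.0 - vals.mean())}
    right_decline = res["right"]["decline"]
    res["asymmetry"] = (
        res["left"]["decline"] / right_decline if right_decline != 0 else np.inf
    )
    return res


def _outermost_upcross(d: np.ndarray, v: np.ndarray, level: float) -> float | None:
    """Interpolated distance of the last upward crossing of ``level``; None
    if the profile never rises to the level, 0.0 if it never drops below."""
    below = v < level
    if not below.any():
        return 0.0
    cross = np.nonzero(below[:-1] & ~below[1:])[0]
    if cross.size == 0:
        return None
    i = int(cross[-1])
    if v[i + 1] == v[i]:
        return float(d[i])
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return float(d[i] + frac * (d[i + 1] - d[i]))


def distance_at_level(profile: NormalizedProfile, ho_site: int, side: str,
                      level: float = 0.5, smooth: int = 3,
                      censor_bound: float | None = None) -> Crossing:
    """Distance from the cut where coverage recovers through ``level``.

    This is the resection front: the outermost coordinate at which the
    (smoothed) T0-normalised coverage climbs back to the level, scanning
    outward.  If coverage never reaches the level the estimate is censored
    at ``censor_bound`` (a blocking element) or at the end of the profile.
    """
    d, v = _smoothed_side(profile, ho_site, side, smooth)
    x = _outermost_upcross(d, v, level)
    if x is None:
        bound = censor_bound if censor_bound is not None else float(d[-1])
        return Crossing(distance=bound, censored=True, bound=bound)
    if censor_bound is not None and x > censor_bound:
        return Crossing(distance=censor_bound, censored=True, bound=censor_bound)
    return Crossing(distance=x, censored=False)


@dataclass
class ResectionReport:
    """Bundle of the resection estimators for one strain/time course."""

    short_range: dict  # output of short_range_resection at 1 h
    half_distance: dict  # side -> {hour: Crossing}
    rate: dict  # side -> RateFit
    max_extent: dict  # side -> {hour: Crossing}


@dataclass
class SynthesisReport:
    """Re-synthesis series, trend lines and initiation rates."""

    series: dict  # (distance, side) -> (times, values)
    trend: dict  # (distance, side) -> TrendLine
    rate: dict  # (distance, side) -> slope S
    initiation_rate: dict  # side -> v (kb/h) or None


@dataclass
class RateFit:
    rate: float  # nt/h
    intercept: float
    times: tuple
    distances: tuple
    residuals: tuple


def long_range_rate(profiles_by_time: dict, ho_site: int, side: str,
                    level: float = 0.5, interval: tuple = (1.0, 4.0),
                    smooth: int = 3, censor_bound: float | None = None) -> RateFit:
    """Long-range resection rate R = Δs/Δt over the 1-4 h interval.

    Ordinary least squares of the half-coverage distance against time; with
    two usable time points this reduces exactly to Δs/Δt.  Censored time
    points are excluded.
    """
    ts, ds = [], []
    for t, prof in sorted(profiles_by_time.items()):
        if not interval[0] <= t <= interval[1]:
            continue
        c = distance_at_level(prof, ho_site, side, level=level, smooth=smooth,
                              censor_bound=censor_bound)
        if not c.censored:
            ts.append(t)
            ds.append(c.distance)
    if len(ts) < 2:
        raise ValueError("need at least two uncensored time points for a rate")
    fit = linregress(ts, ds)
    resid = tuple(d - (fit.slope * t + fit.intercept) for t, d in zip(ts, ds))
    return RateFit(rate=float(fit.slope), intercept=float(fit.intercept),
                   times=tuple(ts), distances=tuple(ds), residuals=resid)


def max_resection_extent(track_scaled: CoverageTrack, mask: dict, recipient: str,
                         ho_site: int, side: str, cutoff: float = 0.9,
                         bin_size: int = 100, smooth: int = 3,
                         censor_bound: float | None = None) -> Crossing:
    """Distance where coverage first reaches cutoff x the recipient
    chromosome's own mean, scanning outward from the cut.

    Uses the same-sample scaled coverage (not the T0 ratio) and the mean over
    unmasked recipient positions, so samples rich in ssDNA have a lower
    effective threshold — the reference behaviour of this estimator.
    """
    if not track_scaled.scaled:
        raise ValueError("max extent is defined on the scaled track")
    v = track_scaled.counts[recipient]
    m = mask[recipient]
    if not (~m).any():
        raise ValueError("recipient chromosome fully masked")
    chrom_mean = v[~m].mean()
    level = cutoff * chrom_mean
    # bin the scaled coverage on a cut-anchored grid
    starts = np.arange(ho_site % bin_size - bin_size if ho_site % bin_size else 0,
                       v.size, bin_size)
    idx = np.clip((np.arange(v.size) - starts[0]) // bin_size, 0, starts.size - 1)
    ok = ~m
    sums = np.bincount(idx[ok], weights=v[ok], minlength=starts.size)
    cnts = np.bincount(idx[ok], minlength=starts.size)
    vals = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    prof = NormalizedProfile(chromosome=recipient, bin_size=bin_size,
                             starts=starts, values=vals, anchor=ho_site)
    d, vv = _smoothed_side(prof, ho_site, side, smooth)
    x = _outermost_upcross(d, vv, level)
    if x is None:
        bound = censor_bound if censor_bound is not None else float(d[-1])
        return Crossing(distance=bound, censored=True, bound=bound)
    if censor_bound is not None and x > censor_bound:
        return Crossing(distance=censor_bound, censored=True, bound=censor_bound)
    return Crossing(distance=x, censored=False)


def coverage_time_series(profiles_by_time: dict, ho_site: int, distance: int,
                         side: str, bin_size: int | None = None) -> tuple:
    """Coverage ratio at a fixed distance from the cut, per time point.

    The value is the bin containing the distance (e.g. x = 500 reads the
    [500, 600) bin on the cut-anchored grid).  Returns (times, values).
    """
    ts, vals = [], []
    for t, prof in sorted(profiles_by_time.items()):
        d, v = prof.side_values(ho_site, side)
        b = prof.bin_size
        i = int(distance // b)
        if i >= d.size or np.isnan(v[i]):
            raise ValueError(f"bin at distance {distance} unavailable at t={t}")
        ts.append(t)
        vals.append(float(v[i]))
    return np.array(ts), np.array(vals)


def synthesis_rate(times, values, interval: tuple = (4.0, 10.0)) -> TrendLine:
    """Least-squares trend line y = m x + b of coverage against time; the
    synthesis rate S is the slope, in coverage units per hour."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = (times >= interval[0]) & (times <= interval[1])
    if sel.sum() < 2:
        raise ValueError("need at least two time points inside the interval")
    fit = linregress(times[sel], values[sel])
    return TrendLine(slope=float(fit.slope), intercept=float(fit.intercept),
                     times=tuple(times[sel]), values=tuple(values[sel]))


def initiation_rate(trend: TrendLine) -> float | None:
    """Re-synthesis initiation rate v = Δs/Δt with Δs = 0.5 kb.

    Δt is the time the trend line needs to progress from coverage 0 to 0.5,
    i.e. Δt = 0.5/m; hence v = 0.5/Δt kb/h.  Undefined (None) for
    non-positive slopes.
    """
    if trend.slope <= 0:
        return None
    dt = 0.5 / trend.slope
    return 0.5 / dt
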