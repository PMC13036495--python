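"""Segmentation and rate extraction from constant-force traces.

Raw 58 Hz traces are low-pass filtered to 1 Hz with a centered moving
average before any decision is taken, mirroring standard practice for
camera-tracked bead data.  Nucleation, growth and compaction rates are then
extracted with threshold rules and sliding-window least-squares slopes:

* nucleation: first sustained (>= 10 s) excursion of the filtered extension
  above baseline mean + 3 sd after the protein flush;
* formation: mean of 20 s sliding-window OLS slopes in the growth region,
  keeping only windows whose net rise clears twice the pre-flush baseline
  dispersion; normalized to monomers/s through the monomer footprint;
* compaction: mean magnitude of negative 50 s window slopes, with a
  0.1 nm/s detection limit;
* ruptures: upward excursions of the averaged signal larger than twice the
  pre-ATP raw baseline sd within a 5 s window, merged when closer than 5 s.

Below-detection outcomes are reported as ``None`` (never silently zero) so
population averages can exclude and count them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trace import TimeTrace
from .wlc import WLCFitResult

CLASS_LABELS = ("fully_compacted", "partially_compacted", "dissociated",
                "extended", "unclassified")


@dataclass(frozen=True)
class AnalysisWindows:
    """Window lengths and thresholds for trace segmentation (all seconds)."""

    formation_window: float = 20.0
    compaction_window: float = 50.0
    rupture_window: float = 5.0
    lowpass_window: int = 58  # samples; 58 frames brings 58 Hz data to ~1 Hz
    nucleation_sigma: float = 3.0  # baseline sds for the nucleation crossing
    nucleation_dwell: float = 10.0  # s the crossing must persist
    compaction_detection_limit: float = 0.1  # nm/s
    formation_threshold_mode: str = "sd"  # 'sd' (2 x baseline sd) or 'variance'

    def __post_init__(self) -> None:
        if min(self.formation_window, self.compaction_window,
               self.rupture_window, self.lowpass_window) <= 0:
            raise ValueError("all windows must be positive")


@dataclass
class KineticEstimates:
    """Per-trace kinetic readout; None marks below-detection outcomes."""

    t_nucl: float | None = None  # s from flush start
    formation_rate_nm: float | None = None  # nm/s
    formation_rate_monomers: float | None = None  # monomers/s
    compaction_rate: float | None = None  # nm/s, positive magnitude
    ruptures: list[tuple[float, float]] = field(default_factory=list)
    class_label: str | None = None


def lowpass(trace: TimeTrace, window: int) -> TimeTrace:
    """Centered moving average over `window` samples, shrinking at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return trace
    smoothed = (pd.Series(trace.extension)
                .rolling(window, center=True, min_periods=1).mean().to_numpy())
    return TimeTrace(trace.time, smoothed, trace.force, trace.turns,
                     dict(trace.metadata))


def resample_1hz(trace: TimeTrace, window: int = 58) -> TimeTrace:
    """Moving-average filter then decimation to ~1 Hz."""
    filt = lowpass(trace, window)
    step = max(1, int(round(trace.sample_rate)))
    sl = slice(step // 2, None, step)
    return TimeTrace(filt.time[sl], filt.extension[sl], filt.force[sl],
                     filt.turns[sl], dict(trace.metadata))


def baseline_stats(trace: TimeTrace, t_end: float,
                   filtered: bool = False,
                   window: int = 58) -> tuple[float, float]:
    """Mean and sd of the (optionally filtered) extension before ``t_end``."""
    src = resample_1hz(trace, window) if filtered else trace
    seg = src.extension[src.time < t_end]
    if seg.size < 2:
        raise ValueError("baseline interval holds fewer than 2 samples")
    return float(np.mean(seg)), float(np.std(seg, ddof=1))


def detect_nucleation(trace: TimeTrace,
                      windows: AnalysisWindows = AnalysisWindows()) -> float | None:
    """Nucleation waiting time (s from flush start), or None.

    Automated surrogate for the manual call on 1 Hz filtered traces: the
    first instant after the flush where the extension exceeds the pre-flush
    baseline mean + ``nucleation_sigma`` baseline sds and stays above for at
    least ``nucleation_dwell`` seconds.  Because the threshold crossing lags
    the true onset by the rise time to the threshold, the reported time is
    refined by back-extrapolating the local growth slope (OLS over the dwell
    window) to the baseline level.
    """
    flush = trace.metadata.get("flush_start_s")
    if flush is None:
        raise ValueError("trace metadata lacks flush_start_s")
    filt = resample_1hz(trace, windows.lowpass_window)
    mean, sd = baseline_stats(trace, flush, filtered=True,
                              window=windows.lowpass_window)
    threshold = mean + windows.nucleation_sigma * sd
    above = (filt.extension > threshold) & (filt.time >= flush)
    if not above.any():
        return None
    # sustained crossing: stays above the threshold for the dwell time
    idx = np.flatnonzero(above)
    t = filt.time
    for i in idx:
        t_end = t[i] + windows.nucleation_dwell
        m = (t >= t[i]) & (t <= t_end)
        if np.all(filt.extension[m] > threshold):
            t_cross = float(t[i])
            # onset refinement: extrapolate the dwell-window slope back to
            # the baseline level
            if m.sum() >= 3:
                slope, intercept = np.polyfit(t[m], filt.extension[m], 1)
                if slope > 0:
                    onset = (mean - intercept) / slope
                    t_cross = float(np.clip(onset,
                                            t_cross - windows.nucleation_dwell,
                                            t_cross))
            return max(0.0, t_cross - flush)
    return None


def _window_slopes(time: np.ndarray, ext: np.ndarray,
                   window: float) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope in sliding windows advanced one sample at a time.

    Returns (window center times, slopes); only windows fully inside the
    span are used.
    """
    if time.size < 2:
        return np.array([]), np.array([])
    dt = float(np.median(np.diff(time)))
    w = max(2, int(round(window / dt)))
    if time.size < w:
        return np.array([]), np.array([])
    n = time.size - w + 1
    centers = np.empty(n)
    slopes = np.empty(n)
    # closed-form OLS on a uniform time grid
    x = np.arange(w) * dt
    x = x - x.mean()
    denom = float(np.sum(x * x))
    for i in range(n):
        y = ext[i:i + w]
        slopes[i] = float(np.sum(x * (y - y.mean()))) / denom
        centers[i] = time[i] + (w - 1) * dt / 2.0
    return centers, slopes


def formation_rate(trace: TimeTrace, region: tuple[float, float],
                   windows: AnalysisWindows = AnalysisWindows(),
                   baseline_sd: float | None = None) -> float | None:
    """Mean growth slope (nm/s) in ``region`` from 20 s sliding windows.

    Windows whose net extension increase fails 2x the pre-flush baseline
    dispersion are discarded; returns None when no window survives (below
    detection).  ``baseline_sd`` defaults to the raw pre-flush sd from the
    trace itself.
    """
    if baseline_sd is None:
        flush = trace.metadata.get("flush_start_s")
        if flush is None:
            raise ValueError("provide baseline_sd or flush_start_s metadata")
        _, baseline_sd = baseline_stats(trace, flush)
    threshold = (2.0 * baseline_sd if windows.formation_threshold_mode == "sd"
                 else 2.0 * baseline_sd**2)
    filt = resample_1hz(trace, windows.lowpass_window)
    sub = filt.slice_time(*region)
    _, slopes = _window_slopes(sub.time, sub.extension, windows.formation_window)
    if slopes.size == 0:
        return None
    keep = slopes * windows.formation_window > threshold
    if not keep.any():
        return None
    return float(np.mean(slopes[keep]))


def monomer_rate(rate_nm_s: float, delta_l_300: float,
                 footprint_bp: int = 14, tether_bp: int = 3149) -> float:
    """Convert a growth slope (nm/s) to monomers/s via the monomer footprint.

    ``delta_l_300`` is the full-filament extension change at the working
    force (saturating concentration); one monomer then accounts for
    ``delta_l_300 * footprint_bp / tether_bp`` nm of extension gain.
    """
    if delta_l_300 <= 0:
        raise ValueError("delta_l_300 must be positive")
    nm_per_monomer = delta_l_300 * footprint_bp / tether_bp
    return rate_nm_s / nm_per_monomer


def compaction_rate(trace: TimeTrace, region: tuple[float, float],
                    windows: AnalysisWindows = AnalysisWindows()) -> float | None:
    """Mean compaction speed (nm/s, positive) from 50 s window slopes.

    Only negative slopes steeper than the 0.1 nm/s detection limit count;
    returns None when every window is below the limit.
    """
    filt = resample_1hz(trace, windows.lowpass_window)
    sub = filt.slice_time(*region)
    _, slopes = _window_slopes(sub.time, sub.extension, windows.compaction_window)
    if slopes.size == 0:
        return None
    mags = -slopes[slopes < 0]
    mags = mags[mags >= windows.compaction_detection_limit]
    if mags.size == 0:
        return None
    return float(np.mean(mags))


def detect_ruptures(trace: TimeTrace, baseline_sd: float,
                    windows: AnalysisWindows = AnalysisWindows()
                    ) -> list[tuple[float, float]]:
    """Rupture events on the averaged signal: (time, jump size) pairs.

    An event is counted whenever the filtered extension rises by more than
    2x the raw pre-ATP baseline sd within any 5 s window; crossings closer
    than 5 s merge into one event.
    """
    if baseline_sd <= 0:
        raise ValueError("baseline_sd must be positive")
    filt = resample_1hz(trace, windows.lowpass_window)
    t, ext = filt.time, filt.extension
    if t.size < 2:
        return []
    dt = float(np.median(np.diff(t)))
    lag = max(1, int(round(windows.rupture_window / dt)))
    rises = ext[lag:] - ext[:-lag]
    crossing = rises > 2.0 * baseline_sd
    events: list[tuple[float, float]] = []
    last_t = -np.inf
    for i in np.flatnonzero(crossing):
        t_event = t[i + lag]
        if t_event - last_t < windows.rupture_window:
            last_t = t_event
            continue
        events.append((float(t_event), float(rises[i])))
        last_t = t_event
    return events


def _stable(segment: np.ndarray, tol: float) -> bool:
    return segment.size >= 2 and float(np.std(segment)) <= tol


def classify_trace(trace: TimeTrace, bare_extension: float,
                   post_fit: WLCFitResult | None = None,
                   windows: AnalysisWindows = AnalysisWindows(),
                   floor_frac: float = 0.25) -> str:
    """Four-way outcome classification of a constant-force ATP trace.

    fully_compacted: ends clamped at the compacted floor (final level below
    ``floor_frac`` of the bare extension, stable) and, when a post force-
    extension fit is supplied, that fit shows no WLC response (rejected fit).
    partially_compacted: drops below the bare level without a stable floor.
    dissociated: extension decreased but never below the bare level.
    extended: extension only increased and remained stable.
    Anything else: unclassified (counted, never silently dropped).
    """
    filt = resample_1hz(trace, windows.lowpass_window)
    ext = filt.extension
    if ext.size < 5:
        return "unclassified"
    tail = ext[filt.time > filt.time[-1] - 10.0]
    final = float(np.mean(tail)) if tail.size else float(ext[-1])
    peak = float(np.max(ext))
    margin = 0.05 * bare_extension
    dropped = float(np.min(ext[np.argmax(ext):])) < bare_extension - margin
    decreased = final < peak - margin

    at_floor = final <= floor_frac * bare_extension and _stable(tail, margin)
    if at_floor:
        if post_fit is None or not post_fit.accepted:
            return "fully_compacted"
        return "partially_compacted"
    if dropped and decreased:
        return "partially_compacted"
    if decreased:
        return "dissociated"
    if final >= bare_extension + margin and _stable(tail, 2 * margin):
        return "extended"
    return "unclassified"


def coilability_check(rotation_trace: TimeTrace,
                      slope_sigma: float = 3.0,
                      min_slope: float = 0.1) -> tuple[bool, float, float]:
    """Coilability flag and branch slopes from a rotation-extension sweep.

    Fits a line to the positive-turn and negative-turn branches of the
    filtered sweep and reports the extension loss per added turn on each
    branch (nm/turn, positive numbers).  The tether is called coilable when
    the positive-branch slope magnitude exceeds ``slope_sigma`` times its
    standard error *and* the ``min_slope`` detection limit (a statistically
    significant but sub-0.1 nm/turn slope is below what the assay resolves).
    """
    filt = lowpass(rotation_trace, 58)
    turns, ext = filt.turns, filt.extension
    pos, neg = turns > 0, turns < 0
    if pos.sum() < 3 or neg.sum() < 3:
        raise ValueError("rotation sweep must cover both turn signs")
    fit_pos = stats.linregress(turns[pos], ext[pos])
    fit_neg = stats.linregress(turns[neg], ext[neg])
    pos_slope = -float(fit_pos.slope)  # loss per added positive turn
    neg_slope = float(fit_neg.slope)  # loss per added negative turn
    coilable = (abs(fit_pos.slope) > slope_sigma * float(fit_pos.stderr)
                and abs(fit_pos.slope) > min_slope)
    return bool(coilable), pos_slope, neg_slope


def propose_regions(trace: TimeTrace,
                    windows: AnalysisWindows = AnalysisWindows()
                    ) -> dict[str, tuple[float, float] | None]:
    """Auto-proposed formation and compaction regions from phase boundaries.

    Reproducible surrogate for manual region selection: the formation region
    runs from the nucleation crossing to the extension maximum of the
    filtered trace; the compaction region from the maximum to the last
    decrease (the floor or the trace end).  Either can be None.
    """
    filt = resample_1hz(trace, windows.lowpass_window)
    flush = trace.metadata.get("flush_start_s", float(filt.time[0]))
    t_nucl = None
    if "flush_start_s" in trace.metadata:
        t_nucl = detect_nucleation(trace, windows)
    start = flush + t_nucl if t_nucl is not None else float(filt.time[0])
    # the argmax of a noisy plateau lands far past the end of growth; end the
    # rise at the first approach of the filtered trace to its plateau level
    if "flush_start_s" in trace.metadata:
        _, sd_f = baseline_stats(trace, flush, filtered=True,
                                 window=windows.lowpass_window)
    else:
        sd_f = float(np.std(np.diff(filt.extension))) / np.sqrt(2.0)
    level = float(np.max(filt.extension))
    risen = np.flatnonzero((filt.extension >= level - 3.0 * sd_f)
                           & (filt.time > start))
    i_max = int(risen[0]) if risen.size else int(np.argmax(filt.extension))
    t_max = float(filt.time[i_max])
    formation = (start, t_max) if t_max > start else None
    # compaction: from the maximum to the last point of the decreasing tail
    tail_ext = filt.extension[i_max:]
    tail_t = filt.time[i_max:]
    compaction = None
    if tail_ext.size > 2 and float(tail_ext[-1]) < float(tail_ext[0]):
        floor = float(np.min(tail_ext))
        below = np.flatnonzero(tail_ext <= floor + 0.02 * (tail_ext[0] - floor))
        t_end = float(tail_t[below[0]]) if below.size else float(tail_t[-1])
        compaction = (t_max, t_end)
    return {"formation": formation, "compaction": compaction}
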