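"""Breath event detection: peaks, on/offsets, peak linking, breath labels.

Breath peaks are local envelope maxima rising sufficiently far above the
moving baseline. On- and offsets are found either where the envelope crosses
the baseline (``onoffpeak_baseline_crossing``) or by extending the
maximum-slope tangent of each flank down to the baseline level
(``onoffpeak_slope_extrapolation``). Detected waveforms carry validity flags
(onset after peak, offset before peak, overlapping windows, peak at or below
baseline, flat flank) rather than being silently dropped.
"""

from __future__ import annotations

import warnings

import numpy as np

from .baseline import MovingBaseline
from .data import InputError, PeakSet, TimeSeries
from .envelope import EnvelopeSignal, _rolling_sums

__all__ = ["detect_peaks", "onoffpeak_baseline_crossing",
           "onoffpeak_slope_extrapolation", "find_linked_peaks",
           "detect_supported_and_occluded"]

from scipy import signal as sps


def _check_aligned(env: EnvelopeSignal, baseline: MovingBaseline) -> None:
    if env.values.size != baseline.values.size:
        raise InputError("envelope and baseline must have equal length")


def detect_peaks(env: EnvelopeSignal, baseline: MovingBaseline,
                 min_prominence_factor: float = 0.5,
                 min_separation: float = 1.0) -> np.ndarray:
    """Local envelope maxima exceeding the baseline by a relative margin.

    A candidate local maximum at sample p is kept when
    env[p] - baseline[p] >= min_prominence_factor * baseline[p] (and > 0).
    Candidates closer than ``min_separation`` seconds keep only the higher
    peak, and candidates within half an envelope window of either recording
    edge are discarded (the shrinking edge windows estimate the envelope from
    too few samples to support a peak). Returns sorted sample indices; may be
    empty.
    """
    _check_aligned(env, baseline)
    if min_separation <= 0:
        raise InputError("min_separation must be > 0")
    dist = max(1, int(round(min_separation * env.fs)))
    cand, _ = sps.find_peaks(env.values, distance=dist)
    guard = int(round(env.window_length * env.fs / 2))
    cand = cand[(cand >= guard) & (cand < env.values.size - guard)]
    if cand.size == 0:
        return cand
    excess = env.values[cand] - baseline.values[cand]
    need = min_prominence_factor * np.maximum(baseline.values[cand], 0.0)
    keep = (excess > 0) & (excess >= need)
    return cand[keep]


def _midpoints(peaks: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak search bounds: midpoint to the neighboring peak (recording
    edges for the first/last peak). Prevents runaway onsets in noisy troughs."""
    left = np.empty(peaks.size, dtype=int)
    right = np.empty(peaks.size, dtype=int)
    for j, p in enumerate(peaks):
        left[j] = 0 if j == 0 else (peaks[j - 1] + p) // 2
        right[j] = n - 1 if j == peaks.size - 1 else (p + peaks[j + 1]) // 2
    return left, right


def _finalize_peakset(ps: PeakSet, env: EnvelopeSignal,
                      baseline: MovingBaseline) -> PeakSet:
    n = len(ps)
    ps.set_flag("onset_after_peak", ps.start_idx > ps.peak_idx)
    ps.set_flag("offset_before_peak", ps.end_idx < ps.peak_idx)
    below = env.values[ps.peak_idx] <= baseline.values[ps.peak_idx] \
        if n else np.zeros(0, dtype=bool)
    if "peak_below_baseline" in ps.flags.columns:
        ps.set_flag("peak_below_baseline",
                    ps.flags["peak_below_baseline"].to_numpy() | below)
    else:
        ps.set_flag("peak_below_baseline", below)
    # closed-interval reading: windows sharing even one sample overlap
    overlap = np.zeros(n, dtype=bool)
    for j in range(n - 1):
        if ps.end_idx[j] >= ps.start_idx[j + 1]:
            overlap[j] = overlap[j + 1] = True
    ps.set_flag("window_overlap", overlap)
    return ps


def onoffpeak_baseline_crossing(env: EnvelopeSignal, baseline: MovingBaseline,
                                peaks) -> PeakSet:
    """On/offsets where the envelope crosses the moving baseline.

    The onset is the last sample at or below the baseline before the peak
    (the upward crossing); the offset is the first sample at or below it
    after the peak. The search is bounded by the midpoint to the neighboring
    peak; an absent crossing snaps to that bound.
    """
    _check_aligned(env, baseline)
    peaks = np.asarray(peaks, dtype=int)
    n = env.values.size
    if peaks.size and (peaks.min() < 0 or peaks.max() >= n):
        raise InputError("peak indices out of range")
    below = env.values <= baseline.values
    lb, rb = _midpoints(peaks, n)
    start = np.empty(peaks.size, dtype=int)
    end = np.empty(peaks.size, dtype=int)
    for j, p in enumerate(peaks):
        idx = np.flatnonzero(below[lb[j]:p + 1])
        start[j] = lb[j] + idx[-1] if idx.size else lb[j]
        idx = np.flatnonzero(below[p:rb[j] + 1])
        end[j] = p + idx[0] if idx.size else rb[j]
    ps = PeakSet(peaks, start, end, fs=env.fs, n_samples=n)
    return _finalize_peakset(ps, env, baseline)


def onoffpeak_slope_extrapolation(env: EnvelopeSignal, peaks,
                                  slope_window: float = 0.05,
                                  baseline: MovingBaseline | None = None) -> PeakSet:
    """On/offsets by extending each flank's maximum-slope tangent to the
    baseline level.

    On each flank (bounded by the surrounding baseline crossings, or the
    midpoints to neighboring peaks where no crossing exists) the
    maximum-magnitude slope of the ``slope_window``-smoothed envelope is
    located and its tangent line extended down to the local baseline level;
    the intersection is the on/offset. A flat (zero-slope) flank flags the
    waveform invalid. With no baseline given, a zero level is used.
    """
    peaks = np.asarray(peaks, dtype=int)
    n = env.values.size
    if peaks.size and (peaks.min() < 0 or peaks.max() >= n):
        raise InputError("peak indices out of range")
    bl_vals = baseline.values if baseline is not None else np.zeros(n)
    if bl_vals.size != n:
        raise InputError("envelope and baseline must have equal length")
    k = max(2, int(round(slope_window * env.fs)))
    s, cnt = _rolling_sums(env.values, k)
    sm = s / cnt
    slope = np.gradient(sm) * env.fs
    below = env.values <= bl_vals
    lb, rb = _midpoints(peaks, n)
    start = np.empty(peaks.size, dtype=int)
    end = np.empty(peaks.size, dtype=int)
    flat = np.zeros(peaks.size, dtype=bool)
    for j, p in enumerate(peaks):
        idx = np.flatnonzero(below[lb[j]:p + 1])
        lo = lb[j] + idx[-1] if idx.size else lb[j]
        idx = np.flatnonzero(below[p:rb[j] + 1])
        hi = p + idx[0] if idx.size else rb[j]
        # rising flank
        if p > lo:
            m = lo + int(np.argmax(slope[lo:p + 1]))
            sl = slope[m]
        else:
            m, sl = p, 0.0
        if sl <= 0:
            flat[j] = True
            start[j] = lo
        else:
            di = (sm[m] - bl_vals[m]) / sl * env.fs
            start[j] = int(np.clip(round(m - di), 0, p))
        # falling flank
        if hi > p:
            m = p + int(np.argmin(slope[p:hi + 1]))
            sl = slope[m]
        else:
            m, sl = p, 0.0
        if sl >= 0:
            flat[j] = True
            end[j] = hi
        else:
            di = (sm[m] - bl_vals[m]) / (-sl) * env.fs
            end[j] = int(np.clip(round(m + di), p, n - 1))
    ps = PeakSet(peaks, start, end, fs=env.fs, n_samples=n)
    ps.set_flag("zero_slope_flank", flat)
    bl = baseline if baseline is not None else \
        MovingBaseline(values=bl_vals, fs=env.fs, spec=None)
    return _finalize_peakset(ps, env, bl)


def find_linked_peaks(times_a, times_b, tolerance: float):
    """One-to-one greedy nearest-first matching of two sorted peak-time lists.

    Returns (pairs, unmatched_a, unmatched_b) where pairs is a list of
    (index_a, index_b) with |t_a - t_b| <= tolerance, matched in order of
    increasing time difference.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    if np.any(np.diff(ta) < 0) or np.any(np.diff(tb) < 0):
        raise InputError("peak time lists must be sorted")
    cands = [(abs(ta[i] - tb[j]), i, j)
             for i in range(ta.size) for j in range(tb.size)
             if abs(ta[i] - tb[j]) <= tolerance]
    cands.sort()
    used_a, used_b, pairs = set(), set(), []
    for _, i, j in cands:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    pairs.sort()
    unmatched_a = [i for i in range(ta.size) if i not in used_a]
    unmatched_b = [j for j in range(tb.size) if j not in used_b]
    return pairs, unmatched_a, unmatched_b


def detect_supported_and_occluded(pressure: TimeSeries | None, peak_times,
                                  window: float | None = None,
                                  deflection_fraction: float = 0.3):
    """Label each breath supported / occluded / unsupported from the airway
    pressure trace.

    A breath with a time-locked positive pressure deflection (relative to the
    median pressure) is 'supported'; a negative deflection marks an occlusion
    manoeuvre ('occluded'); otherwise 'unsupported'. Deflections count when
    they exceed ``deflection_fraction`` of the largest absolute deflection in
    the recording. Returns a list of labels, one per breath; with no pressure
    channel (or a flat one) all labels are None.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if pressure is None:
        warnings.warn("no pressure channel: breath support labels absent",
                      UserWarning, stacklevel=2)
        return [None] * peak_times.size
    dev = pressure.samples - np.median(pressure.samples)
    scale = np.max(np.abs(dev)) if dev.size else 0.0
    if scale <= 0:
        return [None] * peak_times.size
    if window is None:
        window = float(np.median(np.diff(peak_times))) \
            if peak_times.size >= 2 else 2.0
    half = int(round(window / 2 * pressure.fs))
    labels = []
    for tp in peak_times:
        c = int(round(tp * pressure.fs))
        lo, hi = max(0, c - half), min(pressure.n_samples, c + half + 1)
        seg = dev[lo:hi]
        if seg.size == 0:
            labels.append("unsupported")
            continue
        posmax, negmin = seg.max(), seg.min()
        if -negmin >= deflection_fraction * scale and -negmin > posmax:
            labels.append("occluded")
        elif posmax >= deflection_fraction * scale:
            labels.append("supported")
        else:
            labels.append("unsupported")
    return labels
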