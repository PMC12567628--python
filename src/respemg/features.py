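"""Per-breath magnitude and timing features from envelope, baseline, PeakSet.

All features are computed on the (envelope, baseline) pair: amplitude is the
envelope excess over the baseline at the peak, the electrical time product
(ETP) the area between envelope and baseline across the breath. Everything is
invariant to adding a constant to both envelope and baseline, and amplitude
and ETP scale linearly with envelope gain. Invalid waveforms receive NaN
features with their flags preserved.

Output column names are fixed: duration_s, t_max_s, t_max_rel, amplitude_uv,
etp_uvs, pseudo_slope_uv_per_s, rr_bpm.
"""

from __future__ import annotations

import numpy as np

from .baseline import MovingBaseline
from .data import PeakSet
from .envelope import EnvelopeSignal

__all__ = ["compute_amplitude", "compute_etp", "compute_timing",
           "compute_pseudo_slope", "compute_respiratory_rate",
           "compute_features"]


def compute_amplitude(env: EnvelopeSignal, baseline: MovingBaseline,
                      peakset: PeakSet) -> np.ndarray:
    """env[peak] - baseline[peak] per breath (µV); NaN for invalid waveforms."""
    out = env.values[peakset.peak_idx] - baseline.values[peakset.peak_idx]
    out = np.asarray(out, dtype=float)
    out[~peakset.valid] = np.nan
    return out


def compute_etp(env: EnvelopeSignal, baseline: MovingBaseline,
                peakset: PeakSet) -> np.ndarray:
    """Electrical time product: trapezoidal area of max(env - baseline, 0)
    over each breath window (µV·s).

    Excursions below the baseline are clipped to zero here; they are counted
    by the area-under-baseline quality metric instead.
    """
    diff = np.clip(env.values - baseline.values, 0.0, None)
    valid = peakset.valid
    out = np.full(len(peakset), np.nan)
    for j in range(len(peakset)):
        if not valid[j]:
            continue
        a, b = peakset.start_idx[j], peakset.end_idx[j]
        out[j] = np.trapezoid(diff[a:b + 1], dx=1.0 / env.fs)
    return out


def compute_timing(peakset: PeakSet, fs: float | None = None):
    """(duration, t_max_abs, t_max_rel) in seconds / dimensionless."""
    if fs is None:
        fs = peakset.fs
    duration = (peakset.end_idx - peakset.start_idx) / fs
    t_max = (peakset.peak_idx - peakset.start_idx) / fs
    with np.errstate(divide="ignore", invalid="ignore"):
        t_rel = np.where(duration > 0, t_max / duration, np.nan)
    bad = ~peakset.valid
    duration = np.where(bad, np.nan, duration)
    t_max = np.where(bad, np.nan, t_max)
    t_rel = np.where(bad, np.nan, t_rel)
    return duration, t_max, t_rel


def compute_pseudo_slope(env: EnvelopeSignal, baseline: MovingBaseline,
                         peakset: PeakSet) -> np.ndarray:
    """Activation-rate proxy: amplitude / time-to-peak (µV/s).

    A zero time-to-peak yields NaN (the degenerate waveform keeps its
    onset/validity flags).
    """
    amp = compute_amplitude(env, baseline, peakset)
    _, t_max, _ = compute_timing(peakset)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(t_max > 0, amp / t_max, np.nan)


def compute_respiratory_rate(peak_times, method: str = "median") -> float:
    """Breaths/min from inter-peak intervals: 60 / median (or mean) interval.

    The median is robust to occasional missed breaths. Returns NaN for
    fewer than 2 peaks.
    """
    t = np.asarray(peak_times, dtype=float)
    if t.size < 2:
        return float("nan")
    iv = np.diff(t)
    ref = np.median(iv) if method == "median" else np.mean(iv)
    return 60.0 / ref


def compute_features(env: EnvelopeSignal, baseline: MovingBaseline,
                     peakset: PeakSet) -> PeakSet:
    """Attach the full feature table to the PeakSet (in place) and return it."""
    duration, t_max, t_rel = compute_timing(peakset)
    peakset.set_feature("duration_s", duration)
    peakset.set_feature("t_max_s", t_max)
    peakset.set_feature("t_max_rel", t_rel)
    peakset.set_feature("amplitude_uv", compute_amplitude(env, baseline, peakset))
    peakset.set_feature("etp_uvs", compute_etp(env, baseline, peakset))
    peakset.set_feature("pseudo_slope_uv_per_s",
                        compute_pseudo_slope(env, baseline, peakset))
    rr = compute_respiratory_rate(peakset.peak_times)
    peakset.set_feature("rr_bpm", np.full(len(peakset), rr))
    return peakset
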