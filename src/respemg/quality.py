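"""Breath- and recording-level quality assessment of sEMG waveforms.

Per breath: pseudo-SNR (peak amplitude relative to the moving baseline), area
under the baseline (AUB — the envelope deficit below the baseline, an
uncertainty proxy for the ETP, also expressed as a percentage of the ETP),
locally high AUB, extreme ETP, and the bell-curve error (residual of a
least-squares Gaussian bell fit, as a percentage of the ETP — respiratory
effort waveforms are physiologically bell-shaped, so a high residual marks
artifact).

Recording level: EMG-vs-ECG peak-count ratio, respiratory-rate agreement with
a pneumatic reference, matched-peak timing, and temporal separation of
occlusion manoeuvres.

The clinical thresholds behind the flags are not settled in the literature;
every factor here is configuration-exposed with a documented placeholder
default. All percentage metrics are invariant to global signal gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .baseline import MovingBaseline
from .data import InputError, PeakSet
from .envelope import EnvelopeSignal

__all__ = ["QualitySpec", "pseudo_snr", "area_under_baseline",
           "detect_local_high_aub", "detect_extreme_timeproducts",
           "evaluate_bell_curve_error", "interpeak_dist",
           "evaluate_respiratory_rates", "evaluate_event_timing",
           "detect_non_consecutive_manoeuvres", "compute_quality"]


@dataclass
class QualitySpec:
    aub_margin: float = 0.5          # s, AUB window extension on each side
    local_aub_factor: float = 2.0
    local_aub_window_breaths: int = 5
    extreme_etp_factor: float = 3.0
    bell_max_error_pct: float = 40.0
    min_snr: float = 1.0
    timing_window_s: float = 0.5
    rr_max_dev_pct: float = 25.0
    interpeak_min_ratio: float = 1.5


def pseudo_snr(env: EnvelopeSignal, baseline: MovingBaseline,
               peakset: PeakSet) -> np.ndarray:
    """(env[peak] - baseline[peak]) / baseline[peak]; NaN where the baseline
    is non-positive at the peak (flag it via :func:`compute_quality`)."""
    b = baseline.values[peakset.peak_idx]
    a = env.values[peakset.peak_idx] - b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(b > 0, a / b, np.nan)
    out = np.asarray(out, dtype=float)
    out[~peakset.valid] = np.nan
    return out


def area_under_baseline(env: EnvelopeSignal, baseline: MovingBaseline,
                        peakset: PeakSet, aub_window: float = 0.5,
                        etp: np.ndarray | None = None):
    """Per-breath AUB (µV·s) and its percentage of the ETP.

    The AUB window is the breath window extended by ``aub_window`` seconds on
    each side; AUB = max(0, baseline - min(env over window)) * breath
    duration, with the baseline taken as its mean over the window. Breaths
    with zero ETP get NaN percentage.
    """
    n = env.values.size
    m = int(round(aub_window * env.fs))
    if etp is None:
        from .features import compute_etp
        etp = compute_etp(env, baseline, peakset)
    aub = np.full(len(peakset), np.nan)
    pct = np.full(len(peakset), np.nan)
    valid = peakset.valid
    for j in range(len(peakset)):
        if not valid[j]:
            continue
        a = max(0, peakset.start_idx[j] - m)
        b = min(n - 1, peakset.end_idx[j] + m)
        bl_ref = float(np.mean(baseline.values[a:b + 1]))
        dur = (peakset.end_idx[j] - peakset.start_idx[j]) / env.fs
        aub[j] = max(0.0, bl_ref - float(np.min(env.values[a:b + 1]))) * dur
        if np.isfinite(etp[j]) and etp[j] > 0:
            pct[j] = 100.0 * aub[j] / etp[j]
    return aub, pct


def _rolling_median_excluding_nan(x: np.ndarray, w: int) -> np.ndarray:
    return pd.Series(x).rolling(w, center=True, min_periods=1)\
        .median().to_numpy()


def detect_local_high_aub(aub, threshold_factor: float = 2.0,
                          window_breaths: int = 5) -> np.ndarray:
    """Flag breaths whose AUB exceeds ``threshold_factor`` times the rolling
    median AUB of neighboring breaths. Scale-invariant by construction."""
    aub = np.asarray(aub, dtype=float)
    if aub.size < 3:
        warnings.warn("fewer than 3 breaths: no local-AUB flags",
                      UserWarning, stacklevel=2)
        return np.zeros(aub.size, dtype=bool)
    med = _rolling_median_excluding_nan(aub, window_breaths)
    with np.errstate(invalid="ignore"):
        return np.asarray(aub > threshold_factor * med)


def detect_extreme_timeproducts(etp, threshold_factor: float = 3.0) -> np.ndarray:
    """Flag breaths whose ETP exceeds ``threshold_factor`` times the median."""
    etp = np.asarray(etp, dtype=float)
    if etp.size < 3:
        warnings.warn("fewer than 3 breaths: no extreme-ETP flags",
                      UserWarning, stacklevel=2)
        return np.zeros(etp.size, dtype=bool)
    med = np.nanmedian(etp)
    with np.errstate(invalid="ignore"):
        return np.asarray(etp > threshold_factor * med)


def _gauss(t, a, c, w):
    return a * np.exp(-((t - c) ** 2) / (2.0 * w ** 2))


def fit_bell(t: np.ndarray, y: np.ndarray):
    """Bounded least-squares Gaussian bell fit; returns (a, c, w) or None."""
    if t.size < 4 or not np.any(y > 0):
        return None
    span = t[-1] - t[0]
    if span <= 0:
        return None
    a0 = float(np.max(y))
    c0 = float(t[int(np.argmax(y))])
    p0 = (a0, c0, span / 6.0)
    bounds = ([0.0, t[0], span / 100.0], [5.0 * a0 + 1e-12, t[-1], 2.0 * span])
    try:
        popt, _ = curve_fit(_gauss, t, y, p0=p0, bounds=bounds, maxfev=2000)
    except (RuntimeError, ValueError):
        return None
    return tuple(popt)


def evaluate_bell_curve_error(env: EnvelopeSignal, baseline: MovingBaseline,
                              peakset: PeakSet,
                              etp: np.ndarray | None = None):
    """Residual of the best-fit Gaussian bell as a percentage of the ETP.

    Per valid breath, a three-parameter bell (amplitude, center, width) is
    least-squares fitted to env - baseline over the breath window;
    bell_error_pct = 100 * integral |waveform - bell| / ETP. Fit failures
    return NaN with the ``bell_fail`` flag left to :func:`compute_quality`.
    Invariant to amplitude scaling (numerator and denominator scale together).
    """
    if etp is None:
        from .features import compute_etp
        etp = compute_etp(env, baseline, peakset)
    diff = env.values - baseline.values
    out = np.full(len(peakset), np.nan)
    valid = peakset.valid
    for j in range(len(peakset)):
        if not valid[j] or not (np.isfinite(etp[j]) and etp[j] > 0):
            continue
        a, b = peakset.start_idx[j], peakset.end_idx[j]
        t = np.arange(a, b + 1) / env.fs
        y = diff[a:b + 1]
        fit = fit_bell(t, y)
        if fit is None:
            continue
        resid = np.abs(y - _gauss(t, *fit))
        out[j] = 100.0 * np.trapezoid(resid, dx=1.0 / env.fs) / etp[j]
    return out


def interpeak_dist(ecg_peaks, emg_peaks, min_ratio: float = 1.5):
    """Recording-level check that the heart beats faster than breathing.

    Passes iff (ECG peak count / EMG peak count) >= min_ratio. An EMG peak
    count close to the beat count suggests the envelope is tracking residual
    cardiac activity. Returns (passed, reason).
    """
    n_ecg = len(ecg_peaks)
    n_emg = len(emg_peaks)
    if n_ecg == 0 or n_emg == 0:
        return False, "empty peak list"
    ratio = n_ecg / n_emg
    if ratio >= min_ratio:
        return True, f"ECG/EMG peak ratio {ratio:.2f} >= {min_ratio}"
    return False, (f"ECG/EMG peak ratio {ratio:.2f} < {min_ratio}: EMG peaks "
                   "may track the heart")


def evaluate_respiratory_rates(emg_rr: float, reference_rr: float | None,
                               max_deviation_pct: float = 25.0):
    """Pass iff the EMG-derived rate deviates from the reference (e.g.
    pneumatic) rate by at most ``max_deviation_pct`` percent. Returns None
    (indeterminate, with a warning) when the reference is missing."""
    if reference_rr is None or not np.isfinite(reference_rr) or reference_rr <= 0:
        warnings.warn("missing reference respiratory rate: agreement "
                      "indeterminate", UserWarning, stacklevel=2)
        return None
    if not np.isfinite(emg_rr) or emg_rr <= 0:
        raise InputError("emg_rr must be a positive finite rate")
    return abs(emg_rr - reference_rr) / reference_rr <= max_deviation_pct / 100.0


def evaluate_event_timing(linked_pairs, times_a, times_b,
                          window_s: float) -> np.ndarray:
    """Per matched pair: True iff |t_a - t_b| <= window_s."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    return np.array([abs(ta[i] - tb[j]) <= window_s for i, j in linked_pairs],
                    dtype=bool)


def detect_non_consecutive_manoeuvres(labels) -> np.ndarray:
    """Validity of each manoeuvre in an ordered breath/manoeuvre sequence.

    A manoeuvre is valid iff every neighbor it has is a regular breath;
    manoeuvres at the sequence boundary need no neighbor on that side. Two
    adjacent manoeuvres invalidate each other. Returns one boolean per
    'manoeuvre' entry, in order.
    """
    labels = list(labels)
    out = []
    for i, lab in enumerate(labels):
        if lab != "manoeuvre":
            continue
        ok = True
        if i > 0 and labels[i - 1] != "breath":
            ok = False
        if i < len(labels) - 1 and labels[i + 1] != "breath":
            ok = False
        out.append(ok)
    return np.array(out, dtype=bool)


def compute_quality(env: EnvelopeSignal, baseline: MovingBaseline,
                    peakset: PeakSet,
                    spec: QualitySpec | None = None) -> PeakSet:
    """Attach per-breath quality metrics and flags to the PeakSet."""
    if spec is None:
        spec = QualitySpec()
    if "etp_uvs" in peakset.features.columns:
        etp = peakset.features["etp_uvs"].to_numpy()
    else:
        from .features import compute_etp
        etp = compute_etp(env, baseline, peakset)
    snr = pseudo_snr(env, baseline, peakset)
    aub, aub_pct = area_under_baseline(env, baseline, peakset,
                                       aub_window=spec.aub_margin, etp=etp)
    bell = evaluate_bell_curve_error(env, baseline, peakset, etp=etp)
    peakset.set_feature("pseudo_snr", snr)
    peakset.set_feature("aub_uvs", aub)
    peakset.set_feature("aub_pct", aub_pct)
    peakset.set_feature("bell_error_pct", bell)
    with np.errstate(invalid="ignore"):
        peakset.set_flag("snr_fail", np.where(np.isfinite(snr),
                                              snr < spec.min_snr, True))
        peakset.set_flag("bell_fail",
                         ~np.isfinite(bell) | (bell > spec.bell_max_error_pct))
    peakset.set_flag("local_high_aub",
                     detect_local_high_aub(aub, spec.local_aub_factor,
                                           spec.local_aub_window_breaths)
                     if len(peakset) >= 3 else np.zeros(len(peakset), bool))
    peakset.set_flag("extreme_etp",
                     detect_extreme_timeproducts(etp, spec.extreme_etp_factor)
                     if len(peakset) >= 3 else np.zeros(len(peakset), bool))
    return peakset
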