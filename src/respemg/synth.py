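"""Synthetic contaminated respiratory sEMG recordings with ground truth.

The respiratory EMG channel is built as breath-envelope-modulated white noise
on top of a constant white noise floor, contaminated by a periodic QRS-complex
train (Mexican-hat template), a low-frequency baseline-wander sinusoid, and a
powerline sinusoid. An optional ventilator pressure channel carries a
positive-pressure boxcar per supported breath and negative deflections for
occlusion manoeuvres. Ground-truth breath and QRS annotations make every
processing stage testable without patient recordings.

Note that amplitude-modulated white noise has a flat power spectrum up to the
Nyquist frequency — broader than real muscle activity, which concentrates its
power roughly between 20 and 150 Hz. Consequences for what synthetic tests can
and cannot show are discussed in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import InputError, TimeSeries, TimeSeriesGroup

__all__ = ["SynthSpec", "GroundTruth", "simulate_semg", "simulate_ventilator"]

BREATH_SHAPES = ("halfsine", "gaussian", "triangle")


@dataclass
class SynthSpec:
    """Full parameterization of a simulated recording.

    Rates are constant per recording (no breath-to-breath variability model).
    Amplitudes are in µV; the noise floor is the RMS of the unmodulated white
    noise component.
    """

    fs: float = 2048.0          # Hz
    duration: float = 60.0      # s
    rr: float = 12.0            # breaths/min
    hr: float = 80.0            # beats/min
    emg_amp: float = 5.0        # µV, peak of the modulation envelope
    breath_shape: str = "gaussian"
    duty: float = 0.4           # inspiratory fraction of the breath cycle
    ecg_amp: float = 10.0       # µV, QRS peak amplitude
    qrs_width: float = 0.1      # s, half-support of the QRS template
    wander_amp: float = 0.5     # µV
    wander_freq: float = 0.25   # Hz, must stay below 0.5 Hz
    powerline_amp: float = 0.5  # µV
    powerline_freq: float = 50.0
    noise_floor: float = 1.0    # µV RMS
    seed: int = 0

    def validate(self) -> None:
        if not (self.fs > 0 and self.duration > 0):
            raise InputError("fs and duration must be positive")
        if not 0 < self.duty < 1:
            raise InputError(f"duty must be in (0, 1), got {self.duty}")
        if self.breath_shape not in BREATH_SHAPES:
            raise InputError(
                f"breath_shape must be one of {BREATH_SHAPES}, "
                f"got '{self.breath_shape}'")
        for name in ("emg_amp", "ecg_amp", "wander_amp", "powerline_amp",
                     "noise_floor"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if not 0 <= self.wander_freq < 0.5:
            raise InputError("wander_freq must be in [0, 0.5) Hz")
        highest = max(self.powerline_freq, 4.0 / max(self.qrs_width, 1e-9))
        if self.fs < 2 * highest:
            raise InputError(
                f"fs={self.fs} Hz below twice the highest generated "
                f"frequency (~{highest:.0f} Hz)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """True annotations of a simulated recording (all times in seconds).

    ``breath_amplitude`` and ``breath_area`` are defined on the noise-free
    modulation envelope, not on any realized envelope estimate.
    """

    breath_onsets: np.ndarray
    breath_peaks: np.ndarray
    breath_offsets: np.ndarray
    breath_amplitude: np.ndarray   # µV
    breath_area: np.ndarray        # µV·s
    qrs_peaks: np.ndarray
    spec: SynthSpec = field(repr=False, default=None)


def _shape_profile(u: np.ndarray, shape: str) -> np.ndarray:
    """Unit-peak breath profile on normalized inspiratory time u in [0, 1]."""
    y = np.zeros_like(u)
    m = (u >= 0) & (u <= 1)
    if shape == "halfsine":
        y[m] = np.sin(np.pi * u[m])
    elif shape == "gaussian":
        # sigma = 1/6 of the inspiration: ~0.011 residual at the edges
        y[m] = np.exp(-((u[m] - 0.5) ** 2) / (2 * (1.0 / 6.0) ** 2))
    elif shape == "triangle":
        y[m] = 1.0 - np.abs(2.0 * u[m] - 1.0)
    return y


def modulation_envelope(t: np.ndarray, spec: SynthSpec) -> np.ndarray:
    """Noise-free breath modulation envelope (µV) at times ``t``."""
    period = 60.0 / spec.rr
    insp = spec.duty * period
    u = np.mod(t, period) / insp
    return spec.emg_amp * _shape_profile(u, spec.breath_shape)


def _qrs_template(fs: float, width: float) -> np.ndarray:
    """Unit-peak Mexican-hat (second Gaussian derivative) QRS template.

    ``width`` is the nominal QRS complex duration: sigma = width/5 puts the
    main lobe and both side lobes essentially inside ±width/2 (the residual
    at ±width/2 is ~3% of the peak), with the tail truncated at ±width.
    """
    half = int(round(width * fs))
    tt = np.arange(-half, half + 1) / fs
    sigma = width / 5.0
    z = tt / sigma
    return (1.0 - z ** 2) * np.exp(-(z ** 2) / 2.0)


def simulate_semg(spec: SynthSpec) -> tuple[TimeSeriesGroup, GroundTruth]:
    """Generate one contaminated sEMG channel plus its ground truth.

    The EMG channel is ``noise_floor * w1(t) + emg_amp * shape(t) * w2(t)``
    with independent zero-mean unit-variance white-noise streams w1, w2, plus
    the QRS train, wander and powerline sinusoids. Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    env = modulation_envelope(t, spec)
    x = spec.noise_floor * rng.standard_normal(n)
    x += env * rng.standard_normal(n)

    # QRS train: first beat offset into the recording so its template fits
    beat_period = 60.0 / spec.hr
    first_beat = min(0.3, beat_period / 2.0)
    qrs_times = np.arange(first_beat, spec.duration - spec.qrs_width,
                          beat_period)
    if spec.ecg_amp > 0:
        template = spec.ecg_amp * _qrs_template(spec.fs, spec.qrs_width)
        half = (template.size - 1) // 2
        for tb in qrs_times:
            c = int(round(tb * spec.fs))
            lo, hi = c - half, c + half + 1
            tlo = max(0, -lo)
            thi = template.size - max(0, hi - n)
            x[max(0, lo):min(n, hi)] += template[tlo:thi]

    if spec.wander_amp > 0:
        x += spec.wander_amp * np.sin(2 * np.pi * spec.wander_freq * t)
    if spec.powerline_amp > 0:
        x += spec.powerline_amp * np.sin(2 * np.pi * spec.powerline_freq * t)

    period = 60.0 / spec.rr
    insp = spec.duty * period
    n_breaths = int(np.floor((spec.duration - 1e-9) / period)) + 1
    onsets = np.arange(n_breaths) * period
    # keep only breaths whose inspiration completes within the recording
    keep = onsets + insp <= spec.duration
    onsets = onsets[keep]
    offsets = onsets + insp
    peaks = onsets + insp / 2.0

    # true per-breath area of the modulation envelope (closed forms)
    if spec.breath_shape == "halfsine":
        area_unit = 2.0 / np.pi * insp
    elif spec.breath_shape == "triangle":
        area_unit = 0.5 * insp
    else:  # gaussian, sigma = insp/6, truncated at ±3 sigma
        from scipy.stats import norm
        sigma = insp / 6.0
        area_unit = sigma * np.sqrt(2 * np.pi) * (2 * norm.cdf(3.0) - 1.0)
    areas = np.full(onsets.size, spec.emg_amp * area_unit)
    amps = np.full(onsets.size, spec.emg_amp)

    ts = TimeSeries(samples=x, fs=spec.fs, label="sEMGdi", units="uV")
    truth = GroundTruth(breath_onsets=onsets, breath_peaks=peaks,
                        breath_offsets=offsets, breath_amplitude=amps,
                        breath_area=areas, qrs_peaks=qrs_times, spec=spec)
    return TimeSeriesGroup([ts]), truth


def simulate_ventilator(spec: SynthSpec,
                        occlusion_breath_indices=(),
                        peep: float = 5.0,
                        support_pressure: float = 10.0,
                        occlusion_depth: float = 10.0) -> TimeSeries:
    """Ventilator pressure channel aligned with :func:`simulate_semg` breaths.

    Supported breaths carry a positive-pressure boxcar above PEEP over the
    inspiration; occluded breaths are replaced by a negative half-sine
    deflection time-locked to the breath onset. Pressures in cmH2O.
    """
    spec.validate()
    occ = np.asarray(occlusion_breath_indices, dtype=int)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    period = 60.0 / spec.rr
    insp = spec.duty * period
    onsets = np.arange(int(np.floor((spec.duration - 1e-9) / period)) + 1) * period
    onsets = onsets[onsets + insp <= spec.duration]
    if occ.size and (occ.min() < 0 or occ.max() >= onsets.size):
        raise InputError(
            f"occlusion indices out of range [0, {onsets.size - 1}]")
    p = np.full(n, peep)
    for i, t0 in enumerate(onsets):
        lo = int(round(t0 * spec.fs))
        hi = min(n, int(round((t0 + insp) * spec.fs)))
        if i in occ:
            u = (t[lo:hi] - t0) / insp
            p[lo:hi] = peep - occlusion_depth * np.sin(np.pi * u)
        else:
            p[lo:hi] = peep + support_pressure
    return TimeSeries(samples=p, fs=spec.fs, label="Paw", units="cmH2O")
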