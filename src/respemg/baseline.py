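"""Moving baselines under the envelope: running percentile and slope-sum.

The moving baseline estimates the tonic (non-breath) envelope level, the
reference against which breaths are detected and measured. The percentile
baseline takes a low running percentile (default the 33rd over a 7.5 s
window) so that quiet expiratory stretches dominate; the slope-sum variant
first augments the envelope with a fraction of its smoothed derivative to
better track rapid respiratory changes, then applies the same running
percentile.

The percentile is evaluated every ``step`` seconds (granularity vs speed
trade-off) with linear interpolation in between. Both baselines are
translation-equivariant: baseline(env + c) = baseline(env) + c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import InputError
from .envelope import EnvelopeSignal, _rolling_sums

__all__ = ["BaselineSpec", "MovingBaseline", "percentile_baseline",
           "slopesum_baseline"]


@dataclass
class BaselineSpec:
    window: float = 7.5            # s, smoothing window
    percentile: float = 33.0       # running percentile in [0, 100]
    step: float = 0.2              # s between percentile evaluations
    augmented_fraction: float = 0.25  # slope-sum only
    derivative_smooth: float = 0.2    # s, moving average before differencing

    def validate(self) -> None:
        if not 0 < self.step <= self.window:
            raise InputError(
                f"need window >= step > 0, got window={self.window}, "
                f"step={self.step}")
        if not 0 <= self.percentile <= 100:
            raise InputError(f"percentile must be in [0, 100], got {self.percentile}")
        if self.augmented_fraction < 0:
            raise InputError("augmented_fraction must be >= 0")


@dataclass
class MovingBaseline:
    """Per-sample baseline level aligned to an envelope."""

    values: np.ndarray
    fs: float
    spec: BaselineSpec


def _running_percentile(vals: np.ndarray, fs: float, spec: BaselineSpec) -> np.ndarray:
    n = vals.size
    w = int(round(spec.window * fs))
    if w >= n:
        warnings.warn(
            f"baseline window {spec.window} s exceeds the recording; using a "
            "single global percentile", UserWarning, stacklevel=3)
        return np.full(n, np.percentile(vals, spec.percentile))
    step = max(1, int(round(spec.step * fs)))
    pts = np.arange(0, n, step)
    if pts[-1] != n - 1:
        pts = np.append(pts, n - 1)
    out = np.empty(pts.size)
    half = w // 2
    for j, p in enumerate(pts):
        lo = max(0, p - half)
        hi = min(n, lo + w)
        lo = max(0, hi - w)
        out[j] = np.percentile(vals[lo:hi], spec.percentile)
    return np.interp(np.arange(n), pts, out)


def percentile_baseline(env: EnvelopeSignal,
                        spec: BaselineSpec | None = None) -> MovingBaseline:
    """Running percentile of the envelope over a centered window."""
    if spec is None:
        spec = BaselineSpec()
    spec.validate()
    return MovingBaseline(values=_running_percentile(env.values, env.fs, spec),
                          fs=env.fs, spec=spec)


def slopesum_baseline(env: EnvelopeSignal,
                      spec: BaselineSpec | None = None) -> MovingBaseline:
    """Running percentile of env + augmented_fraction * smoothed(d env/dt).

    With augmented_fraction = 0 (or a constant envelope) this reduces exactly
    to :func:`percentile_baseline`.
    """
    if spec is None:
        spec = BaselineSpec()
    spec.validate()
    vals = env.values
    if spec.augmented_fraction > 0:
        deriv = np.gradient(vals) * env.fs  # µV/s
        k = max(2, int(round(spec.derivative_smooth * env.fs)))
        s, cnt = _rolling_sums(deriv, k)
        vals = vals + spec.augmented_fraction * (s / cnt)
    return MovingBaseline(values=_running_percentile(vals, env.fs, spec),
                          fs=env.fs, spec=spec)
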