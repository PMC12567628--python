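"""Butterworth band-pass and notch filtering of raw sEMG.

Respiratory sEMG power sits roughly between 10 and 500 Hz with most of it
between 20 and 150 Hz; baseline wander lives below 0.5 Hz and movement
artifacts below ~20 Hz. The default band-pass (20–500 Hz, order 3) removes
both without eating much muscle signal.

All filters are applied forward-backward (zero phase): notch and band-pass
filters would otherwise introduce phase distortion near their edges. The
effective magnitude response of a bidirectional pass is the *square* of the
single-pass response (−3 dB becomes −6 dB at the cutoffs); tests and
documentation account for this. Filters are realized as cascaded second-order
sections for numerical stability up to order 8, with reflect padding before
the bidirectional pass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data import InputError, TimeSeries

logger = logging.getLogger(__name__)

__all__ = ["FilterSpec", "emg_bandpass", "notch_filter"]


@dataclass
class FilterSpec:
    """Band-pass parameters: high-pass cutoff < low-pass cutoff < fs/2."""

    cf_hp: float = 20.0    # Hz
    cf_lp: float = 500.0   # Hz
    order: int = 3

    def validate(self, fs: float) -> None:
        if not 1 <= self.order <= 8:
            raise InputError(f"filter order must be in [1, 8], got {self.order}")
        if not 0 < self.cf_hp < self.cf_lp:
            raise InputError(
                f"need 0 < cf_hp < cf_lp, got hp={self.cf_hp}, lp={self.cf_lp}")
        nyq = fs / 2.0
        if self.cf_lp >= nyq:
            raise InputError(
                f"low-pass cutoff {self.cf_lp} Hz is at or above the Nyquist "
                f"limit {nyq} Hz; lower cf_lp below fs/2 (e.g. {0.9 * nyq:.0f} Hz)")
        if self.cf_lp > 0.95 * nyq:
            warnings.warn(
                f"low-pass cutoff {self.cf_lp} Hz leaves <5% margin to the "
                f"Nyquist limit {nyq} Hz", UserWarning, stacklevel=2)


def _sos_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    return sps.butter(spec.order, [spec.cf_hp, spec.cf_lp],
                      btype="bandpass", fs=fs, output="sos")


def _filtfilt_sos(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # reflect padding, 3x the impulse-response-scale pad scipy derives
    padlen = min(x.size - 1, 3 * 6 * sos.shape[0])
    return sps.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def emg_bandpass(ts: TimeSeries, spec: FilterSpec | None = None) -> TimeSeries:
    """Zero-phase Butterworth band-pass; same length and fs as the input.

    The band-pass is designed directly (single band-pass prototype of the
    requested order, i.e. 2*order poles), not as a high-pass/low-pass cascade.
    """
    if spec is None:
        spec = FilterSpec()
    spec.validate(ts.fs)
    sos = _sos_bandpass(spec, ts.fs)
    y = _filtfilt_sos(sos, ts.samples)
    return ts.copy_with(y)


def notch_filter(ts: TimeSeries, notch_freq: float, notch_q: float = 30.0) -> TimeSeries:
    """Zero-phase narrow-band rejection at ``notch_freq`` (powerline)."""
    if not 0 < notch_freq < ts.fs / 2:
        raise InputError(
            f"notch frequency must be in (0, fs/2), got {notch_freq} Hz "
            f"at fs={ts.fs}")
    if not notch_q > 0:
        raise InputError(f"notch_q must be > 0, got {notch_q}")
    b, a = sps.iirnotch(notch_freq, notch_q, fs=ts.fs)
    padlen = min(ts.n_samples - 1, 3 * max(len(a), len(b)) * 10)
    y = sps.filtfilt(b, a, ts.samples, padtype="even", padlen=padlen)
    return ts.copy_with(y)
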