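"""Core data model: single-channel time series, channel groups, peak sets, I/O.

All downstream modules consume :class:`TimeSeries` / :class:`TimeSeriesGroup`
objects, never raw files. The layout convention is channels x samples, sample
``i`` occurs at time ``i / fs`` seconds (0-based indexing, half-open windows
``[start, end)`` throughout the package). The sampling rate is never inferred
from CSV/NPY files; it is always an explicit argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InputError",
    "TimeSeries",
    "TimeSeriesGroup",
    "PeakSet",
    "load_csv",
    "write_csv",
    "load_npy",
    "write_npy",
    "write_features_csv",
    "read_features_csv",
]


class InputError(ValueError):
    """Raised for malformed input data or invalid parameter combinations."""


def _clean_samples(samples, fill_nan: bool, context: str) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise InputError(f"{context}: samples must be 1-D, got shape {x.shape}")
    if x.size < 1:
        raise InputError(f"{context}: empty channel")
    bad = ~np.isfinite(x)
    if bad.any():
        if not fill_nan:
            i = int(np.flatnonzero(bad)[0])
            raise InputError(
                f"{context}: non-finite value at sample {i} "
                "(pass fill_nan=True to interpolate)"
            )
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise InputError(f"{context}: all samples non-finite")
        x = x.copy()
        x[bad] = np.interp(np.flatnonzero(bad), good, x[good])
        logger.info("%s: filled %d non-finite samples by linear interpolation",
                    context, int(bad.sum()))
    return x


@dataclass
class TimeSeries:
    """One uniformly sampled signal channel.

    Parameters
    ----------
    samples : array-like, shape (n,)
        Signal values (typically µV for EMG, cmH2O for airway pressure).
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Free-text channel name.
    units : str
        Free-text unit string; metadata only, never rescaled silently.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    units: str = "uV"
    fill_nan: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.samples = _clean_samples(
            self.samples, self.fill_nan, f"channel '{self.label}'")
        self.fs = float(self.fs)
        if not self.fs > 0:
            raise InputError(f"fs must be > 0, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording span in seconds (n / fs)."""
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds; sample i is at i / fs."""
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, samples: np.ndarray, label: str | None = None) -> "TimeSeries":
        return TimeSeries(samples=np.asarray(samples, dtype=float),
                          fs=self.fs,
                          label=self.label if label is None else label,
                          units=self.units)


class TimeSeriesGroup:
    """Ordered collection of channels sharing sampling rate and length."""

    def __init__(self, channels: list[TimeSeries]):
        if len(channels) == 0:
            raise InputError("TimeSeriesGroup requires at least one channel")
        fs0 = channels[0].fs
        n0 = channels[0].n_samples
        for c in channels:
            if c.fs != fs0:
                raise InputError(
                    f"channel '{c.label}' has fs={c.fs}, expected {fs0}")
            if c.n_samples != n0:
                raise InputError(
                    f"ragged group: channel '{c.label}' has {c.n_samples} "
                    f"samples, expected {n0}")
        self.channels = list(channels)

    @property
    def fs(self) -> float:
        return self.channels[0].fs

    @property
    def n_samples(self) -> int:
        return self.channels[0].n_samples

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)

    def __getitem__(self, key) -> TimeSeries:
        if isinstance(key, str):
            for c in self.channels:
                if c.label == key:
                    return c
            raise KeyError(f"no channel labelled '{key}'")
        return self.channels[key]

    def to_array(self) -> np.ndarray:
        """Stack into the standard channels x samples array."""
        return np.vstack([c.samples for c in self.channels])


# ---------------------------------------------------------------------------
# File I/O (CSV and NPY only)
# ---------------------------------------------------------------------------

def _locate_bad_cell(df: pd.DataFrame) -> tuple[int, str]:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            row = int(np.flatnonzero(newly_bad.to_numpy())[0])
            return row, str(col)
    return -1, ""


def load_csv(path, fs: float, has_header: bool = True,
             channels_in: str = "columns", fill_nan: bool = False) -> TimeSeriesGroup:
    """Read a numeric CSV into a channel group.

    By default columns are channels and rows are samples (long recordings sit
    naturally row-major in spreadsheets); pass ``channels_in='rows'`` to
    transpose. ``fs`` is required — CSV does not embed it.
    """
    path = Path(path)
    if channels_in not in ("columns", "rows"):
        raise InputError("channels_in must be 'columns' or 'rows'")
    if not fs > 0:
        raise InputError(f"fs must be > 0, got {fs}")
    try:
        df = pd.read_csv(path, header=0 if has_header else None,
                         skip_blank_lines=True, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: malformed CSV ({exc})") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InputError(f"{path}: no data")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    row, col = _locate_bad_cell(df)
    if col:
        raise InputError(
            f"{path}: non-numeric cell at data row {row}, column '{col}'")
    values = numeric.to_numpy(dtype=float)
    if channels_in == "columns":
        labels = [str(c) for c in df.columns] if has_header else \
            [f"ch{i}" for i in range(values.shape[1])]
        data = values.T
    else:
        labels = [f"ch{i}" for i in range(values.shape[0])]
        data = values
    channels = [TimeSeries(samples=data[i], fs=fs, label=labels[i],
                           fill_nan=fill_nan)
                for i in range(data.shape[0])]
    return TimeSeriesGroup(channels)


def write_csv(group: TimeSeriesGroup, path, channels_in: str = "columns") -> None:
    """Write a channel group to CSV (inverse of :func:`load_csv`)."""
    arr = group.to_array()
    if channels_in == "columns":
        df = pd.DataFrame(arr.T, columns=group.labels)
        df.to_csv(path, index=False, float_format="%.17g")
    elif channels_in == "rows":
        pd.DataFrame(arr).to_csv(path, index=False, header=False,
                                 float_format="%.17g")
    else:
        raise InputError("channels_in must be 'columns' or 'rows'")


def load_npy(path, fs: float, channel_labels: list[str] | None = None,
             fill_nan: bool = False) -> TimeSeriesGroup:
    """Read a 1-D or 2-D ``.npy`` array (2-D interpreted channels x samples)."""
    arr = np.load(path, allow_pickle=False)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise InputError(
            f"{path}: expected 1-D or 2-D array, got {arr.ndim}-D")
    n_ch = arr.shape[0]
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_ch)]
    if len(channel_labels) != n_ch:
        raise InputError(
            f"{path}: {len(channel_labels)} labels for {n_ch} channels")
    channels = [TimeSeries(samples=arr[i].astype(float), fs=fs,
                           label=channel_labels[i], fill_nan=fill_nan)
                for i in range(n_ch)]
    return TimeSeriesGroup(channels)


def write_npy(group: TimeSeriesGroup, path) -> None:
    np.save(path, group.to_array())


# ---------------------------------------------------------------------------
# PeakSet
# ---------------------------------------------------------------------------

#: flags that invalidate a waveform when set
INVALIDATING_FLAGS = ("onset_after_peak", "offset_before_peak",
                      "peak_below_baseline", "zero_slope_flank")


class PeakSet:
    """Per-breath peak/onset/offset indices with validity flags and features.

    Invariants: waveforms are sorted by ``peak_idx``; for every valid waveform
    ``start_idx <= peak_idx <= end_idx``. Flags are the complete explanation of
    invalidity — no waveform is silently dropped.
    """

    def __init__(self, peak_idx, start_idx, end_idx, fs: float,
                 n_samples: int | None = None):
        self.peak_idx = np.asarray(peak_idx, dtype=int)
        self.start_idx = np.asarray(start_idx, dtype=int)
        self.end_idx = np.asarray(end_idx, dtype=int)
        if not (self.peak_idx.size == self.start_idx.size == self.end_idx.size):
            raise InputError("peak/start/end index arrays must have equal length")
        if np.any(np.diff(self.peak_idx) < 0):
            raise InputError("waveforms must be sorted by peak_idx")
        for name, idx in (("peak_idx", self.peak_idx),
                          ("start_idx", self.start_idx),
                          ("end_idx", self.end_idx)):
            if idx.size and idx.min() < 0:
                raise InputError(f"{name} contains negative indices")
            if n_samples is not None and idx.size and idx.max() >= n_samples:
                raise InputError(f"{name} exceeds signal length {n_samples}")
        self.fs = float(fs)
        self.n_samples = n_samples
        n = self.peak_idx.size
        self.flags = pd.DataFrame(index=pd.RangeIndex(n))
        self.features = pd.DataFrame(index=pd.RangeIndex(n))

    def __len__(self) -> int:
        return self.peak_idx.size

    @property
    def peak_times(self) -> np.ndarray:
        return self.peak_idx / self.fs

    @property
    def valid(self) -> np.ndarray:
        """True where no invalidating flag is set."""
        v = np.ones(len(self), dtype=bool)
        for name in self.flags.columns:
            if name in INVALIDATING_FLAGS:
                v &= ~self.flags[name].to_numpy(dtype=bool)
        return v

    def set_flag(self, name: str, values) -> None:
        self.flags[name] = np.asarray(values, dtype=bool)

    def set_feature(self, name: str, values) -> None:
        self.features[name] = np.asarray(values, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate indices, times, features and flags in deterministic order."""
        df = pd.DataFrame({
            "peak_idx": self.peak_idx,
            "start_idx": self.start_idx,
            "end_idx": self.end_idx,
            "peak_time_s": self.peak_idx / self.fs,
            "start_time_s": self.start_idx / self.fs,
            "end_time_s": self.end_idx / self.fs,
            "valid": self.valid,
        })
        for name in sorted(self.features.columns):
            df[name] = self.features[name].to_numpy()
        for name in sorted(self.flags.columns):
            df[name] = self.flags[name].to_numpy(dtype=bool)
        return df


def write_features_csv(peakset: PeakSet, path) -> None:
    """One row per waveform; numbers carry 12+ significant digits."""
    peakset.to_frame().to_csv(path, index=False, float_format="%.15g")


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
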