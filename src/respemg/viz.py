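"""Minimal visualization of the processing cascade."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_stages(result, path) -> None:
    """Plot raw, filtered, ECG-removed and envelope+baseline stages (PNG)."""
    fig, axes = plt.subplots(4, 1, figsize=(10, 8), sharex=True)
    t = result.raw.t
    axes[0].plot(t, result.raw.samples, lw=0.3)
    axes[0].set_ylabel("raw (µV)")
    axes[1].plot(t, result.filtered.samples, lw=0.3)
    axes[1].set_ylabel("filtered (µV)")
    axes[2].plot(t, result.ecg_removed.samples, lw=0.3)
    axes[2].set_ylabel("ECG removed (µV)")
    axes[3].plot(t, result.envelope.values, lw=0.6, label="envelope")
    axes[3].plot(t, result.baseline.values, lw=0.8, label="baseline")
    if len(result.peakset):
        pk = result.peakset.peak_idx
        axes[3].plot(t[pk], result.envelope.values[pk], "v", ms=5,
                     label="breath peaks")
    axes[3].legend(loc="upper right", fontsize=8)
    axes[3].set_xlabel("time (s)")
    axes[3].set_ylabel("sEAdi (µV)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
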