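# Methods

## Problem and signal model

Respiratory surface EMG (sEMG), recorded over the diaphragm or accessory
respiratory muscles, is a stochastic, approximately zero-mean signal whose
variance is modulated by muscle activation. Its useful power lies roughly
between 10 and 500 Hz, most of it between 20 and 150 Hz. Raw recordings are
contaminated by baseline wander (< 0.5 Hz), movement artifacts (< ~20 Hz),
powerline interference (50/60 Hz), and — dominantly — the ECG, whose QRS
complexes exceed the muscle signal in amplitude while overlapping its
spectrum.

The toolkit processes a recording through a fixed cascade: QRS detection on
the raw trace → Butterworth band-pass (optionally plus notch) → ECG removal
(gating or stationary-wavelet denoising) → moving-window envelope (the
surface electrical activity, e.g. sEAdi for the diaphragm) → moving baseline
→ breath event detection → per-breath features → quality assessment.

## Filtering

Filters are Butterworth designs realized as cascaded second-order sections
and applied forward–backward (zero phase) with reflect padding. Bidirectional
application squares the magnitude response: the −3 dB cutoff of the design
becomes −6 dB in effect. The band-pass is a single band-pass design of the
requested order (2·order poles), not a high-pass/low-pass cascade; its exact
gain at any frequency is the closed-form low-pass-prototype magnitude under
the band-pass transform evaluated at bilinear-prewarped frequencies, which
the tests use as an oracle. The Nyquist guard rejects a low-pass cutoff at or
above fs/2 and warns within 5% of it (the published under-filtering setting
of 1000 Hz at fs = 2048 Hz deliberately sits in that warning band).

## QRS detection

`detect_qrs_peaks` expects *unfiltered* input (high-pass filtering distorts
QRS morphology; a warning is raised when the input has near-zero power below
10 Hz). The detector band-passes into the QRS energy band (5–30 Hz), smooths
the trace with a 50 ms running RMS, picks local maxima separated by at least
80% of the shortest credible beat interval, keeps those above half the 95th
percentile of candidate heights, refines each detection to the band-passed
extremum, and finally removes detections that would imply a rate above
`max_hr` (keeping the stronger peak). The thresholds are heuristic but
scale-free; on the synthetic generator's conditions the detector reaches
100% sensitivity and precision at a 10:1 QRS-to-noise-floor ratio.

## ECG removal

**Gating** blanks `round(gate_width·fs)` samples centered on each QRS peak
(one-sample right bias for even counts; overlapping gates merged) and fills
with: zeros; the mean of the preceding gate-width segment (or the following
one at the recording start); linear interpolation of the raw trace across
the gate; or linear interpolation between the running-RMS envelope levels at
the gate edges. The RMS-interpolation envelope is computed from *ungated
samples only* (a mask-aware running RMS) — computing it naively on the raw
trace lets the QRS energy being removed inflate the fill level, which
reintroduces envelope bumps at every beat. The 0.20 s default covers the
up-to-110 ms healthy QRS with margin; gates much narrower than the QRS leave
residual side lobes that spike the envelope, which the tests reproduce.

**Wavelet denoising** decomposes the signal with an undecimated stationary
wavelet transform (default Daubechies-4; level n = floor(log2(fs/20)), so
the approximation band ends just above 20 Hz and is assumed non-EMG). The
noise-free ECG estimate keeps the full approximation plus every detail
coefficient whose magnitude reaches its level's threshold, computed per
decomposition level as running-MAD / 0.6745 × `fixed_threshold` (running MAD
over 0.5 s, centered, hop one sample, on that level's own coefficients;
0.6745 converts MAD to a normal σ). Thresholding is hard (keep-or-kill).
The estimate is subtracted from the input. Limits: threshold 0 keeps
everything (perfect reconstruction, output ≈ 0); an arbitrarily large
threshold keeps only the approximation (output = detail reconstruction).
The rule is peak-independent; the peaks argument exists for interface
symmetry with gating. Signals are reflect-padded to a multiple of 2^n and
trimmed on return.

## Envelope

Running RMS (sqrt of windowed mean square) and ARV (windowed mean absolute
value), centered windows of `round(window_length·fs)` samples. Centered
alignment keeps peak timing unbiased; at the recording edges the window
shrinks symmetrically instead of padding, so no data is fabricated — edge
estimates are simply noisier, and peak detection ignores candidates within
half a window of the edges for that reason. Confidence bands use the normal
approximation to the windowed mean (CLT): ARV = m ± z·sd/√k on |x|; for RMS
the band is computed on the mean square and mapped through the square root
(delta method). Lower bounds are clipped at zero. Empirical coverage on
white noise at the 95% level with k = 512 is ~0.95.

## Moving baseline

The percentile baseline evaluates a low running percentile (default 33rd,
7.5 s centered window) every `step` = 0.2 s and interpolates linearly; the
step is a pure granularity/speed trade-off, ≪ breath duration and ≫ sample
period. The slope-sum variant first augments the envelope with
`augmented_fraction` (default 0.25) times its smoothed derivative (0.2 s
centered moving average before differencing) to track rapid respiratory
changes, then applies the same running percentile. Both are
translation-equivariant. A 7.5 s window does not follow individual ≤ 3 s
breaths; a 1 s window does, which is the published failure mode of too-short
baseline windows.

## Event detection

Breath peaks are local envelope maxima whose excess over the baseline is at
least `min_prominence_factor` (default 0.5) times the local baseline, with a
minimum separation (default 1 s, higher peak wins). On/offsets come from
either (a) baseline crossing — the last at-or-below-baseline sample before
the peak and the first after it, searched no further than the midpoint to
the neighboring peak to prevent runaway onsets in noisy troughs — or (b)
slope extrapolation — the maximum-magnitude slope of the 50 ms-smoothed
envelope on each flank, its tangent extended to the local baseline level.
For a linear flank the tangent is the flank, so triangle vertices are
recovered exactly; for a concave bell the tangent meets the baseline at or
inside the crossing point, so slope extrapolation yields a *tighter* window
that cuts off shallow feet (this is its practical advantage over crossing,
which drags onsets far into slowly decaying tails). Waveforms are never
dropped: onsets after the peak, offsets before it, peaks at or below
baseline, flat flanks and overlapping windows (closed-interval reading:
sharing a boundary sample counts) are flagged.

Peak linking between tracings is greedy nearest-first one-to-one matching
within a tolerance; on small cases it is verified against brute-force
enumeration of maximum matchings. Breath support labels come from the
airway-pressure deviation from its median within half a breath period of
each peak: a negative deflection exceeding 30% of the recording's largest
deflection marks an occlusion manoeuvre, a positive one a supported breath.

## Features

Per breath (all invariant to a common offset of envelope and baseline, and
linear in envelope gain where dimensionally expected): amplitude =
env − baseline at the peak (µV); ETP = trapezoidal area of
max(env − baseline, 0) over the breath window (µV·s; below-baseline
excursions are counted by AUB, not subtracted here); duration, absolute and
relative time-to-peak; pseudo-slope = amplitude / time-to-peak (µV/s — the
published quantity has these units but no printed formula; this simplest
activation-rate reading is isolated behind one function); respiratory rate =
60 / median inter-peak interval (median for robustness to missed breaths;
mean available).

## Quality assessment

Pseudo-SNR = (env − baseline)/baseline at the peak. AUB = max(0, baseline −
min(env)) × breath duration over the breath window extended by 0.5 s per
side (the window extension is a design choice; the baseline reference is its
mean over that window), also expressed as a percentage of ETP. Locally high
AUB: above 2× the rolling 5-breath median. Extreme ETP: above 3× the
recording median. Bell-curve error: a three-parameter Gaussian (amplitude,
center, width; bounded least squares, center constrained to the breath
window) is fitted to env − baseline, and the L1 residual is expressed as a
percentage of ETP — an exact Gaussian breath scores ~0, a boxcar ~26%.
Recording-level checks: ECG/EMG peak-count ratio ≥ 1.5 (heart must beat
faster than breathing, else the envelope is likely tracking cardiac
residue), respiratory-rate agreement with a reference within 25%, matched
peak timing within a window, and occlusion manoeuvres valid only when
separated by regular breaths. All flag thresholds are placeholders exposed
in configuration; the clinical literature does not fix them.

## Synthetic data generator

The generator emulates a contaminated respiratory sEMG channel as
`noise_floor·w1(t) + emg_amp·shape(t)·w2(t)` with independent unit-variance
white-noise streams, plus a Mexican-hat QRS train (σ = qrs_width/5, nominal
QRS duration 0.1 s), a wander sinusoid (0.25 Hz) and a powerline sinusoid
(50 Hz). Defaults — 2048 Hz, 60 s, 12 breaths/min with Gaussian inspiratory
envelopes occupying 40% of the cycle, 80 beats/min, 5 µV peak modulation
over a 1 µV noise floor, 10 µV QRS — define the study conditions of every
end-to-end test. Rates are constant per recording; ground-truth amplitude
and area are defined on the noise-free modulation envelope. The ventilator
channel is a PEEP level plus positive-pressure boxcars per supported breath
and negative half-sine deflections for occluded ones.

What the generator does *not* emulate: amplitude-modulated white noise is
spectrally flat to Nyquist, whereas real sEMG concentrates between 20 and
150 Hz. Consequently the band-pass presets remove proportionally less signal
here than on patient data, and effect sizes of over-/under-filtering are
smaller than clinically reported (e.g. over-filtering costs ~12% amplitude
on synthetic data against the reported −58% on a patient recording) —
directions agree, magnitudes do not transfer. There is also no heart-rate or
breath-to-breath variability, no P/T waves, and no motion artifacts: passing
tests demonstrate the correctness and the qualitative behaviour of the
processing chain, not clinical performance.

Note the RMS envelope adds the noise floor in quadrature, so the amplitude
estimate env_peak − baseline is biased low by sqrt(b² + s²) − b − s (about
−18% at a 5:1 modulation-to-floor ratio, −10% at 10:1); amplitude-recovery
tests therefore run at 10:1.

## Numerical choices

- Indices are 0-based; windows half-open `[start, end)`; sample i at i/fs.
- Gate arithmetic: `round(w·fs)` samples, `[peak − k//2, peak + (k − k//2))`.
- Equal maxima within a breath: earliest sample wins (NumPy argmax).
- ETP/AUB integrals are trapezoidal over `[start, end]` sample range / fs.
- CSV output carries 15–17 significant digits and is read back with
  round-trip float parsing, so file round trips are value-exact.
- The analysis path contains no randomness; repeated runs on identical input
  and configuration are byte-identical.

## Problem sizes used in the test and acceptance runs

End-to-end measurements use 20 seeded 60 s recordings at 2048 Hz (the
generator defaults) per preset; the confidence-band coverage uses 10⁴
disjoint 512-sample windows; gating contracts use 20 seeded 10 s recordings.
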