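import numpy as np
import pytest
import pywt

from respemg import (GateSpec, SynthSpec, TimeSeries, WaveletSpec,
                     detect_qrs_peaks, emg_bandpass, gate_ecg,
                     percentile_baseline, rolling_envelope, simulate_semg,
                     wavelet_denoise_ecg)
from respemg.data import InputError
from respemg.ecg import default_swt_level, swt_decompose

FS = 2048.0


class TestDetectQrsPeaks:
    def test_clean_ecg_60bpm_found_within_20ms(self):
        spec = SynthSpec(duration=60.0, hr=60.0, emg_amp=0.0, wander_amp=0.0,
                         powerline_amp=0.0, noise_floor=0.05, ecg_amp=1.0,
                         seed=3)
        group, truth = simulate_semg(spec)
        t = detect_qrs_peaks(group[0]) / spec.fs
        assert abs(t.size - 60) <= 1
        for tb in truth.qrs_peaks:
            assert np.min(np.abs(t - tb)) <= 0.020

    def test_zero_signal_returns_empty_with_warning(self):
        ts = TimeSeries(np.zeros(int(5 * FS)), fs=FS)
        with pytest.warns(UserWarning, match="flat"):
            assert detect_qrs_peaks(ts).size == 0

    def test_mixed_emg_ecg_high_sensitivity_and_precision(self):
        # ECG 10x the noise floor, breaths present; 5 seeds here (the
        # 20-seed measurement lives in the acceptance suite)
        sens, prec = [], []
        for seed in range(5):
            group, truth = simulate_semg(SynthSpec(seed=seed))
            t = detect_qrs_peaks(group[0]) / FS
            hit = sum(1 for tb in truth.qrs_peaks
                      if t.size and np.min(np.abs(t - tb)) <= 0.1)
            sens.append(hit / truth.qrs_peaks.size)
            prec.append(hit / max(t.size, 1))
        assert min(sens) >= 0.95 and min(prec) >= 0.95

    def test_filtered_input_warns(self):
        group, _ = simulate_semg(SynthSpec(seed=0))
        filt = emg_bandpass(group[0])
        with pytest.warns(UserWarning, match="high-pass filtered"):
            detect_qrs_peaks(filt)

    def test_intervals_respect_max_hr(self):
        group, _ = simulate_semg(SynthSpec(seed=1))
        pk = detect_qrs_peaks(group[0], max_hr=220.0)
        assert np.all(np.diff(pk) >= FS * 60.0 / 220.0)


class TestGateEcg:
    def test_gate_window_arithmetic_and_zero_fill(self, rng):
        x = rng.normal(size=int(2 * FS))
        ts = TimeSeries(x, fs=FS)
        out = gate_ecg(ts, [1000], GateSpec(gate_width=0.2,
                                            fill_method="zeros"))
        # round(0.2 * 2048) = 410 samples: [1000-205, 1000+205)
        assert np.all(out.samples[795:1205] == 0.0)
        mask = np.ones(x.size, dtype=bool)
        mask[795:1205] = False
        assert np.array_equal(out.samples[mask], x[mask])

    def test_no_peaks_is_identity(self, rng):
        ts = TimeSeries(rng.normal(size=4096), fs=FS)
        out = gate_ecg(ts, [], GateSpec(fill_method="zeros"))
        assert np.array_equal(out.samples, ts.samples)

    def test_zero_fill_is_idempotent(self, rng):
        ts = TimeSeries(rng.normal(size=4096), fs=FS)
        spec = GateSpec(gate_width=0.2, fill_method="zeros")
        once = gate_ecg(ts, [1000, 2000], spec)
        twice = gate_ecg(once, [1000, 2000], spec)
        assert np.array_equal(once.samples, twice.samples)

    @pytest.mark.parametrize("fill", ["zeros", "prior_average", "raw_interp",
                                      "rms_interp"])
    def test_out_of_gate_samples_bit_identical(self, fill, rng):
        x = rng.normal(size=int(4 * FS))
        ts = TimeSeries(x, fs=FS)
        peaks = [2000, 4000, 6000]
        out = gate_ecg(ts, peaks, GateSpec(gate_width=0.2, fill_method=fill))
        mask = np.ones(x.size, dtype=bool)
        for p in peaks:
            mask[p - 205:p + 205] = False
        assert np.array_equal(out.samples[mask], x[mask])

    def test_zero_mean_fills_sit_near_local_mean(self, rng):
        x = rng.normal(size=int(4 * FS))
        ts = TimeSeries(x, fs=FS)
        for fill in ("zeros", "prior_average"):
            out = gate_ecg(ts, [4000], GateSpec(gate_width=0.2,
                                                fill_method=fill))
            assert abs(np.mean(out.samples[3795:4205])) < 0.25

    def test_overlapping_gates_merged(self, rng):
        ts = TimeSeries(rng.normal(size=4096), fs=FS)
        out = gate_ecg(ts, [1000, 1100], GateSpec(gate_width=0.2,
                                                  fill_method="zeros"))
        assert np.all(out.samples[795:1305] == 0.0)

    def test_edge_gate_truncated(self, rng):
        ts = TimeSeries(rng.normal(size=1024), fs=FS)
        out = gate_ecg(ts, [10], GateSpec(gate_width=0.2, fill_method="zeros"))
        assert np.all(out.samples[:215] == 0.0)

    def test_short_gate_leaves_envelope_spikes_long_gate_does_not(self):
        # dominant ECG: gates narrower than the QRS leave residual side
        # lobes that spike the envelope; the 200 ms default covers them
        spec = SynthSpec(seed=5, emg_amp=0.0, wander_amp=0.0,
                         powerline_amp=0.0, ecg_amp=50.0)
        group, truth = simulate_semg(spec)
        filt = emg_bandpass(group[0])
        pk = detect_qrs_peaks(group[0])
        ratios = {}
        for w in (0.05, 0.20):
            gated = gate_ecg(filt, pk, GateSpec(gate_width=w,
                                                fill_method="zeros"))
            env = rolling_envelope(gated)
            bl = percentile_baseline(env)
            r = []
            for tq in truth.qrs_peaks:
                c = int(tq * FS)
                sl = slice(max(0, c - 205), c + 205)
                r.append(np.max(env.values[sl] / bl.values[sl]))
            ratios[w] = np.median(r)
        assert ratios[0.05] > 2.0
        assert ratios[0.20] < 2.0

    def test_unusual_width_warns(self, rng):
        with pytest.warns(UserWarning, match="range"):
            GateSpec(gate_width=0.5).validate()


class TestWaveletDenoise:
    def test_zero_threshold_is_perfect_reconstruction_limit(self, rng):
        ts = TimeSeries(rng.normal(size=int(5 * FS)), fs=FS)
        out = wavelet_denoise_ecg(ts, spec=WaveletSpec(fixed_threshold=0.0))
        rms = np.sqrt(np.mean(ts.samples ** 2))
        assert np.max(np.abs(out.samples)) < 1e-8 * rms

    def test_huge_threshold_leaves_detail_reconstruction(self, rng):
        ts = TimeSeries(rng.normal(size=int(5 * FS)), fs=FS)
        out = wavelet_denoise_ecg(ts, spec=WaveletSpec(fixed_threshold=1e9))
        level = default_swt_level(FS)
        coeffs, _ = swt_decompose(ts.samples, level, "db4")
        detail_only = pywt.iswt([np.zeros_like(coeffs[0])] + coeffs[1:],
                                "db4", norm=True)[:ts.n_samples]
        err = np.max(np.abs(out.samples - detail_only))
        assert err < 1e-8 * np.sqrt(np.mean(detail_only ** 2))

    def test_default_level_rule(self):
        assert default_swt_level(2048.0) == 6
        assert default_swt_level(1024.0) == 5

    def test_excessive_level_names_max_feasible(self):
        ts = TimeSeries(np.zeros(256), fs=FS)
        with pytest.raises(InputError, match="maximum feasible level"):
            wavelet_denoise_ecg(ts, spec=WaveletSpec(n=12))

    def test_output_power_nondecreasing_in_threshold(self, rng):
        ts = TimeSeries(rng.normal(size=int(3 * 1024)), fs=1024.0)
        powers = [np.mean(wavelet_denoise_ecg(
            ts, spec=WaveletSpec(fixed_threshold=thr)).samples ** 2)
            for thr in (0.0, 2.0, 4.5, 12.0, 1e9)]
        assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_residual_qrs_power_grows_with_threshold(self):
        # higher thresholds keep fewer coefficients in the ECG estimate,
        # leaving more cardiac residue in the denoised EMG
        res = {thr: [] for thr in (4.0, 8.0, 12.0)}
        for seed in range(10):
            spec = SynthSpec(fs=1024.0, duration=20.0, seed=seed,
                             wander_amp=0.0, powerline_amp=0.0)
            group, truth = simulate_semg(spec)
            for thr in res:
                y = wavelet_denoise_ecg(
                    group[0], spec=WaveletSpec(fixed_threshold=thr))
                idx = np.concatenate([
                    np.arange(max(0, int(tq * spec.fs) - 51),
                              min(y.n_samples, int(tq * spec.fs) + 52))
                    for tq in truth.qrs_peaks])
                res[thr].append(np.mean(y.samples[idx] ** 2))
        means = [np.mean(res[thr]) for thr in (4.0, 8.0, 12.0)]
        assert means[0] < means[1] < means[2]
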