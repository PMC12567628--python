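import itertools

import numpy as np
import pytest

from respemg import (BaselineSpec, SynthSpec, detect_peaks,
                     detect_supported_and_occluded, find_linked_peaks,
                     onoffpeak_baseline_crossing,
                     onoffpeak_slope_extrapolation, percentile_baseline,
                     simulate_semg, simulate_ventilator)
from respemg.baseline import MovingBaseline
from respemg.envelope import EnvelopeSignal

FS = 256.0


def make_env(values, fs=FS):
    return EnvelopeSignal(values=np.asarray(values, dtype=float), fs=fs,
                          method="rms", window_length=0.25)


def flat_baseline(n, level, fs=FS):
    return MovingBaseline(values=np.full(n, float(level)), fs=fs, spec=None)


def gaussian_bells(centers, height=3.0, width=0.4, base=1.0, dur=30.0):
    t = np.arange(int(dur * FS)) / FS
    y = np.full(t.size, base)
    for c in centers:
        y += height * np.exp(-((t - c) ** 2) / (2 * width ** 2))
    return make_env(y), flat_baseline(t.size, base)


class TestDetectPeaks:
    def test_env_equal_baseline_no_peaks(self):
        env = make_env(np.full(2000, 1.0))
        assert detect_peaks(env, flat_baseline(2000, 1.0)).size == 0

    def test_two_bells_found_at_centers(self):
        env, bl = gaussian_bells([10.0, 20.0])
        pk = detect_peaks(env, bl)
        assert pk.size == 2
        assert np.allclose(pk / FS, [10.0, 20.0], atol=1 / FS)

    def test_close_peaks_merged_by_separation(self):
        env, bl = gaussian_bells([10.0, 10.5])
        pk = detect_peaks(env, bl, min_separation=1.0)
        assert pk.size == 1

    def test_synth_breaths_recovered(self, default_pipeline_result,
                                     default_recording):
        _, truth = default_recording
        pt = default_pipeline_result.peakset.peak_times
        assert pt.size == truth.breath_peaks.size
        assert np.all(np.abs(pt - truth.breath_peaks) <= 0.25)


class TestBaselineCrossing:
    def test_triangle_on_and_offsets_at_base(self):
        t = np.arange(int(20 * FS)) / FS
        tri = np.clip(1.0 - np.abs(t - 10.0) / 2.0, 0, None)  # base [8, 12]
        env = make_env(0.2 + tri)
        bl = flat_baseline(t.size, 0.2)
        ps = onoffpeak_baseline_crossing(env, bl, [int(10 * FS)])
        assert abs(ps.start_idx[0] - int(8 * FS)) <= 1
        assert abs(ps.end_idx[0] - int(12 * FS)) <= 1
        assert ps.valid[0]

    def test_overlapping_windows_flagged(self):
        # fused bells never dip below the baseline between their peaks, so
        # the two breath windows meet and share the boundary sample
        env, _ = gaussian_bells([10.0, 12.0], width=1.2)
        bl = flat_baseline(env.values.size, 1.05)
        ps = onoffpeak_baseline_crossing(
            env, bl, [int(10 * FS), int(12 * FS)])
        assert ps.flags["window_overlap"].all()
        assert len(ps) == 2  # flagged, not dropped

    def test_peak_below_baseline_flagged_not_dropped(self):
        env = make_env(np.full(2000, 1.0))
        bl = flat_baseline(2000, 2.0)
        ps = onoffpeak_baseline_crossing(env, bl, [1000])
        assert len(ps) == 1
        assert not ps.valid[0]
        assert ps.flags["peak_below_baseline"][0]

    def test_higher_percentile_gives_later_onset_earlier_offset(self):
        # monotone-flanked bell: raising the baseline level moves the
        # crossings inwards, shifting onsets later and offsets earlier
        env, _ = gaussian_bells([15.0], height=3.0, width=0.8)
        starts, ends = [], []
        for p in (10.0, 50.0):
            bl = percentile_baseline(env, BaselineSpec(percentile=p))
            ps = onoffpeak_baseline_crossing(env, bl, [int(15 * FS)])
            starts.append(ps.start_idx[0])
            ends.append(ps.end_idx[0])
        assert starts[1] > starts[0]
        assert ends[1] < ends[0]


class TestSlopeExtrapolation:
    def test_triangle_recovers_vertices(self):
        t = np.arange(int(20 * FS)) / FS
        tri = np.clip(1.0 - np.abs(t - 10.0) / 2.0, 0, None)
        env = make_env(tri)
        ps = onoffpeak_slope_extrapolation(env, [int(10 * FS)])
        # linear flank: tangent equals the flank, intersection is the vertex
        assert abs(ps.start_idx[0] - int(8 * FS)) <= 2
        assert abs(ps.end_idx[0] - int(12 * FS)) <= 2

    def test_bell_tangent_cuts_off_shallow_foot(self):
        # the tangent through the steepest flank point excludes the shallow
        # Gaussian foot that the baseline crossing includes, giving a
        # tighter breath window ordered around the peak
        env, bl = gaussian_bells([15.0], height=3.0, width=0.8, base=1.0)
        peaks = [int(15 * FS)]
        cross = onoffpeak_baseline_crossing(env, bl, peaks)
        slope = onoffpeak_slope_extrapolation(env, peaks, baseline=bl)
        assert slope.start_idx[0] < slope.peak_idx[0] < slope.end_idx[0]
        assert slope.start_idx[0] > cross.start_idx[0]
        assert slope.end_idx[0] < cross.end_idx[0]

    def test_flat_envelope_all_invalid(self):
        env = make_env(np.full(2000, 1.0))
        ps = onoffpeak_slope_extrapolation(env, [1000])
        assert not ps.valid[0]
        assert ps.flags["zero_slope_flank"][0]


class TestFindLinkedPeaks:
    def test_identical_lists_fully_matched(self):
        pairs, ua, ub = find_linked_peaks([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                          tolerance=0.1)
        assert pairs == [(0, 0), (1, 1), (2, 2)]
        assert ua == [] and ub == []

    def test_partial_match_with_unmatched_reported(self):
        pairs, ua, ub = find_linked_peaks([1.0, 2.0, 3.0], [1.05, 2.9],
                                          tolerance=0.2)
        assert pairs == [(0, 0), (2, 1)]
        assert ua == [1] and ub == []

    def test_empty_b_all_unmatched(self):
        pairs, ua, ub = find_linked_peaks([1.0, 2.0], [], tolerance=0.5)
        assert pairs == [] and ua == [0, 1]

    def test_greedy_matches_agree_with_brute_force_on_small_cases(self, rng):
        # oracle: enumerate all one-to-one matchings within tolerance and
        # verify the greedy result is one of maximum cardinality
        for _ in range(30):
            a = np.sort(rng.uniform(0, 10, size=rng.integers(1, 5)))
            b = np.sort(rng.uniform(0, 10, size=rng.integers(1, 5)))
            tol = 1.0
            pairs, _, _ = find_linked_peaks(a, b, tol)
            ok = [(i, j) for i in range(a.size) for j in range(b.size)
                  if abs(a[i] - b[j]) <= tol]
            best = 0
            for r in range(len(ok), 0, -1):
                for combo in itertools.combinations(ok, r):
                    ii = [p[0] for p in combo]
                    jj = [p[1] for p in combo]
                    if len(set(ii)) == r and len(set(jj)) == r:
                        best = r
                        break
                if best:
                    break
            assert len(pairs) == best


class TestSupportedOccluded:
    def test_synth_occlusion_labelled(self):
        spec = SynthSpec(duration=30.0, seed=2)
        _, truth = simulate_semg(spec)
        pressure = simulate_ventilator(spec, occlusion_breath_indices=[3])
        labels = detect_supported_and_occluded(pressure, truth.breath_peaks)
        assert labels[3] == "occluded"
        assert all(lab == "supported" for i, lab in enumerate(labels)
                   if i != 3)

    def test_zero_pressure_no_labels(self):
        from respemg import TimeSeries
        spec = SynthSpec(duration=30.0, seed=2)
        _, truth = simulate_semg(spec)
        flat = TimeSeries(np.full(int(30 * spec.fs), 5.0), fs=spec.fs)
        labels = detect_supported_and_occluded(flat, truth.breath_peaks)
        assert all(lab is None for lab in labels)

    def test_missing_pressure_warns_none(self):
        with pytest.warns(UserWarning, match="pressure"):
            labels = detect_supported_and_occluded(None, [1.0, 2.0])
        assert labels == [None, None]

    def test_all_positive_boxcars_supported(self):
        spec = SynthSpec(duration=30.0, seed=2)
        _, truth = simulate_semg(spec)
        pressure = simulate_ventilator(spec)
        labels = detect_supported_and_occluded(pressure, truth.breath_peaks)
        assert all(lab == "supported" for lab in labels)
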