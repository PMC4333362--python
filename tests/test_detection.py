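import warnings

import numpy as np
import pytest

import gazefix as gf
from gazefix.detection import segment_by_velocity, interpolate_gaps
from gazefix.preprocessing import SmoothingParams, compute_velocity

from conftest import DPP, DT, FS, make_trace


def rle_oracle(labels):
    """Independent run-length encoder: list of (label, start, stop)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    return runs


def oracle_labels(trace, v, threshold):
    """Per-sample labels computed independently of the implementation."""
    out = []
    for i in range(trace.n_samples):
        if not trace.available[i]:
            out.append("gap")
        elif np.isfinite(v.v[i]) and v.v[i] > threshold:
            out.append("saccade")
        else:
            out.append("fixation")
    return out


def random_trace(seed, n=1000):
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(0, 8, n)) + 800
    y = np.cumsum(rng.normal(0, 8, n)) + 500
    avail = rng.random(n) > 0.15
    return make_trace(x, y, available=avail)


class TestSegmentByVelocity:
    def test_constant_trace_single_fixation(self):
        trace = make_trace(np.full(30, 100.0))
        v = compute_velocity(trace, DPP)
        seg = segment_by_velocity(trace, v, 9.0)
        assert len(seg) == 1
        s = seg.segments[0]
        assert s.label == "fixation"
        assert s.onset == 0.0
        assert s.offset == pytest.approx(30 * DT)
        assert (s.start, s.stop) == (0, 30)

    def test_single_spike_three_segments(self):
        # one big displacement at sample k -> fixation, 1-sample saccade, fixation
        k = 10
        x = np.zeros(25)
        x[k + 1:] = 100.0
        trace = make_trace(x)
        v = compute_velocity(trace, DPP)
        seg = segment_by_velocity(trace, v, 9.0)
        labels = [s.label for s in seg]
        assert labels == ["fixation", "saccade", "fixation"]
        assert seg.segments[1].n_samples == 1
        assert seg.segments[1].start == k

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_rle_oracle(self, seed):
        trace = random_trace(seed)
        v = compute_velocity(trace, DPP)
        for thr in (9.0, 20.0, 50.0):
            got = segment_by_velocity(trace, v, thr)
            expect = rle_oracle(oracle_labels(trace, v, thr))
            assert [(s.label, s.start, s.stop) for s in got] == expect

    def test_segments_tile_recording(self):
        trace = random_trace(99, n=400)
        v = compute_velocity(trace, DPP)
        seg = segment_by_velocity(trace, v, 20.0)
        assert seg.segments[0].start == 0
        assert seg.segments[-1].stop == trace.n_samples
        for a, b in zip(seg.segments, seg.segments[1:]):
            assert a.stop == b.start
            assert a.offset == b.onset
            assert a.label != b.label

    def test_threshold_monotone_in_saccade_samples(self):
        trace = random_trace(5)
        v = compute_velocity(trace, DPP)
        counts = []
        for thr in (5.0, 10.0, 20.0, 40.0, 80.0):
            seg = segment_by_velocity(trace, v, thr)
            counts.append(sum(s.n_samples for s in seg.by_label("saccade")))
        assert counts == sorted(counts, reverse=True)

    def test_all_missing_warns(self):
        trace = make_trace(np.full(20, np.nan))
        v = compute_velocity(trace, DPP)
        with pytest.warns(UserWarning, match="missing"):
            seg = segment_by_velocity(trace, v, 9.0)
        assert seg.by_label("fixation") == []


def _gapped_fixation_trace(gap_start, gap_len, n=60, step=None):
    """Constant fixation with a missing run; optional position step across it."""
    x = np.full(n, 500.0)
    if step:
        x[gap_start + gap_len:] += step
    avail = np.ones(n, dtype=bool)
    avail[gap_start:gap_start + gap_len] = False
    return make_trace(x, np.full(n, 400.0), available=avail)


class TestInterpolateGaps:
    def test_gap_longer_than_latency_untouched(self, high_params):
        # ~70 ms gap (9 samples at 120 Hz) vs latency 60 ms
        trace = _gapped_fixation_trace(20, 9)
        v = compute_velocity(trace, DPP)
        out, n = interpolate_gaps(trace, v, high_params)
        assert n == 0
        np.testing.assert_array_equal(out.available, trace.available)

    def test_short_gap_same_centroid_filled(self, high_params):
        # ~40 ms gap (5 samples) inside one fixation
        trace = _gapped_fixation_trace(20, 5)
        v = compute_velocity(trace, DPP)
        out, n = interpolate_gaps(trace, v, high_params)
        assert n == 1
        assert out.available.all()
        assert out.interpolated[20:25].all()
        assert not out.interpolated[:20].any()
        # recomputed velocity has no spike at the former gap
        v2 = compute_velocity(out, DPP)
        seg = gf.segment_by_velocity(out, v2, high_params.velocity_threshold)
        assert [s.label for s in seg] == ["fixation"]

    def test_displacement_gate_blocks_fill(self, high_params):
        # flanking centroids 1.0 deg apart > 0.25 deg gate
        trace = _gapped_fixation_trace(20, 5, step=1.0 / DPP)
        v = compute_velocity(trace, DPP)
        out, n = interpolate_gaps(trace, v, high_params)
        assert n == 0
        assert not out.available[20:25].any()

    def test_displacement_just_under_gate_fills(self, high_params):
        trace = _gapped_fixation_trace(20, 5, step=0.2 / DPP)
        v = compute_velocity(trace, DPP)
        _, n = interpolate_gaps(trace, v, high_params)
        assert n == 1

    def test_edge_gap_never_filled(self, high_params):
        trace = _gapped_fixation_trace(0, 4)
        v = compute_velocity(trace, DPP)
        out, n = interpolate_gaps(trace, v, high_params)
        assert n == 0
        assert not out.available[:4].any()

    def test_available_samples_never_modified(self, high_params, rng):
        x = 500 + rng.normal(0, 2, 80)
        avail = rng.random(80) > 0.2
        trace = make_trace(x, available=avail)
        v = compute_velocity(trace, DPP)
        out, _ = interpolate_gaps(trace, v, high_params)
        np.testing.assert_array_equal(out.x[avail], trace.x[avail])
        np.testing.assert_array_equal(out.y[avail], trace.y[avail])
        assert out.available[avail].all()

    def test_zero_latency_disables(self, high_params):
        trace = _gapped_fixation_trace(20, 5)
        v = compute_velocity(trace, DPP)
        _, n = interpolate_gaps(
            trace, v, high_params.replace(interpolation_latency=0.0)
        )
        assert n == 0

    def test_linear_fill_values(self, high_params):
        x = np.full(40, 100.0)
        x[25:] = 103.0
        avail = np.ones(40, dtype=bool)
        avail[22:25] = False
        trace = make_trace(x, available=avail)
        v = compute_velocity(trace, DPP)
        out, n = interpolate_gaps(trace, v, high_params)
        assert n == 1
        np.testing.assert_allclose(out.x[22:25], [100.75, 101.5, 102.25])


class TestDetectFixations:
    def test_noise_free_recovery(self, high_params):
        params = gf.SimulationParams(
            seed=1, n_fixations=10, fixation_duration_ms=(200, 800),
            saccade_duration_ms=30, saccade_amplitude_deg=5.0, noise_rms=0.0,
        )
        rec, truth = gf.simulate_recording(params)
        result = gf.detect_fixations(rec, high_params)
        assert len(result.fixations.surviving) == 10
        rep = gf.score_recovery(result.fixations, truth)
        assert rep.hit_rate == 1.0
        assert rep.mean_onset_error_ms <= DT
        assert rep.mean_offset_error_ms <= DT

    def test_all_missing_zero_fixations(self, high_params):
        rec, _ = gf.simulate_recording(gf.SimulationParams(seed=1, n_fixations=3))
        rec = rec.copy()
        rec.left_valid[:] = False
        rec.right_valid[:] = False
        rec = gf.GazeRecording(
            sampling_rate=rec.sampling_rate, timestamps=rec.timestamps,
            left_x=rec.left_x, left_y=rec.left_y,
            right_x=rec.right_x, right_y=rec.right_y,
            left_valid=rec.left_valid, right_valid=rec.right_valid,
        )
        with pytest.warns(UserWarning, match="missing"):
            result = gf.detect_fixations(rec, high_params)
        assert len(result.fixations.surviving) == 0

    def test_gap_interpolation_toggle_changes_count(self, high_params):
        params = gf.SimulationParams(
            seed=3, n_fixations=10, fixation_duration_ms=(300, 800), noise_rms=0.0,
        )
        rec, truth = gf.simulate_recording(params)
        gapped, ranges = gf.inject_fixation_gaps(
            rec, truth, fraction=0.1, gap_ms=40, seed=5
        )
        assert len(ranges) == 1
        # merge cannot bridge the 40 ms gap here, isolating interpolation
        dp = high_params.replace(merge_max_gap=30.0)
        with_interp = gf.detect_fixations(gapped, dp)
        without = gf.detect_fixations(
            gapped, dp.replace(interpolation_latency=0.0)
        )
        assert len(with_interp.fixations.surviving) == 10
        assert len(without.fixations.surviving) == 11

    def test_deterministic(self, high_params):
        rec, _ = gf.simulate_recording(
            gf.SimulationParams(seed=8, n_fixations=8, noise_rms=0.15,
                                gap_rate_hz=0.5)
        )
        r1 = gf.detect_fixations(rec, high_params)
        r2 = gf.detect_fixations(rec, high_params)
        assert len(r1.fixations.surviving) == len(r2.fixations.surviving)
        for a, b in zip(r1.fixations.surviving, r2.fixations.surviving):
            assert (a.onset, a.offset, a.centroid_x, a.centroid_y, a.rms) == \
                   (b.onset, b.offset, b.centroid_x, b.centroid_y, b.rms)

    def test_surviving_fixations_respect_thresholds(self, low_params):
        rec, _ = gf.simulate_recording(
            gf.SimulationParams(seed=13, n_fixations=15, noise_rms=0.3,
                                gap_rate_hz=1.0)
        )
        result = gf.detect_fixations(rec, low_params)
        for f in result.fixations.surviving:
            assert f.rms <= low_params.max_rms_per_fixation
            assert f.duration >= low_params.min_fixation_duration

    def test_high_threshold_merges_across_small_saccades(self):
        # a 2-px saccade at 120 Hz stays under a 35 deg/s threshold, so the
        # two flanking fixations are read as one
        x = np.concatenate([np.zeros(30), np.full(30, 2.0)])
        trace = make_trace(x)
        v = compute_velocity(trace, DPP)
        high_thr = segment_by_velocity(trace, v, 35.0)
        low_thr = segment_by_velocity(trace, v, 2.0)
        assert len(high_thr.by_label("fixation")) == 1
        assert len(low_thr.by_label("fixation")) == 2
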