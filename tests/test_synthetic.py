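"""Simulator: event bookkeeping, determinism, rendering, analytic motion."""

import numpy as np
import pytest

import somnoflow as sf
from somnoflow import synthetic as syn
from somnoflow.position import PositionSegment


class TestGenerateSubject:
    def test_event_count_follows_rounding_rule(self):
        _, truth = sf.generate_subject(3600.0, 30.0, "single_position", seed=7)
        assert len(truth.events) == 30

    @pytest.mark.parametrize("profile", ["single_position", "positional", "nonpositional"])
    def test_event_definitions_hold(self, profile):
        _, truth = sf.generate_subject(2400.0, 25.0, profile, seed=11)
        events = sorted(truth.events, key=lambda e: e.start_s)
        for ev in events:
            assert ev.duration_s > 10.0
        for a, b in zip(events, events[1:]):
            assert b.start_s - a.end_s >= 10.0 - 1e-9

    def test_zero_ahi_gives_pure_breathing(self):
        trace, truth = sf.generate_subject(600.0, 0.0, "single_position", seed=1)
        assert truth.events == []
        assert truth.true_ahi == 0.0
        # quasi-sinusoidal: spectral peak at the base rate, most energy there
        x = trace.amplitude_series - trace.amplitude_series.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1.0 / trace.sample_rate)
        assert abs(freqs[np.argmax(spec)] - trace.base_rate) < 0.05

    def test_true_ahi_consistent_with_event_list(self):
        _, truth = sf.generate_subject(3000.0, 17.0, "positional", seed=2)
        assert truth.true_ahi == pytest.approx(
            3600.0 * len(truth.events) / 3000.0, abs=1e-12
        )

    def test_positional_profile_rate_ratio(self):
        for seed in (0, 4, 9):
            _, truth = sf.generate_subject(3600.0, 30.0, "positional", seed=seed)
            assert truth.true_supine_ahi >= 1.5 * truth.true_lateral_ahi

    def test_position_segments_tile_recording(self):
        _, truth = sf.generate_subject(3600.0, 20.0, "nonpositional", seed=6)
        t = 0.0
        for seg in truth.positions:
            assert seg.start_s == pytest.approx(t)
            t = seg.end_s
        assert t == pytest.approx(3600.0)

    def test_determinism(self):
        a = sf.generate_subject(1200.0, 22.0, "positional", seed=13)
        b = sf.generate_subject(1200.0, 22.0, "positional", seed=13)
        assert np.array_equal(a[0].amplitude_series, b[0].amplitude_series)
        assert [(e.start_s, e.end_s, e.label) for e in a[1].events] == [
            (e.start_s, e.end_s, e.label) for e in b[1].events
        ]

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError):
            sf.generate_subject(60.0, 10.0, seed=0)

    def test_overfull_recording_raises_naming_constraint(self):
        with pytest.raises(ValueError, match="duration too short|no usable"):
            sf.generate_subject(300.0, 120.0, "single_position", seed=0)

    def test_hypopnea_amplitude_reduction(self):
        trace, truth = sf.generate_subject(1200.0, 24.0, "single_position", seed=8)
        fs = trace.sample_rate
        base = np.abs(trace.amplitude_series)
        hyp = [e for e in truth.events if e.label == "hypopnea"]
        assert hyp
        for ev in hyp:
            i0, i1 = int((ev.start_s + 2) * fs), int((ev.end_s - 2) * fs)
            inside = np.percentile(base[i0:i1], 95)
            # amplitude reduced by more than 30 % of the ~1 px baseline
            assert inside < 0.75


class TestRenderFrames:
    def test_zero_amplitude_zero_noise_frames_identical(self, supine_segment):
        trace = syn.BreathingTrace(10.0, np.zeros(100), 0.3, 0.0)
        frames = syn.render_frames(trace, supine_segment, 48, 64, 10.0, seed=0,
                                   noise_sd=0.0)
        assert np.allclose(frames.frames, frames.frames[0])

    def test_boundary_oscillates_at_base_rate(self, sinusoid_trace, supine_segment):
        frames = syn.render_frames(sinusoid_trace, supine_segment, 48, 64, 10.0,
                                   seed=0, noise_sd=0.0)
        col = frames.frames[:, :, 32]
        rows = np.arange(48)
        p = syn._pose(48, 64, "supine")
        band = (rows > p.cy - p.ay - 4) & (rows < p.cy - 0.5 * p.ay + 2)
        w = col[:, band] - col[:, band].min(axis=1, keepdims=True)
        centroid = (w * rows[band]).sum(axis=1) / w.sum(axis=1)
        spec = np.abs(np.fft.rfft(centroid - centroid.mean())) ** 2
        freqs = np.fft.rfftfreq(centroid.size, 1.0 / 10.0)
        assert freqs[np.argmax(spec)] == pytest.approx(0.3, abs=freqs[1])

    def test_pose_change_dominates_frame_differences(self, sinusoid_trace):
        segs = [PositionSegment(0.0, 30.0, "supine"),
                PositionSegment(30.0, 60.0, "lateral")]
        fr = syn.render_frames(sinusoid_trace, segs, 48, 64, 10.0, seed=0,
                               noise_sd=0.0)
        within = np.abs(fr.frames[100] - fr.frames[110]).sum()
        across = np.abs(fr.frames[295] - fr.frames[305]).sum()
        assert across > 5 * within

    def test_invalid_fps_raises(self, sinusoid_trace, supine_segment):
        with pytest.raises(ValueError):
            syn.render_frames(sinusoid_trace, supine_segment, 48, 64, 0.0)

    def test_determinism(self, sinusoid_trace, supine_segment):
        a = syn.render_frames(sinusoid_trace, supine_segment, 32, 32, 10.0, seed=4)
        b = syn.render_frames(sinusoid_trace, supine_segment, 32, 32, 10.0, seed=4)
        assert np.array_equal(a.frames, b.frames)


class TestExactFlow:
    def test_zero_amplitude_gives_zero_flow(self, supine_segment):
        trace = syn.BreathingTrace(10.0, np.zeros(100), 0.3, 0.0)
        flow = syn.exact_flow(trace, supine_segment, 48, 64, 2.0)
        assert np.all(flow.fields == 0)

    def test_19_samples_give_18_fields(self, supine_segment):
        trace = syn.BreathingTrace(2.0, np.linspace(0, 1, 19), 0.3, 0.0)
        flow = syn.exact_flow(trace, supine_segment, 48, 64, 2.0)
        assert flow.n_fields == 18

    def test_constant_velocity_gives_uniform_band_fields(self, supine_segment):
        v = 0.25  # px per frame at 2 Hz
        trace = syn.BreathingTrace(2.0, v * np.arange(20), 0.3, 0.0)
        flow = syn.exact_flow(trace, supine_segment, 48, 64, 2.0)
        band = syn._band_mask(48, 64, syn._pose(48, 64, "supine"))
        assert np.allclose(flow.fields[:, band, 1], -v, atol=1e-6)
        assert np.all(flow.fields[:, ~band, :] == 0)
        assert np.all(flow.fields[..., 0] == 0)

    def test_incompatible_rate_raises(self, sinusoid_trace, supine_segment):
        with pytest.raises(ValueError):
            syn.exact_flow(sinusoid_trace, supine_segment, 48, 64, 3.0)

    def test_matches_trajectory_oracle(self, small_subject):
        trace, truth = small_subject
        flow = syn.exact_flow(trace, truth.positions, 48, 64, 2.0)
        traj = syn.exact_point_trajectories(trace, truth.positions, 48, 64,
                                            rate=2.0, n_points=768)
        # integrate flow at each point's (static) grid location
        grid = traj.origin
        gx = np.round(grid[:, 0]).astype(int)
        gy = np.round(grid[:, 1]).astype(int)
        integrated = np.cumsum(flow.fields[:, gy, gx, :], axis=0)
        expected = traj.positions[:, 1:, :].transpose(1, 0, 2) - grid[None]
        assert np.allclose(integrated, expected, atol=1e-4)


class TestCohort:
    def test_cohort_determinism_and_ids(self):
        a = sf.generate_cohort(3, duration_s=600.0, seed=5)
        b = sf.generate_cohort(3, duration_s=600.0, seed=5)
        assert [r.subject_id for r in a] == ["s000", "s001", "s002"]
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.trace.amplitude_series,
                                  rb.trace.amplitude_series)

    def test_annotation_round_trip(self, small_subject):
        _, truth = small_subject
        df = syn.annotations_to_frame(truth, "s42")
        events, positions = syn.frame_to_annotations(df)
        assert len(events) == len(truth.events)
        assert len(positions) == len(truth.positions)
        assert events[0].start_s == pytest.approx(truth.events[0].start_s)
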