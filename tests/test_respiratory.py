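"""Respiratory signal: PCA extraction, rate and power features."""

import numpy as np
import pytest

from somnoflow.motion import PointTrajectories
from somnoflow import respiratory as resp
from somnoflow import synthetic as syn


def _oscillating_trajectories(freq=0.3, amp=1.5, rate=2.0, duration=120.0,
                              n_points=50, noise=0.0, seed=0):
    """All points oscillating vertically with a shared sinusoid."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * rate)) / rate
    d = amp * np.sin(2 * np.pi * freq * t)
    pos = np.empty((n_points, t.size, 2))
    pos[:, :, 0] = rng.uniform(0, 64, n_points)[:, None]
    pos[:, :, 1] = rng.uniform(0, 48, n_points)[:, None] + d[None, :]
    if noise:
        pos += rng.normal(0, noise, pos.shape)
    return PointTrajectories(positions=pos, rate=rate), d, t


class TestExtractRespiratory:
    def test_recovers_generating_sinusoid(self):
        traj, d, t = _oscillating_trajectories()
        signal = resp.extract_respiratory(traj)
        # oracle: PC1 of the full-record covariance is the same sinusoid
        d_1hz = d[:: int(traj.rate)][: len(signal)]
        r = np.corrcoef(signal.values, d_1hz)[0, 1]
        assert abs(r) > 0.99

    def test_matches_full_record_eigendecomposition_oracle(self):
        traj, _, _ = _oscillating_trajectories(noise=0.05, seed=4)
        signal = resp.extract_respiratory(traj)
        x = traj.positions.transpose(1, 0, 2).reshape(traj.n_samples, -1)
        xc = x - x.mean(axis=0)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        oracle = xc @ vt[0]
        oracle_1hz = oracle[:: int(traj.rate)][: len(signal)]
        r = np.corrcoef(signal.values, oracle_1hz)[0, 1]
        assert abs(r) > 0.99

    def test_static_trajectories_give_flat_signal(self):
        pos = np.tile(np.random.default_rng(2).random((30, 1, 2)), (1, 120, 1))
        traj = PointTrajectories(positions=pos, rate=2.0)
        signal = resp.extract_respiratory(traj)
        assert np.var(signal.values) < 1e-9

    def test_default_window_and_stride(self):
        assert resp.PCA_WINDOW_S == 30.0
        assert resp.PCA_STRIDE_S == 1.0

    def test_short_record_warns_and_returns_empty(self):
        traj, _, _ = _oscillating_trajectories(duration=20.0)
        with pytest.warns(UserWarning):
            signal = resp.extract_respiratory(traj)
        assert len(signal) == 0

    def test_length_invariant(self):
        traj, _, _ = _oscillating_trajectories(duration=100.0)
        signal = resp.extract_respiratory(traj)
        assert len(signal) == 100 - 30 + 1


class TestRespiratoryRate:
    def test_pure_sinusoid_within_one_bin(self):
        t = np.arange(40) / 4.0
        values = np.sin(2 * np.pi * 0.3 * t)
        rate = resp.respiratory_rate(values, window_s=10.0, sample_rate=4.0)
        assert rate == pytest.approx(0.3, abs=0.1)

    def test_dominant_component_wins(self):
        t = np.arange(40) / 4.0
        values = 2 * np.sin(2 * np.pi * 0.25 * t) + np.sin(2 * np.pi * 0.8 * t)
        rate = resp.respiratory_rate(values, window_s=10.0, sample_rate=4.0)
        assert rate == pytest.approx(0.25, abs=0.1)

    def test_all_zero_window_is_undefined_not_zero(self):
        rate = resp.respiratory_rate(np.zeros(10), window_s=10.0)
        assert np.isnan(rate)

    def test_matches_fft_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, 20)
        got = resp.respiratory_rate(values, window_s=None, sample_rate=2.0)
        x = values - values.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(20, 0.5)
        sel = (freqs >= 0.1) & (freqs <= 1.0)
        expected = freqs[sel][np.argmax(spec[sel])]
        assert got == expected


class TestMovementPower:
    def test_constant_value_gives_square(self):
        assert resp.movement_power(np.full(10, 3.0)) == pytest.approx(9.0)

    def test_zero_window_gives_zero(self):
        assert resp.movement_power(np.zeros(10)) == 0.0

    def test_sinusoid_gives_half_amplitude_squared(self):
        t = np.arange(200) / 10.0
        values = 2.5 * np.sin(2 * np.pi * 0.5 * t)  # 10 full periods
        assert resp.movement_power(values, window_s=None) == pytest.approx(
            2.5 ** 2 / 2, rel=0.01
        )


class TestFeatureProperties:
    def test_scale_equivariance(self):
        traj, _, _ = _oscillating_trajectories(noise=0.02, seed=9)
        scaled = PointTrajectories(positions=traj.positions * 3.0, rate=traj.rate)
        f1 = resp.compute_baseline_features(traj)
        f3 = resp.compute_baseline_features(scaled)
        assert np.allclose(f3["movement_power"], 9.0 * f1["movement_power"],
                           rtol=1e-6)
        assert np.allclose(f3["respiratory_rate"], f1["respiratory_rate"],
                           equal_nan=True)
        assert np.allclose(f3["total_displacement"],
                           3.0 * f1["total_displacement"], rtol=1e-6)

    def test_apnea_power_drops_at_least_90_percent(self, small_subject):
        trace, truth = small_subject
        traj = syn.exact_point_trajectories(trace, truth.positions, 48, 64,
                                            rate=2.0)
        feats = resp.compute_baseline_features(traj, annotations=truth.events)
        starts = feats["window_start_s"].to_numpy()
        power = feats["movement_power"].to_numpy()
        normal = np.median(power[feats["label"].to_numpy() == 0])
        for ev in truth.events:
            if ev.label != "apnea":
                continue
            # skip the onset ramp second: airflow decays over ~1 s
            inside = (starts >= ev.start_s + 2.0) & (starts + 10.0 <= ev.end_s)
            assert power[inside].max() < 0.1 * normal

    def test_feature_table_schema(self, small_trajectories, small_subject):
        _, truth = small_subject
        feats = resp.compute_baseline_features(
            small_trajectories, annotations=truth.events
        )
        assert list(feats.columns) == [
            "window_start_s", "respiratory_rate", "movement_power",
            "total_displacement", "label",
        ]
        assert set(feats["label"].unique()) <= {0, 1}
        assert (feats["movement_power"] >= 0).all()
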