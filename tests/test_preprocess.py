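"""Envelope extraction and marker-to-angle geometry."""

import numpy as np
import pytest
from scipy import signal

from emgkin.preprocess import (
    EmgRecording,
    JointAngleSeries,
    MarkerTrajectories,
    compute_joint_angles,
    compute_mvc,
    denormalize_angles,
    downsample,
    lowpass_zero_phase,
    normalize_angles,
    preprocess_angles,
    preprocess_emg,
    rectify_normalize,
)


class TestMvc:
    def test_single_channel_max_abs(self):
        rec = EmgRecording(np.array([[-2.0, 1.0, 0.5]]), fs=2000)
        assert compute_mvc([rec]) == pytest.approx([2.0])

    def test_max_over_trials(self):
        r1 = EmgRecording(np.array([[1.0, -0.2]]), fs=2000)
        r2 = EmgRecording(np.array([[0.1, 3.0]]), fs=2000)
        assert compute_mvc([r1, r2]) == pytest.approx([3.0])

    def test_matches_naive_scan(self, rng):
        x = rng.normal(size=(8, 500))
        rec = EmgRecording(x, fs=2000)
        naive = [max(abs(v) for v in row) for row in x]
        np.testing.assert_allclose(compute_mvc([rec]), naive)

    def test_zero_channel_rejected(self):
        rec = EmgRecording(np.vstack([np.zeros(10), np.ones(10)]), fs=2000,
                           channel_labels=["dead", "live"])
        with pytest.raises(ValueError, match="dead"):
            compute_mvc([rec])


class TestRectifyNormalize:
    def test_basic(self):
        rec = EmgRecording(np.array([[-1.0, 0.5]]), fs=2000)
        out = rectify_normalize(rec, 1.0)
        np.testing.assert_allclose(out.samples, [[1.0, 0.5]])

    def test_self_mvc_peaks_at_one(self, rng):
        x = rng.normal(size=(3, 400))
        rec = EmgRecording(x, fs=2000)
        out = rectify_normalize(rec, compute_mvc([rec]))
        np.testing.assert_allclose(out.samples.max(axis=1), 1.0)
        assert (out.samples >= 0).all()

    def test_nonpositive_mvc_rejected(self):
        rec = EmgRecording(np.ones((1, 5)), fs=2000)
        with pytest.raises(ValueError):
            rectify_normalize(rec, 0.0)


class TestLowpass:
    def test_dc_gain_unity(self):
        out = lowpass_zero_phase(np.full(4000, 0.7), fs=2000, cutoff=4.0)
        np.testing.assert_allclose(out[500:-500], 0.7, atol=1e-6)

    def test_passband_sinusoid_no_lag(self):
        fs = 2000
        t = np.arange(10 * fs) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_zero_phase(x, fs, 4.0)
        mid = slice(2 * fs, 8 * fs)
        # amplitude attenuation < 5 %
        assert np.abs(y[mid]).max() > 0.95
        # zero-phase: cross-correlation peak at zero lag
        lags = np.arange(-50, 51)
        xc = [np.dot(x[mid], np.roll(y, k)[mid]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_stopband_matches_squared_butterworth_magnitude(self):
        # forward+backward order-2 => squared order-2 magnitude response
        fs, f0, fc = 2000, 100.0, 4.0
        t = np.arange(8 * fs) / fs
        y = lowpass_zero_phase(np.sin(2 * np.pi * f0 * t), fs, fc, order=2)
        # discrete-time gain of the actual filter (bilinear-transformed), squared
        sos = signal.butter(2, fc, btype="low", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[f0], fs=fs)
        expected = np.abs(h[0]) ** 2
        measured = np.abs(y[2 * fs : 6 * fs]).max() / 1.0
        assert measured == pytest.approx(expected, rel=0.05)
        # and the analog prototype magnitude is the right order of size
        assert expected == pytest.approx(1 / (1 + (f0 / fc) ** 4), rel=0.2)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_zero_phase(np.zeros(100), fs=100, cutoff=60)


class TestDownsample:
    def test_length_and_constant(self):
        assert downsample(np.arange(100.0), 2000, 200).shape == (10,)
        np.testing.assert_allclose(downsample(np.full(50, 3.3), 1000, 200), 3.3)

    def test_sinusoid_preserved(self):
        fs_in, fs_out = 2000, 200
        t_in = np.arange(fs_in) / fs_in
        out = downsample(np.sin(2 * np.pi * t_in), fs_in, fs_out)
        t_out = np.arange(fs_out) / fs_out
        np.testing.assert_allclose(out, np.sin(2 * np.pi * t_out), atol=1e-12)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.zeros(100), 2000, 300)


class TestPreprocessEmg:
    def test_zero_in_zero_out(self):
        rec = EmgRecording(np.zeros((2, 4000)), fs=2000)
        out = preprocess_emg(rec, np.ones(2))
        np.testing.assert_allclose(out.values, 0.0)
        assert out.fs == 200

    def test_bounded_when_mvc_from_same_trial(self, rng):
        rec = EmgRecording(rng.normal(size=(4, 8000)), fs=2000)
        out = preprocess_emg(rec, compute_mvc([rec]))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_constant_drive_recovered(self, rng):
        # amplitude-modulated surrogate with constant modulation 0.5
        from emgkin.synthetic import SimulationConfig, generate_drive, synthesize_raw_emg

        cfg = SimulationConfig(duration=15.0, seed=5, n_channels=2)
        drive = generate_drive(cfg)
        drive.values[:] = 0.5
        emg = synthesize_raw_emg(drive, cfg)
        env = preprocess_emg(emg, np.ones(2)).values[:, 200:-200]
        assert np.sqrt(np.mean((env - 0.5) ** 2)) < 0.015


class TestJointAngles:
    def _markers(self, pts):
        pos = np.array(pts, dtype=float)[:, None, :]
        return MarkerTrajectories(pos, fs=200, marker_labels=["a", "b", "c"])

    def test_collinear_is_zero(self):
        m = self._markers([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        out = compute_joint_angles(m, {"j": ("a", "b", "c")})
        assert out.angles[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_right_angle(self):
        m = self._markers([(0, 0, 0), (1, 0, 0), (1, 1, 0)])
        out = compute_joint_angles(m, {"j": ("a", "b", "c")})
        assert out.angles[0, 0] == pytest.approx(90.0)

    def test_matches_acos_oracle_and_rigid_invariance(self, rng):
        pts = rng.normal(size=(3, 30, 3)) * 50
        m = MarkerTrajectories(pts, 200, ["a", "b", "c"])
        out = compute_joint_angles(m, {"j": ("a", "b", "c")}).angles[0]
        for f in range(30):
            v1, v2 = pts[0, f] - pts[1, f], pts[2, f] - pts[1, f]
            c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            assert out[f] == pytest.approx(180 - np.degrees(np.arccos(c)), abs=1e-9)
        # rigid motion: random rotation + translation leaves angles unchanged
        from scipy.spatial.transform import Rotation

        R = Rotation.random(rng=42).as_matrix()
        moved = pts @ R.T + np.array([10.0, -40.0, 7.0])
        out2 = compute_joint_angles(
            MarkerTrajectories(moved, 200, ["a", "b", "c"]), {"j": ("a", "b", "c")}
        ).angles[0]
        np.testing.assert_allclose(out2, out, atol=1e-9)

    def test_coincident_markers_error_names_frame(self):
        pts = np.zeros((3, 4, 3))
        pts[2, :, 0] = 1.0  # a == b for every frame
        m = MarkerTrajectories(pts, 200, ["a", "b", "c"])
        with pytest.raises(ValueError, match="frame 0"):
            compute_joint_angles(m, {"j": ("a", "b", "c")})


class TestNormalizeAngles:
    def test_midpoint_and_endpoints(self):
        ja = JointAngleSeries(np.array([[-40.0, 10.0, 60.0]]), ["d1"], 200)
        out = normalize_angles(ja, (np.array([-40.0]), np.array([60.0])))
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_round_trip(self, rng):
        ja = JointAngleSeries(rng.uniform(-40, 90, size=(4, 100)),
                              [f"d{i}" for i in range(4)], 200)
        back = denormalize_angles(normalize_angles(ja))
        np.testing.assert_allclose(back.angles, ja.angles, atol=1e-12)

    def test_degenerate_dof_named(self):
        ja = JointAngleSeries(np.vstack([np.ones(5), np.arange(5.0)]),
                              ["flat_dof", "ok"], 200)
        with pytest.raises(ValueError, match="flat_dof"):
            normalize_angles(ja)


def test_angle_filtering_removes_jitter_without_lag(rng):
    fs = 200
    t = np.arange(6 * fs) / fs
    clean = 30 * np.sin(2 * np.pi * 1.0 * t)
    noisy = clean + rng.normal(0, 2.0, t.size)
    ja = JointAngleSeries(noisy[None, :], ["d1"], fs)
    out = preprocess_angles(ja).angles[0]
    mid = slice(fs, -fs)
    assert np.std(out[mid] - clean[mid]) < np.std(noisy[mid] - clean[mid]) / 2
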