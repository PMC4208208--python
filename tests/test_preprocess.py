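"""Stream conditioning: resampling, zero-phase filtering, static-window
detection and skeleton-to-posture conversion."""

import numpy as np
import pytest

from sesc._rotations import random_rotations, rot_y
from sesc.preprocess import (
    JOINT_NAMES,
    StreamValidationError,
    TimedSeries,
    detect_static_windows,
    joints_to_posture,
    read_cop_csv,
    read_skeleton_csv,
    resample,
    skeleton_to_posture_series,
    write_cop_csv,
    write_skeleton_csv,
    zero_phase_lowpass,
)


def test_resample_constant_and_ramp():
    t = np.sort(np.random.default_rng(0).uniform(0, 10, size=100))
    const = resample(TimedSeries(t, np.full((100, 2), 3.3)), 15.0)
    assert np.allclose(const.values, 3.3)
    assert np.allclose(np.diff(const.timestamps), 1 / 15.0)
    ramp = resample(TimedSeries(t, 2.0 * t - 1.0), 15.0)
    assert np.allclose(ramp.values, 2.0 * ramp.timestamps - 1.0, atol=1e-12)


def test_resample_sine_tracks_analytic_signal():
    rng = np.random.default_rng(1)
    t = np.cumsum(rng.uniform(0.8, 1.2, size=300)) / 24.0  # jittered ~24 Hz
    f = 2.0
    series = TimedSeries(t, np.sin(2 * np.pi * f * t))
    out = resample(series, 15.0)
    assert np.abs(out.values - np.sin(2 * np.pi * f * out.timestamps)).max() < 1e-3


def test_resample_rejects_degenerate_series():
    with pytest.raises(StreamValidationError):
        resample(TimedSeries(np.array([0.0]), np.array([1.0])), 15.0)


def test_lowpass_preserves_dc_and_rejects_bad_cutoff():
    t = np.arange(0, 5, 1 / 100.0)
    series = TimedSeries(t, np.full_like(t, 7.7))
    out = zero_phase_lowpass(series, 5.0)
    assert np.allclose(out.values, 7.7, atol=1e-9)
    with pytest.raises(StreamValidationError, match="Nyquist"):
        zero_phase_lowpass(TimedSeries(t, t), 60.0)


def test_lowpass_gain_at_cutoff_is_minus_3db_twice():
    # forward-backward 2nd-order Butterworth: amplitude 1/2 at the cutoff
    t = np.arange(0, 60, 1 / 100.0)
    series = TimedSeries(t, np.sin(2 * np.pi * 5.0 * t))
    out = zero_phase_lowpass(series, 5.0, order=2)
    mid = slice(len(t) // 4, 3 * len(t) // 4)  # away from edge transients
    gain = np.abs(out.values[mid]).max()
    assert gain == pytest.approx(0.5, rel=0.02)


def test_lowpass_zero_phase_property():
    t = np.arange(0, 20, 1 / 100.0)
    x = np.sin(2 * np.pi * 0.5 * t)
    out = zero_phase_lowpass(TimedSeries(t, x), 5.0)
    xc = np.correlate(out.values - out.values.mean(), x - x.mean(), mode="full")
    lag = int(np.argmax(xc)) - (len(x) - 1)
    assert lag == 0


def _orient_stream(t, R):
    return TimedSeries(t, R, kind="rotations")


def test_constant_streams_merge_into_one_static_window(rng):
    t = np.arange(0, 6, 1 / 15.0)
    R = np.broadcast_to(random_rotations(rng, 9), (len(t), 9, 3, 3)).copy()
    cop = TimedSeries(t, np.tile([0.01, -0.02], (len(t), 1)))
    wins = detect_static_windows(_orient_stream(t, R), cop)
    assert len(wins) == 1
    assert wins[0].n_samples == len(t)
    assert np.allclose(wins[0].mean_cop, [0.01, -0.02])


def test_large_cop_motion_defeats_detection(rng):
    t = np.arange(0, 6, 1 / 15.0)
    R = np.broadcast_to(random_rotations(rng, 9), (len(t), 9, 3, 3)).copy()
    saw = 0.05 * (t * 2 % 1.0)  # 10+ mm dispersion per window
    cop = TimedSeries(t, np.column_stack([saw, saw]))
    assert detect_static_windows(_orient_stream(t, R), cop) == []


def test_detection_invariant_to_cop_translation(rng):
    t = np.arange(0, 10, 1 / 15.0)
    R = np.broadcast_to(random_rotations(rng, 9), (len(t), 9, 3, 3)).copy()
    wobble = 0.0005 * np.sin(2 * np.pi * 0.3 * t)
    base = np.column_stack([wobble, -wobble])
    w1 = detect_static_windows(_orient_stream(t, R), TimedSeries(t, base))
    w2 = detect_static_windows(_orient_stream(t, R), TimedSeries(t, base + [5.0, -3.0]))
    assert [(w.start, w.end) for w in w1] == [(w.start, w.end) for w in w2]
    assert np.allclose(w2[0].mean_cop - w1[0].mean_cop, [5.0, -3.0])


def test_short_stream_warns_and_returns_empty(rng):
    t = np.arange(0, 0.4, 1 / 15.0)
    R = np.broadcast_to(np.eye(3), (len(t), 9, 3, 3)).copy()
    cop = TimedSeries(t, np.zeros((len(t), 2)))
    with pytest.warns(UserWarning):
        assert detect_static_windows(_orient_stream(t, R), cop) == []


def _t_pose_joints():
    """Canonical upright T-pose: torso axes aligned with the global frame."""
    j = {
        "neck": [0.0, 0.0, 1.4], "head": [0.0, 0.0, 1.55],
        "torso": [0.0, 0.0, 1.2],
        "r_hip": [0.0, 0.1, 1.0], "l_hip": [0.0, -0.1, 1.0],
        "r_knee": [0.0, 0.1, 0.55], "l_knee": [0.0, -0.1, 0.55],
        "r_foot": [0.0, 0.1, 0.1], "l_foot": [0.0, -0.1, 0.1],
        "r_shoulder": [0.0, 0.2, 1.4], "l_shoulder": [0.0, -0.2, 1.4],
        "r_elbow": [0.0, 0.5, 1.4], "l_elbow": [0.0, -0.5, 1.4],
        "r_hand": [0.0, 0.8, 1.4], "l_hand": [0.0, -0.8, 1.4],
    }
    return {k: np.array(v) for k, v in j.items()}


def test_t_pose_torso_identity_and_legs_down():
    p = joints_to_posture(_t_pose_joints())
    assert np.allclose(p.orientations[0], np.eye(3), atol=1e-12)
    assert np.allclose(p.root_origin, [0.0, 0.0, 1.0])
    for leg in (5, 6, 7, 8):  # thigh/shank segments point straight down
        assert np.allclose(p.orientations[leg][:, 2], [0, 0, -1], atol=1e-12)
    # arms point along +/- y (ground components show up in the regressor)
    assert np.allclose(p.orientations[1][:, 2], [0, 1, 0], atol=1e-12)
    assert np.allclose(p.orientations[3][:, 2], [0, -1, 0], atol=1e-12)


def test_arm_along_x_maps_to_x_axis():
    joints = _t_pose_joints()
    joints["r_elbow"] = np.array([0.3, 0.2, 1.4])
    p = joints_to_posture(joints)
    assert np.allclose(p.orientations[1][:, 2], [1, 0, 0], atol=1e-12)


def test_joint_frames_are_orthonormal(rng):
    joints = {name: rng.normal(size=3) for name in JOINT_NAMES}
    p = joints_to_posture(joints)  # Posture validates orthonormality itself
    for A in p.orientations:
        assert np.abs(A.T @ A - np.eye(3)).max() < 1e-12
        assert np.linalg.det(A) == pytest.approx(1.0, abs=1e-12)


def test_coincident_joints_reported_by_bone():
    joints = _t_pose_joints()
    joints["r_knee"] = joints["r_hip"]
    with pytest.raises(StreamValidationError, match="r_hip->r_knee"):
        joints_to_posture(joints)


def test_skeleton_and_cop_csv_roundtrip(tmp_path, rng):
    t = np.arange(0, 2, 1 / 15.0)
    skel = TimedSeries(t, rng.normal(size=(len(t), 15, 3)))
    cop = TimedSeries(t, rng.normal(size=(len(t), 2)))
    write_skeleton_csv(tmp_path / "skel.csv", skel, {"note": "roundtrip"})
    write_cop_csv(tmp_path / "cop.csv", cop)
    skel2 = read_skeleton_csv(tmp_path / "skel.csv")
    cop2 = read_cop_csv(tmp_path / "cop.csv")
    assert np.allclose(skel2.values, skel.values, atol=1e-6)
    assert np.allclose(cop2.values, cop.values, atol=1e-6)
    assert np.allclose(skel2.timestamps, t, atol=1e-6)


def test_skeleton_series_matches_per_sample_conversion(rng):
    skel_values = rng.normal(size=(5, 15, 3))
    series = TimedSeries(np.arange(5) / 15.0, skel_values)
    orient, root = skeleton_to_posture_series(series)
    for k in range(5):
        joints = {name: skel_values[k, j] for j, name in enumerate(JOINT_NAMES)}
        p = joints_to_posture(joints)
        assert np.allclose(orient.values[k], p.orientations, atol=1e-12)
        assert np.allclose(root.values[k], p.root_origin, atol=1e-12)
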