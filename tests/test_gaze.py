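"""Gaze geometry: head bearings, arccos eye model, first-view logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from novelfp.experiments import fast_session_config
from novelfp.gaze import (
    FitError,
    build_gaze_table,
    classify_left_right,
    detect_first_view,
    eye_angle,
    eye_angles_per_frame,
    fit_circle,
    fit_ellipse_center,
    head_angle_per_trial,
    trial_speeds,
    viewing_angle,
)
from novelfp.session_io import Keypoints
from novelfp.synthetic import generate_oddball_session

from conftest import make_log


def _head_kp(angles_deg, fps=15.0, length=40.0, center=(100.0, 100.0)):
    n = len(angles_deg)
    t = np.arange(n) / fps
    th = np.deg2rad(np.asarray(angles_deg, float))
    cx, cy = center
    rows = []
    for i in range(n):
        rx = cx + length / 2 * np.cos(th[i])
        ry = cy + length / 2 * np.sin(th[i])
        qx = cx - length / 2 * np.cos(th[i])
        qy = cy - length / 2 * np.sin(th[i])
        rows.append((i, t[i], "rostral", rx, ry, 1.0))
        rows.append((i, t[i], "caudal", qx, qy, 1.0))
    return Keypoints(
        pd.DataFrame(rows, columns=["frame", "time_s", "point_name", "x_px", "y_px", "likelihood"])
    )


def test_static_head_gives_zero_angles():
    log = make_log(["standard"] * 4, period_s=2.0, stim_s=1.0, start_s=1.0)
    kp = _head_kp(np.full(150, 33.0))
    theta = head_angle_per_trial(kp, log)
    assert np.allclose(theta, 0.0, atol=1e-9)


def test_constructed_rotation_recovered():
    """+10 deg keypoint rotation between trials appears as a 10 deg step."""
    log = make_log(["standard"] * 2, period_s=4.0, stim_s=1.0, start_s=1.0)
    angles = np.where(np.arange(120) / 15.0 < 4.0, 20.0, 30.0)
    theta = head_angle_per_trial(_head_kp(angles), log)
    assert theta[1] - theta[0] == pytest.approx(10.0, abs=1e-6)


def test_only_frames_in_400ms_window_used():
    """Angles outside [onset, onset + 0.4 s] do not influence the trial angle."""
    log = make_log(["standard"] * 2, period_s=4.0, stim_s=1.0, start_s=1.0)
    t = np.arange(120) / 15.0
    base = np.where(t < 4.0, 0.0, 40.0)
    spoiled = base.copy()
    in_win = ((t >= 1.0) & (t <= 1.4)) | ((t >= 5.0) & (t <= 5.4))
    spoiled[~in_win] += 77.0  # junk outside the averaging windows
    assert np.allclose(
        np.diff(head_angle_per_trial(_head_kp(base), log)),
        np.diff(head_angle_per_trial(_head_kp(spoiled), log)),
        atol=1e-9,
    )


@given(
    shift=st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
    scale=st.floats(0.5, 3.0),
)
@settings(max_examples=15, deadline=None, derandomize=True)
def test_theta_invariant_to_translation_and_scale(shift, scale):
    log = make_log(["standard"] * 3, period_s=3.0, stim_s=1.0, start_s=1.0)
    angles = np.repeat([10.0, -25.0, 40.0], 45)
    kp = _head_kp(angles)
    kp2 = Keypoints(
        kp.df.assign(
            x_px=(kp.df["x_px"] + shift[0]) * scale, y_px=(kp.df["y_px"] + shift[1]) * scale
        )
    )
    assert np.allclose(head_angle_per_trial(kp, log), head_angle_per_trial(kp2, log), atol=1e-6)


def test_classify_left_right_boundaries():
    got = classify_left_right(np.array([-20.0, 0.0, 15.0, -15.0, 15.0001, np.nan]))
    assert got.tolist() == ["left", "neither", "neither", "neither", "right", "missing"]


@pytest.mark.parametrize(
    "seq,expected",
    [
        ([3.0, 3.0, 3.0], [True, False, False]),
        ([0.0, 6.0, 12.0, 18.0], [True, True, True, True]),
        ([0.0, 4.0, 9.0], [True, False, True]),
    ],
)
def test_first_view_examples(seq, expected):
    assert detect_first_view(np.array(seq)).tolist() == expected


def test_first_view_brute_force_oracle():
    rng = np.random.default_rng(5)
    theta = rng.uniform(-40, 40, size=60)
    theta[[7, 20]] = np.nan
    flags = detect_first_view(theta)
    for i in range(60):
        if np.isnan(theta[i]):
            assert not flags[i]
            continue
        prev = [theta[j] for j in range(i) if not np.isnan(theta[j])]
        want = (not prev) or min(abs(theta[i] - p) for p in prev) >= 5.0
        assert flags[i] == want


def test_eye_angle_anchors():
    """arccos(1) = 0 deg at the socket edge; socket centre maps to 90/90."""
    ang = np.linspace(0, 2 * np.pi, 9)[:-1]
    socket = np.column_stack([50 * np.cos(ang), 50 * np.sin(ang)])

    def pupil_at(cx, cy, a=6.0, b=4.0):
        return np.column_stack([cx + a * np.cos(ang), cy + b * np.sin(ang)])

    psi, phi = eye_angle(pupil_at(50.0, 0.0), socket, rho_deg=0.0)
    assert psi[0] == pytest.approx(0.0, abs=1e-6)
    psi, phi = eye_angle(pupil_at(0.0, 0.0), socket, rho_deg=0.0)
    assert psi == pytest.approx([90.0, 90.0], abs=1e-6)
    assert phi == pytest.approx(psi, abs=1e-9)  # rho = 0 is the identity
    # rho rotates psi by the visual-streak angle
    psi, phi = eye_angle(pupil_at(25.0, 0.0), socket, rho_deg=90.0)
    assert phi[1] == pytest.approx(psi[0])


def test_ellipse_center_against_skimage_oracle():
    skimage = pytest.importorskip("skimage.measure")
    rng = np.random.default_rng(2)
    ang = rng.uniform(0, 2 * np.pi, 12)
    pts = np.column_stack(
        [30 + 8 * np.cos(ang) - 3 * np.sin(ang), -12 + 3 * np.cos(ang) + 5 * np.sin(ang)]
    )
    cx, cy = fit_ellipse_center(pts)
    em = skimage.EllipseModel()
    assert em.estimate(pts)
    assert (cx, cy) == pytest.approx(tuple(em.params[:2]), abs=1e-6)


def test_circle_fit_exact_and_degenerate():
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    pts = np.column_stack([3 + 11 * np.cos(ang), -5 + 11 * np.sin(ang)])
    cx, cy, r = fit_circle(pts)
    assert (cx, cy, r) == pytest.approx((3.0, -5.0, 11.0), abs=1e-9)
    line = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
    with pytest.raises(FitError):
        fit_circle(line)
    with pytest.raises(FitError):
        fit_ellipse_center(np.column_stack([np.arange(6.0), np.arange(6.0)]))


def test_viewing_angle_sum_and_missing():
    v = viewing_angle(np.array([10.0, 5.0, np.nan]), np.array([-10.0, 0.0, 3.0]))
    assert v[0] == 0.0 and v[1] == 5.0 and np.isnan(v[2])


def test_trial_speeds_constant_motion():
    log = make_log(["standard"] * 2, period_s=4.0, stim_s=1.0, start_s=1.0)
    t = np.arange(120) / 15.0
    df = pd.DataFrame({"time_s": t, "x_px": 30.0 * t, "y_px": 0.0})
    sp = trial_speeds(df, log)
    assert sp == pytest.approx([30.0, 30.0], rel=1e-9)
    static = pd.DataFrame({"time_s": t, "x_px": 5.0, "y_px": 5.0})
    assert trial_speeds(static, log) == pytest.approx([0.0, 0.0])


def test_noiseless_synthetic_inversion():
    """The arccos pipeline inverts the generator: phi within 0.5 deg."""
    cfg = fast_session_config(seed=61, n_trials=12, include_eye=True)
    s = generate_oddball_session(cfg)
    est = eye_angles_per_frame(s.eye, s.annotation, frames=np.arange(0, 400, 5))
    truth = s.truth.eye_phi_deg[est.index.to_numpy()]
    assert np.abs(est[["phi_x", "phi_y"]].to_numpy() - truth).max() < 0.5


def test_gaze_table_recovers_ground_truth_viewing(planted_session=None):
    cfg = fast_session_config(seed=62, n_trials=12, include_eye=True)
    s = generate_oddball_session(cfg)
    table = build_gaze_table(s.head, s.log, s.eye, s.annotation)
    df = table.df
    # head angle matches the ground-truth walk (mean-zeroed) per trial
    t_frames = s.truth.head_frame_times
    for i, onset in enumerate(s.log.onsets):
        sel = (t_frames >= onset) & (t_frames <= onset + 0.4)
        true_mean = s.truth.head_angle_deg[sel].mean()
        centered = true_mean - np.mean(
            [
                s.truth.head_angle_deg[(t_frames >= o) & (t_frames <= o + 0.4)].mean()
                for o in s.log.onsets
            ]
        )
        assert df["theta"].iloc[i] == pytest.approx(centered, abs=0.1)
    # viewing = theta + phi_x and is finite where both streams exist
    assert np.allclose(df["viewing"], df["theta"] + df["phi_x"], equal_nan=True)
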