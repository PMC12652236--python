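"""Head, eye and viewing angles from tracked keypoints.

Head direction is the bearing of the caudal-to-rostral keypoint pair on the
top camera, averaged circularly over the frames from stimulus onset to
400 ms after it, and mean-zeroed across trials (0 deg = session-average
heading, positive = rightward).  Eye direction comes from the eye camera:
an ellipse is fit to the tracked pupil outline and a circle to the
once-per-session socket annotation; with the socket centre at the origin,
the raw eye angles are

    psi_k = arccos(k / r_socket),  k in {x, y}

(the eye treated as a sphere centred in its socket), then rotated by the
visual-streak angle rho into streak-aligned coordinates phi and expressed
relative to the session-mean eye position.  The viewing angle is the linear
sum of head and horizontal eye angle.

Also provided: the left/right head-angle split (|theta| > 15 deg, strict),
first-view detection (>= 5 deg from every previous trial's angle), and
per-trial movement speeds (80-480 ms post-onset).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .session_io import EyeAnnotation, Keypoints, TrialLog

__all__ = [
    "GazeTable",
    "FitError",
    "fit_ellipse_center",
    "fit_circle",
    "eye_angle",
    "eye_angles_per_frame",
    "head_angle_per_frame",
    "head_angle_per_trial",
    "classify_left_right",
    "detect_first_view",
    "viewing_angle",
    "trial_speeds",
    "speed_trace",
    "build_gaze_table",
    "pupil_centers",
]

LEFT_RIGHT_THRESHOLD_DEG = 15.0
FIRST_VIEW_MIN_DIST_DEG = 5.0
HEAD_WINDOW = (0.0, 0.400)
SPEED_WINDOW = (0.080, 0.480)
DEFAULT_MIN_LIKELIHOOD = 0.9


class FitError(ValueError):
    """Ellipse or circle least-squares fit is degenerate."""


@dataclasses.dataclass
class GazeTable:
    """Per-trial gaze summary.

    Columns of ``df``: ``theta`` (head angle, deg, session-mean-zeroed),
    ``phi_x``/``phi_y`` (streak-rotated, mean-subtracted eye angles, deg),
    ``viewing`` (theta + phi_x), ``head_speed``/``eye_speed`` (px/s),
    ``angle_group`` (left/right/neither) and ``is_first_view``.  Missing
    angles are NaN and excluded from angle analyses.
    """

    df: pd.DataFrame

    def trial_indices(self, group: str) -> np.ndarray:
        df = self.df
        if group == "Left":
            sel = df["angle_group"] == "left"
        elif group == "Right":
            sel = df["angle_group"] == "right"
        elif group == "FirstView":
            sel = df["is_first_view"].fillna(False).astype(bool)
        else:
            raise KeyError(group)
        return df.loc[sel, "trial_index"].to_numpy(int)


# ---------------------------------------------------------------------------
# geometric fits


def fit_ellipse_center(points: np.ndarray) -> tuple[float, float]:
    """Centre of the least-squares conic through >= 5 points.

    Fits ax^2 + bxy + cy^2 + dx + ey = 1 and returns the conic centre; this
    matches a full ellipse fit whenever the points actually lie near an
    ellipse, which is all the pupil-position estimate needs.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise FitError("ellipse fit needs >= 5 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x * x, x * y, y * y, x, y])
    coef, _, rank, _ = np.linalg.lstsq(A, np.ones(len(pts)), rcond=None)
    if rank < 5:
        raise FitError("degenerate pupil outline (collinear or repeated points)")
    a, b, c, d, e = coef
    M = np.array([[2 * a, b], [b, 2 * c]])
    if abs(np.linalg.det(M)) < 1e-12:
        raise FitError("conic has no unique centre")
    cx, cy = np.linalg.solve(M, [-d, -e])
    return float(cx), float(cy)


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle: returns (cx, cy, radius)."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise FitError("circle fit needs >= 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(pts))])
    coef, _, rank, _ = np.linalg.lstsq(A, x * x + y * y, rcond=None)
    if rank < 3:
        raise FitError("degenerate socket outline (collinear points)")
    cx, cy, c = coef
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise FitError("circle fit produced a non-positive radius")
    return float(cx), float(cy), float(np.sqrt(r2))


def eye_angle(
    pupil_points: np.ndarray,
    socket_points: np.ndarray,
    rho_deg: float = 0.0,
    clip_warn_tol: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and streak-rotated eye angles for one frame, degrees.

    Returns ``(psi, phi)`` where ``psi = (psi_x, psi_y)`` are the arccos
    angles of the fitted pupil centre relative to the socket centre and
    ``phi`` is psi rotated by ``rho_deg``.  The arccos argument is clipped
    to [-1, 1]; a centre beyond the socket circle by more than
    ``clip_warn_tol * radius`` triggers a warning before clipping.
    """
    px, py = fit_ellipse_center(pupil_points)
    cx, cy, r = fit_circle(socket_points)
    ratios = np.array([(px - cx) / r, (py - cy) / r])
    if np.any(np.abs(ratios) > 1.0 + clip_warn_tol):
        warnings.warn("pupil centre outside the socket circle; clipping", stacklevel=2)
    psi = np.degrees(np.arccos(np.clip(ratios, -1.0, 1.0)))
    rho = np.deg2rad(rho_deg)
    rot = np.array([[np.cos(rho), -np.sin(rho)], [np.sin(rho), np.cos(rho)]])
    phi = rot @ psi
    return psi, phi


def pupil_centers(eye: Keypoints, min_likelihood: float = DEFAULT_MIN_LIKELIHOOD) -> pd.DataFrame:
    """Per-frame pupil centre as the centroid of the outline keypoints.

    The outline points sit at evenly spaced parametric angles, so their
    centroid coincides with the ellipse centre; used for the fast speed
    trace, while angle estimation goes through the full fit.
    """
    df = eye.df[eye.df["likelihood"] >= min_likelihood]
    g = df.groupby("frame")
    out = g[["x_px", "y_px"]].mean()
    out["time_s"] = g["time_s"].first()
    return out


def eye_angles_per_frame(
    eye: Keypoints,
    annotation: EyeAnnotation,
    frames: Optional[np.ndarray] = None,
    min_likelihood: float = DEFAULT_MIN_LIKELIHOOD,
) -> pd.DataFrame:
    """Ellipse-fit eye angles for the requested frames (default: all).

    Returns a frame-indexed DataFrame with columns ``time_s, psi_x, psi_y,
    phi_x, phi_y``; ``phi`` here is raw (not yet mean-subtracted).
    """
    df = eye.df[eye.df["likelihood"] >= min_likelihood]
    if frames is not None:
        df = df[df["frame"].isin(frames)]
    cx, cy, r = fit_circle(annotation.socket_points)
    rho = np.deg2rad(annotation.rho_deg)
    rot = np.array([[np.cos(rho), -np.sin(rho)], [np.sin(rho), np.cos(rho)]])
    records = []
    for frame, sub in df.groupby("frame"):
        pts = sub[["x_px", "y_px"]].to_numpy()
        if len(pts) < 5:
            continue
        try:
            px, py = fit_ellipse_center(pts)
        except FitError:
            continue
        psi = np.degrees(np.arccos(np.clip([(px - cx) / r, (py - cy) / r], -1.0, 1.0)))
        phi = rot @ psi
        records.append((frame, sub["time_s"].iloc[0], psi[0], psi[1], phi[0], phi[1]))
    out = pd.DataFrame(records, columns=["frame", "time_s", "psi_x", "psi_y", "phi_x", "phi_y"])
    return out.set_index("frame")


# ---------------------------------------------------------------------------
# head angles


def head_angle_per_frame(
    head: Keypoints, min_likelihood: float = DEFAULT_MIN_LIKELIHOOD
) -> pd.DataFrame:
    """Bearing of the caudal->rostral vector per frame, degrees."""
    rostral = head.point("rostral", min_likelihood)
    caudal = head.point("caudal", min_likelihood)
    common = rostral.index.intersection(caudal.index)
    r = rostral.loc[common]
    c = caudal.loc[common]
    ang = np.degrees(np.arctan2(r["y_px"] - c["y_px"], r["x_px"] - c["x_px"]))
    return pd.DataFrame({"time_s": r["time_s"], "angle_deg": ang})


def _circmean_deg(angles: np.ndarray) -> float:
    rad = np.deg2rad(angles)
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def head_angle_per_trial(
    head: Keypoints,
    log: TrialLog,
    window: tuple[float, float] = HEAD_WINDOW,
    min_likelihood: float = DEFAULT_MIN_LIKELIHOOD,
) -> np.ndarray:
    """Session-mean-zeroed head angle per trial (NaN where untrackable).

    Per trial, the circular mean of the frame bearings between stimulus
    onset and 400 ms after it; the circular mean over valid trials is then
    subtracted so 0 deg is the session-average heading.
    """
    frames = head_angle_per_frame(head, min_likelihood)
    t = frames["time_s"].to_numpy()
    a = frames["angle_deg"].to_numpy()
    raw = np.full(len(log), np.nan)
    for i, onset in enumerate(log.onsets):
        sel = (t >= onset + window[0]) & (t <= onset + window[1])
        if sel.any():
            raw[i] = _circmean_deg(a[sel])
    n_missing = int(np.isnan(raw).sum())
    if n_missing:
        warnings.warn(f"{n_missing} trials have no valid head frames; marked missing", stacklevel=2)
    valid = ~np.isnan(raw)
    if not valid.any():
        return raw
    mean = _circmean_deg(raw[valid])
    out = np.full(len(log), np.nan)
    out[valid] = _wrap_deg(raw[valid] - mean)
    return out


def classify_left_right(
    theta: np.ndarray, threshold_deg: float = LEFT_RIGHT_THRESHOLD_DEG
) -> np.ndarray:
    """'left' for theta < -15 deg, 'right' for theta > 15 deg, else 'neither'.

    Inequalities are strict; NaN maps to 'missing'.
    """
    theta = np.asarray(theta, float)
    out = np.full(theta.shape, "neither", dtype=object)
    out[theta < -threshold_deg] = "left"
    out[theta > threshold_deg] = "right"
    out[np.isnan(theta)] = "missing"
    return out


def detect_first_view(theta: np.ndarray, min_dist_deg: float = FIRST_VIEW_MIN_DIST_DEG) -> np.ndarray:
    """Flag trials whose head angle is >= 5 deg from every previous trial.

    The first valid trial is flagged by convention (no predecessors);
    missing-angle trials are never flagged and never enter the comparison
    set.
    """
    theta = np.asarray(theta, float)
    flags = np.zeros(len(theta), dtype=bool)
    seen: list[float] = []
    for i, a in enumerate(theta):
        if np.isnan(a):
            continue
        if not seen or min(abs(a - b) for b in seen) >= min_dist_deg:
            flags[i] = True
        seen.append(a)
    return flags


def viewing_angle(theta: np.ndarray, phi_x: np.ndarray) -> np.ndarray:
    """Head plus horizontal eye angle; NaN where either is missing."""
    return np.asarray(theta, float) + np.asarray(phi_x, float)


# ---------------------------------------------------------------------------
# speeds


def speed_trace(
    keypoints_xy: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-to-frame speed (px/s) of a tracked point.

    ``keypoints_xy`` must have columns ``time_s, x_px, y_px`` (one row per
    frame).  Returns (times, speed) with speed assigned to the later frame
    of each pair; the first sample is zero.
    """
    t = keypoints_xy["time_s"].to_numpy(float)
    x = keypoints_xy["x_px"].to_numpy(float)
    y = keypoints_xy["y_px"].to_numpy(float)
    dt = np.diff(t)
    d = np.hypot(np.diff(x), np.diff(y))
    speed = np.concatenate([[0.0], d / dt])
    return t, speed


def trial_speeds(
    keypoints_xy: pd.DataFrame,
    log: TrialLog,
    window: tuple[float, float] = SPEED_WINDOW,
) -> np.ndarray:
    """Mean point speed per trial over 80-480 ms post-onset (px/s).

    Trials with fewer than two frames in the window are NaN.
    """
    t, speed = speed_trace(keypoints_xy)
    out = np.full(len(log), np.nan)
    for i, onset in enumerate(log.onsets):
        sel = (t >= onset + window[0]) & (t <= onset + window[1])
        idx = np.flatnonzero(sel)
        idx = idx[idx > 0]  # the very first frame has no defined speed
        if sel.sum() >= 2 and len(idx):
            out[i] = speed[idx].mean()
    return out


# ---------------------------------------------------------------------------
# assembly


def build_gaze_table(
    head: Keypoints,
    log: TrialLog,
    eye: Optional[Keypoints] = None,
    annotation: Optional[EyeAnnotation] = None,
    min_likelihood: float = DEFAULT_MIN_LIKELIHOOD,
) -> GazeTable:
    """Assemble the per-trial gaze summary from the keypoint streams."""
    theta = head_angle_per_trial(head, log, min_likelihood=min_likelihood)
    rostral = head.point("rostral", min_likelihood)
    head_speed = trial_speeds(rostral, log)

    phi_x = np.full(len(log), np.nan)
    phi_y = np.full(len(log), np.nan)
    eye_speed = np.full(len(log), np.nan)
    if eye is not None and annotation is not None:
        frames = eye_angles_per_frame_for_trials(eye, annotation, log, min_likelihood)
        if len(frames):
            t = frames["time_s"].to_numpy()
            fx = frames["phi_x"].to_numpy()
            fy = frames["phi_y"].to_numpy()
            for i, onset in enumerate(log.onsets):
                sel = (t >= onset + HEAD_WINDOW[0]) & (t <= onset + HEAD_WINDOW[1])
                if sel.any():
                    phi_x[i] = fx[sel].mean()
                    phi_y[i] = fy[sel].mean()
            # eye angles are expressed relative to the session-mean position
            phi_x -= np.nanmean(phi_x)
            phi_y -= np.nanmean(phi_y)
        eye_speed = trial_speeds(pupil_centers(eye, min_likelihood), log)

    df = pd.DataFrame(
        {
            "trial_index": log.df["trial_index"].to_numpy(),
            "theta": theta,
            "phi_x": phi_x,
            "phi_y": phi_y,
            "viewing": viewing_angle(theta, phi_x),
            "head_speed": head_speed,
            "eye_speed": eye_speed,
            "angle_group": classify_left_right(theta),
            "is_first_view": detect_first_view(theta),
        }
    )
    return GazeTable(df)


def eye_angles_per_frame_for_trials(
    eye: Keypoints,
    annotation: EyeAnnotation,
    log: TrialLog,
    min_likelihood: float = DEFAULT_MIN_LIKELIHOOD,
    window: tuple[float, float] = HEAD_WINDOW,
) -> pd.DataFrame:
    """Eye angles restricted to frames inside per-trial averaging windows."""
    times = eye.frame_times
    frames_all = np.sort(eye.df["frame"].unique())
    need = np.zeros(len(frames_all), dtype=bool)
    for onset in log.onsets:
        need |= (times >= onset + window[0]) & (times <= onset + window[1])
    return eye_angles_per_frame(eye, annotation, frames=frames_all[need], min_likelihood=min_likelihood)
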