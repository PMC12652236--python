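"""Synthetic oddball sessions with known ground truth.

Emulates the four data streams of a visual spatial-oddball recording in
freely viewing turtles: continuous LFP with an oscillatory evoked response
whose gain adapts position-specifically, the trial schedule (one frequent
"standard" grid position, one rare "deviant" position, 2 s stimuli with a
5 s inter-stimulus interval), top-camera head keypoints following a bounded
random head-angle walk, and eye-camera pupil-outline keypoints generated by
the forward model that the gaze-geometry stage inverts.

The generator plants the structure the analysis is meant to detect:

* deviant and first-presentation responses are large, repeated standards
  adapt toward a floor — the gain is keyed to the *allocentric* screen
  position (``adaptation_mode="allocentric"``, the default), or optionally
  to a gaze-relative key (``"retinotopic"``) so the pipeline's ability to
  tell the two regimes apart can be exercised;
* head and eye movement epochs are injected into quiet inter-stimulus
  intervals, by default with no evoked LFP at all (movement-silent cortex).

Everything is a deterministic function of ``SessionConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .session_io import ContinuousRecording, EyeAnnotation, Keypoints, TrialLog

__all__ = [
    "GridSpec",
    "SessionConfig",
    "GroundTruth",
    "SyntheticSession",
    "generate_oddball_session",
    "generate_control_session",
]

CONTROL_POSITIONS = [(0, 0), (2, 0), (1, 1), (0, 2), (2, 2)]  # four corners + middle


@dataclasses.dataclass
class GridSpec:
    """Stimulus grid: 3x3 positions, one standard and one deviant index."""

    shape: tuple[int, int] = (3, 3)
    standard: tuple[int, int] = (1, 1)
    deviant: tuple[int, int] = (0, 0)

    def validate(self) -> None:
        for name in ("standard", "deviant"):
            c, r = getattr(self, name)
            if not (0 <= c < self.shape[0] and 0 <= r < self.shape[1]):
                raise ValueError(f"grid.{name} outside grid shape {self.shape}")
        if self.standard == self.deviant:
            raise ValueError("grid.standard and grid.deviant must differ")


@dataclasses.dataclass
class SessionConfig:
    """All knobs of the synthetic session generator.

    The schedule defaults mirror the oddball protocol (deviants ~1/10 of
    trials, 2 s stimulus, 5 s inter-stimulus interval); the evoked-response
    and noise amplitudes are free parameters of the simulation, fixed at
    values giving single-trial-visible responses over a 1/f-ish background.
    """

    n_trials: int = 200
    deviant_prob: float = 0.1
    stim_duration_s: float = 2.0
    isi_s: float = 5.0
    grid: GridSpec = dataclasses.field(default_factory=GridSpec)
    fs_lfp: float = 20_000.0
    fs_video: float = 15.0
    fs_eye: float = 60.0
    n_channels: int = 1

    # evoked response: damped oscillation starting `latency` after onset
    gain_deviant: float = 3.0
    gain_standard_initial: float = 3.0
    gain_standard_floor: float = 1.0
    adaptation_tau_trials: float = 4.0
    adaptation_mode: str = "allocentric"  # or "retinotopic"
    retinotopic_bin_deg: float = 15.0
    gain_jitter_sd: float = 0.15  # lognormal sigma on per-trial gain
    template_amp_uV: float = 140.0
    template_freq_hz: float = 20.0
    template_decay_s: float = 0.150
    response_latency_s: float = 0.080

    # background noise
    noise_sd_uV: float = 70.0
    pink_fraction: float = 0.5  # share of noise variance with a 1/f spectrum
    noise_highpass_hz: float = 1.0  # AC coupling of the acquisition chain

    # head kinematics (top camera)
    head_walk_sd_deg: float = 0.8  # per-frame innovation of the angle walk
    head_ou_tau_s: float = 150.0  # mean-reversion time of the angle walk
    head_angle_bound_deg: float = 60.0
    still_trial_prob: float = 0.3  # trials during which the head is frozen
    head_length_px: float = 60.0
    head_center_px: tuple[float, float] = (200.0, 200.0)

    # eye kinematics
    eye_walk_sd_deg: float = 0.8
    socket_radius_px: float = 60.0
    socket_center_px: tuple[float, float] = (160.0, 120.0)
    pupil_axes_px: tuple[float, float] = (18.0, 14.0)
    n_pupil_points: int = 8
    rho_deg: float = 15.0
    include_eye: bool = True

    # movement epochs injected into inter-stimulus intervals
    movement_prob: float = 0.25  # per ISI
    movement_duration_s: float = 0.4
    head_move_speed_px_s: float = 150.0
    eye_saccade_deg: float = 20.0
    movement_lfp_gain: float = 0.0  # evoked gain locked to movement onsets

    keypoint_noise_px: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.deviant_prob < 1.0:
            raise ValueError("deviant_prob must lie in (0, 1)")
        for name in ("gain_deviant", "gain_standard_initial", "gain_standard_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fs_lfp <= 0 or abs(self.fs_lfp / 400.0 - round(self.fs_lfp / 400.0)) > 1e-9:
            raise ValueError("fs_lfp must be a positive multiple of 400 Hz")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if self.adaptation_mode not in ("allocentric", "retinotopic"):
            raise ValueError("adaptation_mode must be 'allocentric' or 'retinotopic'")
        if self.noise_sd_uV < 0:
            raise ValueError("noise_sd_uV must be >= 0")
        if not 0.0 <= self.pink_fraction <= 1.0:
            raise ValueError("pink_fraction must lie in [0, 1]")
        self.grid.validate()

    def null(self) -> "SessionConfig":
        """Copy with no novelty structure: equal, non-adapting gains."""
        return dataclasses.replace(
            self,
            gain_deviant=1.0,
            gain_standard_initial=1.0,
            gain_standard_floor=1.0,
        )


@dataclasses.dataclass
class GroundTruth:
    """Planted values, for validation only — never fed to the analysis."""

    gains: np.ndarray  # per trial
    head_angle_deg: np.ndarray  # per top-camera frame (raw, not mean-zeroed)
    head_frame_times: np.ndarray
    eye_psi_deg: Optional[np.ndarray]  # per eye frame, columns (psi_x, psi_y)
    eye_phi_deg: Optional[np.ndarray]  # streak-rotated, same shape
    eye_frame_times: Optional[np.ndarray]
    head_movement_onsets_s: np.ndarray
    eye_movement_onsets_s: np.ndarray
    adaptation_mode: str = "allocentric"

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "gains": arr(self.gains),
            "head_angle_deg": arr(self.head_angle_deg),
            "head_frame_times": arr(self.head_frame_times),
            "eye_psi_deg": arr(self.eye_psi_deg),
            "eye_phi_deg": arr(self.eye_phi_deg),
            "eye_frame_times": arr(self.eye_frame_times),
            "head_movement_onsets_s": arr(self.head_movement_onsets_s),
            "eye_movement_onsets_s": arr(self.eye_movement_onsets_s),
            "adaptation_mode": self.adaptation_mode,
        }


@dataclasses.dataclass
class SyntheticSession:
    recording: ContinuousRecording
    log: TrialLog
    head: Keypoints
    eye: Optional[Keypoints]
    annotation: Optional[EyeAnnotation]
    truth: GroundTruth
    config: SessionConfig


# ---------------------------------------------------------------------------
# building blocks


def evoked_template(fs: float, cfg: SessionConfig) -> np.ndarray:
    """Damped 20 Hz sinusoid beginning ``response_latency_s`` after onset."""
    dur = cfg.response_latency_s + 6.0 * cfg.template_decay_s
    t = np.arange(int(round(dur * fs))) / fs
    tt = t - cfg.response_latency_s
    out = np.zeros_like(t)
    on = tt >= 0
    out[on] = (
        cfg.template_amp_uV
        * np.exp(-tt[on] / cfg.template_decay_s)
        * np.sin(2.0 * np.pi * cfg.template_freq_hz * tt[on])
    )
    return out


def pink_noise(
    rng: np.random.Generator, n: int, fs: float = 1.0, highpass_hz: float = 0.0
) -> np.ndarray:
    """Unit-variance noise with a 1/f amplitude spectrum.

    ``highpass_hz`` models the AC coupling of the acquisition chain: below
    it the 1/f amplitude rolls off linearly toward DC instead of diverging,
    as in a first-order high-passed recording.  Synthesised at the next fast
    FFT length and truncated; the spectrum of the truncated segment is
    unchanged in expectation.
    """
    from scipy.fft import irfft, next_fast_len, rfft

    m = next_fast_len(n, real=True)
    white = rng.standard_normal(m)
    spec = rfft(white)
    f = np.fft.rfftfreq(m, d=1.0 / fs)
    spec[0] = 0.0
    amp = np.ones_like(f)
    amp[1:] = 1.0 / np.sqrt(f[1:])
    if highpass_hz > 0:
        low = (f > 0) & (f < highpass_hz)
        amp[low] = (f[low] / highpass_hz) / np.sqrt(highpass_hz)
    spec *= amp
    x = irfft(spec, m)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _background_noise(rng: np.random.Generator, n: int, cfg: SessionConfig) -> np.ndarray:
    if cfg.noise_sd_uV == 0:
        return np.zeros(n)
    w = np.sqrt(1.0 - cfg.pink_fraction) * rng.standard_normal(n)
    if cfg.pink_fraction > 0:
        w += np.sqrt(cfg.pink_fraction) * pink_noise(
            rng, n, fs=cfg.fs_lfp, highpass_hz=cfg.noise_highpass_hz
        )
    return cfg.noise_sd_uV * w


def reflect_into(x: np.ndarray, bound: float) -> np.ndarray:
    """Reflect an unbounded random walk into the interval [-bound, bound]."""
    period = 4.0 * bound
    y = np.mod(x + bound, period)
    return np.where(y <= 2.0 * bound, y - bound, 3.0 * bound - y)


def _trial_schedule(cfg: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_trials
    n_dev = int(round(n * cfg.deviant_prob))
    if n <= 10 or n_dev >= n - 10:
        raise ValueError("n_trials too small for the requested deviant fraction")
    # deviants are placed uniformly after the first ten trials, so the
    # First10 group stays a pure early-standard group
    dev_idx = np.sort(rng.choice(np.arange(10, n), size=n_dev, replace=False))
    cond = np.full(n, "standard", dtype=object)
    cond[dev_idx] = "deviant"
    pos = np.array(
        [cfg.grid.deviant if c == "deviant" else cfg.grid.standard for c in cond], int
    )
    period = cfg.stim_duration_s + cfg.isi_s
    onsets = cfg.isi_s + np.arange(n) * period
    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "onset_s": onsets,
            "offset_s": onsets + cfg.stim_duration_s,
            "condition": cond,
            "pos_col": pos[:, 0],
            "pos_row": pos[:, 1],
        }
    )


def _session_duration(cfg: SessionConfig, n_trials: int) -> float:
    return cfg.isi_s + n_trials * (cfg.stim_duration_s + cfg.isi_s) + 1.0


def _head_streams(
    cfg: SessionConfig,
    rng: np.random.Generator,
    duration: float,
    schedule: pd.DataFrame,
) -> tuple[Keypoints, np.ndarray, np.ndarray, np.ndarray]:
    """Head-angle walk, keypoints, and injected translation epochs."""
    from scipy.signal import lfilter

    n_frames = int(duration * cfg.fs_video)
    times = np.arange(n_frames) / cfg.fs_video
    steps = rng.standard_normal(n_frames) * cfg.head_walk_sd_deg
    steps[0] = rng.uniform(-cfg.head_angle_bound_deg / 2, cfg.head_angle_bound_deg / 2)

    # freeze the head during "still" trials (onset..offset window)
    still = rng.random(len(schedule)) < cfg.still_trial_prob
    for on, off, s in zip(schedule["onset_s"], schedule["offset_s"], still):
        if s:
            steps[(times >= on) & (times <= off)] = 0.0
    # mean-reverting (OU) walk: wanders over minutes, stays bounded
    a = np.exp(-1.0 / (cfg.head_ou_tau_s * cfg.fs_video))
    theta = lfilter([1.0], [1.0, -a], steps)
    theta = reflect_into(theta, cfg.head_angle_bound_deg)

    # translation movement epochs in quiet parts of the ISI
    move_isis = np.flatnonzero(rng.random(len(schedule)) < cfg.movement_prob)
    onsets = []
    cx = np.full(n_frames, cfg.head_center_px[0])
    cy = np.full(n_frames, cfg.head_center_px[1])
    for i in move_isis:
        off = float(schedule["offset_s"].iloc[i])
        next_on = off + cfg.isi_s
        lo, hi = off + 0.6, next_on - 0.6 - cfg.movement_duration_s
        if hi <= lo:
            continue
        t_on = lo + rng.uniform(0.0, hi - lo)
        direction = rng.uniform(0.0, 2.0 * np.pi)
        sel = (times >= t_on) & (times < t_on + cfg.movement_duration_s)
        k = sel.sum()
        if k < 2:
            continue
        profile = np.hanning(k) * cfg.head_move_speed_px_s / cfg.fs_video
        dx, dy = np.cos(direction) * profile, np.sin(direction) * profile
        start = int(np.flatnonzero(sel)[0])
        cx[start : start + k] += np.cumsum(dx)
        cx[start + k :] += dx.sum()
        cy[start : start + k] += np.cumsum(dy)
        cy[start + k :] += dy.sum()
        onsets.append(t_on)

    th = np.deg2rad(theta)
    half = cfg.head_length_px / 2.0
    rx, ry = cx + half * np.cos(th), cy + half * np.sin(th)
    qx, qy = cx - half * np.cos(th), cy - half * np.sin(th)
    if cfg.keypoint_noise_px > 0:
        rx = rx + rng.standard_normal(n_frames) * cfg.keypoint_noise_px
        ry = ry + rng.standard_normal(n_frames) * cfg.keypoint_noise_px
        qx = qx + rng.standard_normal(n_frames) * cfg.keypoint_noise_px
        qy = qy + rng.standard_normal(n_frames) * cfg.keypoint_noise_px
    frames = np.arange(n_frames)
    df = pd.DataFrame(
        {
            "frame": np.repeat(frames, 2),
            "time_s": np.repeat(times, 2),
            "point_name": np.tile(["rostral", "caudal"], n_frames),
            "x_px": np.column_stack([rx, qx]).ravel(),
            "y_px": np.column_stack([ry, qy]).ravel(),
            "likelihood": 1.0,
        }
    )
    return Keypoints(df), theta, times, np.asarray(onsets)


def _eye_streams(
    cfg: SessionConfig,
    rng: np.random.Generator,
    duration: float,
    schedule: pd.DataFrame,
) -> tuple[Keypoints, EyeAnnotation, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pupil keypoints from the forward arccos model, plus saccade epochs."""
    n_frames = int(duration * cfg.fs_eye)
    times = np.arange(n_frames) / cfg.fs_eye
    psi = np.empty((n_frames, 2))
    for k in range(2):
        walk = np.cumsum(rng.standard_normal(n_frames) * cfg.eye_walk_sd_deg)
        psi[:, k] = 90.0 + reflect_into(walk, 25.0)

    # saccade epochs: rapid jumps of the raw eye angle inside quiet ISIs
    move_isis = np.flatnonzero(rng.random(len(schedule)) < cfg.movement_prob)
    onsets = []
    for i in move_isis:
        off = float(schedule["offset_s"].iloc[i])
        lo, hi = off + 0.6, off + cfg.isi_s - 0.6
        if hi <= lo:
            continue
        t_on = lo + rng.uniform(0.0, hi - lo)
        sel = np.flatnonzero((times >= t_on) & (times < t_on + 0.1))
        if len(sel) < 2:
            continue
        jump = rng.choice([-1.0, 1.0]) * cfg.eye_saccade_deg
        psi[sel, 0] += np.linspace(0.0, jump, len(sel))
        psi[sel[-1] + 1 :, 0] += jump
        onsets.append(t_on)
    psi = np.clip(psi, 5.0, 175.0)

    rho = np.deg2rad(cfg.rho_deg)
    rot = np.array([[np.cos(rho), -np.sin(rho)], [np.sin(rho), np.cos(rho)]])
    phi = psi @ rot.T

    r = cfg.socket_radius_px
    scx, scy = cfg.socket_center_px
    px = scx + r * np.cos(np.deg2rad(psi[:, 0]))
    py = scy + r * np.cos(np.deg2rad(psi[:, 1]))

    # pupil outline: points on an ellipse around the pupil centre at evenly
    # spaced parametric angles (their centroid is exactly the centre)
    a, b = cfg.pupil_axes_px
    ang = 2.0 * np.pi * np.arange(cfg.n_pupil_points) / cfg.n_pupil_points
    tilt = np.deg2rad(20.0)
    ex = np.cos(tilt) * a * np.cos(ang) - np.sin(tilt) * b * np.sin(ang)
    ey = np.sin(tilt) * a * np.cos(ang) + np.cos(tilt) * b * np.sin(ang)
    X = px[:, None] + ex[None, :]
    Y = py[:, None] + ey[None, :]
    if cfg.keypoint_noise_px > 0:
        X = X + rng.standard_normal(X.shape) * cfg.keypoint_noise_px
        Y = Y + rng.standard_normal(Y.shape) * cfg.keypoint_noise_px

    npts = cfg.n_pupil_points
    names = [f"pupil_{j}" for j in range(npts)]
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), npts),
            "time_s": np.repeat(times, npts),
            "point_name": np.tile(names, n_frames),
            "x_px": X.ravel(),
            "y_px": Y.ravel(),
            "likelihood": 1.0,
        }
    )
    sang = 2.0 * np.pi * np.arange(12) / 12
    socket = np.column_stack([scx + r * np.cos(sang), scy + r * np.sin(sang)])
    ann = EyeAnnotation(socket_points=socket, rho_deg=cfg.rho_deg)
    return Keypoints(df), ann, psi, phi, times, np.asarray(onsets)


def _trial_gains(
    cfg: SessionConfig,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    head_theta: np.ndarray,
    head_times: np.ndarray,
    position_bias: Optional[dict] = None,
) -> np.ndarray:
    """Per-trial evoked gain with position-keyed adaptation.

    Standards decay from ``gain_standard_initial`` to ``gain_standard_floor``
    with the count of prior presentations at the adaptation key; deviants
    keep ``gain_deviant``.  In retinotopic mode the key also includes the
    binned true head angle at stimulus onset, so a previously unseen viewing
    angle resets the adaptation state.
    """
    counts: dict = {}
    gains = np.empty(len(schedule))
    onsets = schedule["onset_s"].to_numpy(float)
    idx = np.clip(np.searchsorted(head_times, onsets), 0, len(head_times) - 1)
    theta_at = head_theta[idx]
    for i, row in enumerate(schedule.itertuples()):
        pos = (row.pos_col, row.pos_row)
        key = pos
        if cfg.adaptation_mode == "retinotopic":
            key = (pos, int(np.floor(theta_at[i] / cfg.retinotopic_bin_deg)))
        k = counts.get(key, 0)
        counts[key] = k + 1
        if row.condition == "deviant":
            g = cfg.gain_deviant
        else:
            decay = np.exp(-k / cfg.adaptation_tau_trials) if np.isfinite(cfg.adaptation_tau_trials) else 1.0
            g = cfg.gain_standard_floor + (cfg.gain_standard_initial - cfg.gain_standard_floor) * decay
        if position_bias:
            g = g * position_bias.get(pos, 1.0)
        gains[i] = g
    if cfg.gain_jitter_sd > 0:
        # lognormal trial-to-trial variability, truncated at +-2 sigma so a
        # physiological response can never trip the artifact threshold
        z = np.clip(rng.standard_normal(len(gains)), -2.0, 2.0)
        gains = gains * np.exp(cfg.gain_jitter_sd * z)
    return gains


def _render_lfp(
    cfg: SessionConfig,
    rng: np.random.Generator,
    duration: float,
    schedule: pd.DataFrame,
    gains: np.ndarray,
    movement_onsets: np.ndarray,
) -> ContinuousRecording:
    n = int(duration * cfg.fs_lfp)
    template = evoked_template(cfg.fs_lfp, cfg)
    voltage = np.empty((cfg.n_channels, n), dtype=np.float32)
    for ch in range(cfg.n_channels):
        trace = _background_noise(rng, n, cfg)
        # channel gain profile: channel 0 carries the full response
        ch_gain = 1.0 / (1.0 + ch)
        for onset, g in zip(schedule["onset_s"].to_numpy(float), gains):
            k0 = int(round(onset * cfg.fs_lfp))
            k1 = min(k0 + len(template), n)
            trace[k0:k1] += ch_gain * g * template[: k1 - k0]
        if cfg.movement_lfp_gain > 0:
            for onset in movement_onsets:
                k0 = int(round(onset * cfg.fs_lfp))
                k1 = min(k0 + len(template), n)
                if k0 < n:
                    trace[k0:k1] += ch_gain * cfg.movement_lfp_gain * template[: k1 - k0]
        voltage[ch] = trace
    return ContinuousRecording(voltage, cfg.fs_lfp, 0.0)


# ---------------------------------------------------------------------------
# public generators


def generate_oddball_session(config: SessionConfig) -> SyntheticSession:
    """Generate one complete synthetic oddball session.

    Returns the continuous recording, trial log, head and (optionally) eye
    keypoint streams, the socket annotation, and the planted ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    schedule = _trial_schedule(config, rng)
    duration = _session_duration(config, config.n_trials)
    head, theta, head_times, head_moves = _head_streams(config, rng, duration, schedule)
    if config.include_eye:
        eye, ann, psi, phi, eye_times, eye_moves = _eye_streams(config, rng, duration, schedule)
    else:
        eye = ann = psi = phi = eye_times = None
        eye_moves = np.asarray([])
    gains = _trial_gains(config, schedule, rng, theta, head_times)
    rec = _render_lfp(config, rng, duration, schedule, gains, head_moves)
    truth = GroundTruth(
        gains=gains,
        head_angle_deg=theta,
        head_frame_times=head_times,
        eye_psi_deg=psi,
        eye_phi_deg=phi,
        eye_frame_times=eye_times,
        head_movement_onsets_s=head_moves,
        eye_movement_onsets_s=eye_moves,
        adaptation_mode=config.adaptation_mode,
    )
    return SyntheticSession(rec, TrialLog(schedule), head, eye, ann, truth, config)


def generate_control_session(
    config: SessionConfig,
    position_bias: Optional[dict] = None,
    n_repeats: int = 20,
) -> SyntheticSession:
    """Uniform spatial-control session: each position shown equally often.

    Five grid positions (the four corners and the middle) are each presented
    ``n_repeats`` times in uniformly random order, with no oddball structure
    and no adaptation.  ``position_bias`` maps a (col, row) position to a
    multiplicative evoked-gain factor, used to plant a spatial response bias.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    positions = np.array(CONTROL_POSITIONS * n_repeats)
    rng.shuffle(positions, axis=0)
    n = len(positions)
    period = config.stim_duration_s + config.isi_s
    onsets = config.isi_s + np.arange(n) * period
    schedule = pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "onset_s": onsets,
            "offset_s": onsets + config.stim_duration_s,
            "condition": "standard",
            "pos_col": positions[:, 0],
            "pos_row": positions[:, 1],
        }
    )
    duration = _session_duration(config, n)
    head, theta, head_times, head_moves = _head_streams(config, rng, duration, schedule)
    flat = dataclasses.replace(
        config,
        gain_standard_initial=config.gain_standard_floor,
        adaptation_tau_trials=np.inf,
    )
    gains = _trial_gains(flat, schedule, rng, theta, head_times, position_bias=position_bias)
    rec = _render_lfp(config, rng, duration, schedule, gains, head_moves)
    truth = GroundTruth(
        gains=gains,
        head_angle_deg=theta,
        head_frame_times=head_times,
        eye_psi_deg=None,
        eye_phi_deg=None,
        eye_frame_times=None,
        head_movement_onsets_s=head_moves,
        eye_movement_onsets_s=np.asarray([]),
        adaptation_mode=config.adaptation_mode,
    )
    return SyntheticSession(rec, TrialLog(schedule), head, None, None, truth, config)
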