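"""Movement-evoked versus stimulus-evoked LFP activity.

Tests whether cortical responses could be explained by the animal's own
head or eye movements rather than the visual stimulus.  Movement onsets are
detected as isolated peaks of the keypoint speed trace; each event's
activity magnitude — the mean absolute LFP over a 200 ms window — is
maximised over a sliding window (50 ms steps) spanning 1 s after a head
movement or 0.5 s after an eye movement, then baseline-subtracted using the
same sliding procedure on the nearest quiet episode (no movement peak, no
stimulus).  Stimulus events use a fixed 80-280 ms post-onset window with a
200 ms pre-onset baseline.  Per-session differences (stimulus minus
movement) feed a one-sided one-sample t test across sessions.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from .session_io import ContinuousRecording, TrialLog

__all__ = [
    "MovementEpoch",
    "MovementComparison",
    "detect_movement_onsets",
    "activity_magnitude",
    "movement_relative_magnitude",
    "stimulus_relative_magnitude",
    "compare_movement_vs_stimulus",
]

RESPONSE_WINDOW_S = 0.200
SLIDE_STEP_S = 0.050
HEAD_SPAN_S = 1.0
EYE_SPAN_S = 0.5
STIM_EXCLUSION_S = (0.080, 0.480)  # after stimulus onset and offset


@dataclasses.dataclass
class MovementEpoch:
    onset_s: float
    kind: str  # "head" or "eye"
    chosen_window: Optional[tuple[float, float]] = None
    magnitude: Optional[float] = None
    baseline_window: Optional[tuple[float, float]] = None
    baseline_magnitude: Optional[float] = None

    @property
    def relative_magnitude(self) -> Optional[float]:
        if self.magnitude is None or self.baseline_magnitude is None:
            return None
        return self.magnitude - self.baseline_magnitude

    @property
    def span(self) -> float:
        return HEAD_SPAN_S if self.kind == "head" else EYE_SPAN_S


def detect_movement_onsets(
    speed: np.ndarray,
    times: np.ndarray,
    log: Optional[TrialLog] = None,
    k_sd: float = 2.0,
    min_separation_s: float = 1.0,
) -> np.ndarray:
    """Isolated peaks of a uniformly sampled speed trace, in seconds.

    Peaks must exceed mean + ``k_sd`` SD of the trace and be at least
    ``min_separation_s`` apart.  Peaks inside the stimulus exclusion zones —
    80-480 ms after any stimulus onset or offset — are discarded, since
    movement there cannot be separated from the visual response.
    """
    speed = np.asarray(speed, float)
    times = np.asarray(times, float)
    if len(speed) == 0:
        raise ValueError("empty speed trace")
    fs = 1.0 / np.median(np.diff(times))
    height = speed.mean() + k_sd * speed.std()
    peaks, _ = signal.find_peaks(speed, height=height, distance=max(1, int(round(min_separation_s * fs))))
    onsets = times[peaks]
    if log is not None and len(onsets):
        keep = np.ones(len(onsets), bool)
        for ref in np.concatenate([log.onsets, log.offsets]):
            keep &= ~((onsets >= ref + STIM_EXCLUSION_S[0]) & (onsets <= ref + STIM_EXCLUSION_S[1]))
        onsets = onsets[keep]
    return onsets


def activity_magnitude(
    rec: ContinuousRecording, window: tuple[float, float], channel: int = 0
) -> float:
    """Mean absolute LFP (uV) over a time window on one channel."""
    k0, k1 = rec.time_to_sample(window[0]), rec.time_to_sample(window[1])
    if k1 <= k0:
        raise ValueError("empty activity window")
    if k0 < 0 or k1 > rec.n_samples:
        raise ValueError("activity window outside the recording")
    return float(np.abs(rec.voltage[channel, k0:k1]).mean())


def _sliding_max(
    rec: ContinuousRecording, start_s: float, span_s: float, channel: int
) -> tuple[float, tuple[float, float]]:
    """Max 200 ms activity magnitude over 50 ms-step windows in a span.

    Ties break to the earliest window.
    """
    n = int(round((span_s - RESPONSE_WINDOW_S) / SLIDE_STEP_S)) + 1
    best = -np.inf
    best_win = (start_s, start_s + RESPONSE_WINDOW_S)
    for j in range(n):
        w0 = start_s + j * SLIDE_STEP_S
        m = activity_magnitude(rec, (w0, w0 + RESPONSE_WINDOW_S), channel)
        if m > best:
            best = m
            best_win = (w0, w0 + RESPONSE_WINDOW_S)
    return best, best_win


def _forbidden_intervals(
    log: TrialLog, movement_onsets: Sequence[float], span_s: float
) -> list[tuple[float, float]]:
    iv = [(on, off + STIM_EXCLUSION_S[1]) for on, off in zip(log.onsets, log.offsets)]
    iv += [(m - RESPONSE_WINDOW_S, m + span_s) for m in movement_onsets]
    return iv


def _episode_quiet(t0: float, t1: float, intervals: Sequence[tuple[float, float]]) -> bool:
    return all(t1 <= a or t0 >= b for a, b in intervals)


def movement_relative_magnitude(
    rec: ContinuousRecording,
    epoch: MovementEpoch,
    log: TrialLog,
    all_movement_onsets: Sequence[float] = (),
    channel: int = 0,
    search_horizon_s: float = 30.0,
) -> Optional[MovementEpoch]:
    """Fill in an epoch's sliding-max magnitude and quiet-episode baseline.

    The baseline episode is the nearest span of the same length containing
    no movement peak and no stimulus epoch, searched outward in 50 ms steps
    alternating before/after the epoch (nearer side first).  Returns None
    (with a warning) if no quiet episode exists within the search horizon.
    """
    span = epoch.span
    mag, win = _sliding_max(rec, epoch.onset_s, span, channel)
    forbidden = _forbidden_intervals(log, all_movement_onsets, span)
    t_end = rec.t0 + rec.duration

    baseline = None
    offset = SLIDE_STEP_S
    while offset <= search_horizon_s:
        for s0 in (epoch.onset_s - offset - span, epoch.onset_s + offset):
            if s0 < rec.t0 or s0 + span > t_end:
                continue
            if _episode_quiet(s0, s0 + span, forbidden):
                baseline = s0
                break
        if baseline is not None:
            break
        offset += SLIDE_STEP_S
    if baseline is None:
        warnings.warn(
            f"no quiet baseline episode within {search_horizon_s} s of movement at "
            f"{epoch.onset_s:.2f} s; epoch dropped",
            stacklevel=2,
        )
        return None
    bmag, bwin = _sliding_max(rec, baseline, span, channel)
    return dataclasses.replace(
        epoch,
        chosen_window=win,
        magnitude=mag,
        baseline_window=bwin,
        baseline_magnitude=bmag,
    )


def stimulus_relative_magnitude(
    rec: ContinuousRecording, log: TrialLog, trial: int, channel: int = 0
) -> float:
    """Stimulus activity magnitude minus its pre-onset baseline (uV).

    Response window: 80-280 ms after onset; baseline: the 200 ms immediately
    before onset.
    """
    onset = float(log.onsets[trial])
    resp = activity_magnitude(rec, (onset + 0.080, onset + 0.080 + RESPONSE_WINDOW_S), channel)
    base = activity_magnitude(rec, (onset - RESPONSE_WINDOW_S, onset), channel)
    return resp - base


@dataclasses.dataclass
class MovementComparison:
    """Across-session movement-vs-stimulus comparison (one movement kind)."""

    delta_standard: np.ndarray  # per session: stim(standard) - movement mean
    delta_deviant: np.ndarray
    t_standard: float
    p_standard: float
    t_deviant: float
    p_deviant: float
    degenerate_variance: bool = False

    def to_dict(self) -> dict:
        return {
            "delta_standard": self.delta_standard.tolist(),
            "delta_deviant": self.delta_deviant.tolist(),
            "t_standard": self.t_standard,
            "p_standard": self.p_standard,
            "t_deviant": self.t_deviant,
            "p_deviant": self.p_deviant,
            "degenerate_variance": self.degenerate_variance,
        }


def _one_sided_t(delta: np.ndarray) -> tuple[float, float, bool]:
    """One-sample t of delta > 0; zero-variance vectors handled explicitly."""
    if np.ptp(delta) == 0:
        if delta[0] == 0:
            return 0.0, 0.5, True
        return (np.inf if delta[0] > 0 else -np.inf), (0.0 if delta[0] > 0 else 1.0), True
    t, p = stats.ttest_1samp(delta, 0.0, alternative="greater")
    return float(t), float(p), False


def compare_movement_vs_stimulus(
    session_movement_means: Sequence[float],
    session_standard_means: Sequence[float],
    session_deviant_means: Sequence[float],
) -> MovementComparison:
    """Per-session stimulus-minus-movement differences and one-sided t tests.

    Inputs are per-session means of baseline-subtracted activity magnitudes;
    sessions lacking movement epochs (NaN movement mean) are excluded.
    """
    mv = np.asarray(session_movement_means, float)
    st = np.asarray(session_standard_means, float)
    dv = np.asarray(session_deviant_means, float)
    valid = ~np.isnan(mv) & ~np.isnan(st) & ~np.isnan(dv)
    if valid.sum() < 2:
        raise ValueError("need at least 2 sessions with both event kinds")
    d_std = st[valid] - mv[valid]
    d_dev = dv[valid] - mv[valid]
    t_s, p_s, deg_s = _one_sided_t(d_std)
    t_d, p_d, deg_d = _one_sided_t(d_dev)
    return MovementComparison(d_std, d_dev, t_s, p_s, t_d, p_d, deg_s or deg_d)
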