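"""Movement-onset detection and activity-magnitude comparisons."""

import numpy as np
import pytest

from novelfp.movement import (
    MovementEpoch,
    activity_magnitude,
    compare_movement_vs_stimulus,
    detect_movement_onsets,
    movement_relative_magnitude,
    stimulus_relative_magnitude,
)
from novelfp.session_io import ContinuousRecording

from conftest import make_log


def _rec(n_s=120.0, fs=2000.0, value=0.0):
    return ContinuousRecording(np.full((1, int(n_s * fs)), value), fs)


def test_flat_speed_no_onsets():
    t = np.arange(1000) / 15.0
    assert len(detect_movement_onsets(np.ones(1000), t)) == 0
    with pytest.raises(ValueError, match="empty"):
        detect_movement_onsets(np.array([]), np.array([]))


def test_two_bumps_detected_at_peaks():
    fps = 15.0
    t = np.arange(600) / fps
    rng = np.random.default_rng(0)
    speed = 1.0 + 0.1 * rng.standard_normal(600)
    for center in (10.0, 13.0):
        speed += 30.0 * np.exp(-0.5 * ((t - center) / 0.15) ** 2)
    onsets = detect_movement_onsets(speed, t)
    assert len(onsets) == 2
    assert np.allclose(onsets, [10.0, 13.0], atol=1.5 / fps)


def test_bump_in_stimulus_exclusion_zone_discarded():
    log = make_log(["standard"] * 2, period_s=20.0, stim_s=2.0, start_s=5.0)
    fps = 15.0
    t = np.arange(int(50 * fps)) / fps
    speed = np.zeros_like(t)
    speed += 20.0 * np.exp(-0.5 * ((t - (5.0 + 0.2)) / 0.1) ** 2)  # 200 ms post-onset
    speed += 20.0 * np.exp(-0.5 * ((t - 40.0) / 0.1) ** 2)  # quiet period
    onsets = detect_movement_onsets(speed, t, log)
    assert len(onsets) == 1
    assert onsets[0] == pytest.approx(40.0, abs=0.1)


def test_activity_magnitude_closed_forms():
    rec = _rec(value=-7.5)
    assert activity_magnitude(rec, (1.0, 2.0)) == pytest.approx(7.5)
    rec0 = _rec(value=0.0)
    assert activity_magnitude(rec0, (0.0, 1.0)) == 0.0
    # |A sin| over whole cycles averages 2A/pi
    fs, A, f = 2000.0, 50.0, 10.0
    t = np.arange(int(10 * fs)) / fs
    rec_sin = ContinuousRecording((A * np.sin(2 * np.pi * f * t))[None, :], fs)
    assert activity_magnitude(rec_sin, (0.0, 1.0)) == pytest.approx(2 * A / np.pi, rel=1e-3)
    with pytest.raises(ValueError):
        activity_magnitude(rec, (2.0, 1.0))


def test_sliding_max_matches_enumeration():
    """17 candidate windows over a 1 s span; max matches brute force."""
    rng = np.random.default_rng(4)
    fs = 2000.0
    rec = ContinuousRecording(rng.standard_normal(int(60 * fs))[None, :] * 20, fs)
    log = make_log(["standard"], period_s=50.0, stim_s=2.0, start_s=40.0)
    epoch = movement_relative_magnitude(
        rec, MovementEpoch(10.0, "head"), log, all_movement_onsets=[10.0]
    )
    starts = [10.0 + 0.05 * j for j in range(17)]
    assert len(starts) == 17 and starts[-1] == pytest.approx(10.8)
    mags = [activity_magnitude(rec, (s, s + 0.2)) for s in starts]
    assert epoch.magnitude == pytest.approx(max(mags))
    assert all(epoch.magnitude >= m for m in mags)
    # earliest-window tie-break: chosen window is a real argmax
    assert epoch.chosen_window[0] == pytest.approx(starts[int(np.argmax(mags))])


def test_boxcar_deflection_captured():
    fs = 2000.0
    rec = _rec(n_s=120.0, fs=fs)
    rec.voltage[0, int(10.30 * fs) : int(10.45 * fs)] = 80.0
    log = make_log(["standard"], period_s=50.0, stim_s=2.0, start_s=100.0)
    epoch = movement_relative_magnitude(
        rec, MovementEpoch(10.0, "head"), log, all_movement_onsets=[10.0]
    )
    # best 200 ms window fully covers the 150 ms boxcar: mean |v| = 80 * 0.15/0.2
    assert epoch.magnitude == pytest.approx(80.0 * 0.15 / 0.2, rel=1e-6)
    assert epoch.baseline_magnitude == 0.0
    assert epoch.relative_magnitude == pytest.approx(60.0, rel=1e-6)


def test_flat_recording_relative_zero_and_eye_span():
    rec = _rec()
    log = make_log(["standard"], period_s=50.0, stim_s=2.0, start_s=100.0)
    head = movement_relative_magnitude(rec, MovementEpoch(20.0, "head"), log, [20.0])
    eye = movement_relative_magnitude(rec, MovementEpoch(20.0, "eye"), log, [20.0])
    assert head.relative_magnitude == 0.0
    assert eye.relative_magnitude == 0.0
    assert eye.span == 0.5 and head.span == 1.0


def test_no_quiet_episode_drops_epoch():
    rec = _rec(n_s=30.0)
    # wall-to-wall stimuli leave no quiet baseline within the horizon
    log = make_log(["standard"] * 4, period_s=7.0, stim_s=6.5, start_s=1.0)
    with pytest.warns(UserWarning, match="quiet"):
        out = movement_relative_magnitude(
            rec, MovementEpoch(10.0, "head"), log, [10.0], search_horizon_s=5.0
        )
    assert out is None


def test_scaling_invariance():
    """Scaling the whole trace by c > 0 scales all magnitudes by c."""
    rng = np.random.default_rng(9)
    fs = 2000.0
    v = rng.standard_normal(int(60 * fs)) * 30
    log = make_log(["standard"], period_s=50.0, stim_s=2.0, start_s=40.0)
    e1 = movement_relative_magnitude(
        ContinuousRecording(v[None, :], fs), MovementEpoch(10.0, "head"), log, [10.0]
    )
    e2 = movement_relative_magnitude(
        ContinuousRecording(3.0 * v[None, :], fs), MovementEpoch(10.0, "head"), log, [10.0]
    )
    assert e2.magnitude == pytest.approx(3.0 * e1.magnitude, rel=1e-9)
    assert e2.relative_magnitude == pytest.approx(3.0 * e1.relative_magnitude, rel=1e-9)


def test_stimulus_relative_magnitude_planted_bump():
    fs = 2000.0
    rec = _rec(n_s=60.0, fs=fs)
    log = make_log(["standard"], period_s=20.0, stim_s=2.0, start_s=20.0)
    assert stimulus_relative_magnitude(rec, log, 0) == 0.0
    rec.voltage[0, int(20.08 * fs) : int(20.28 * fs)] = 55.0
    assert stimulus_relative_magnitude(rec, log, 0) == pytest.approx(55.0)


def test_compare_movement_vs_stimulus_boundaries():
    zero = compare_movement_vs_stimulus([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert zero.t_standard == 0.0 and zero.p_standard == 0.5
    assert zero.degenerate_variance
    const = compare_movement_vs_stimulus([0.0] * 4, [1.0] * 4, [2.0] * 4)
    assert const.p_standard == 0.0 and const.degenerate_variance
    with pytest.raises(ValueError, match="2 sessions"):
        compare_movement_vs_stimulus([1.0], [2.0], [3.0])
    # NaN movement means exclude sessions
    mixed = compare_movement_vs_stimulus(
        [0.0, np.nan, 0.0, 0.0], [1.0, 9.0, 1.2, 0.8], [2.0, 9.0, 2.2, 1.9]
    )
    assert len(mixed.delta_standard) == 3
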