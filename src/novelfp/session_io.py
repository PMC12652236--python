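"""Session artifacts and their on-disk formats.

A recording session consists of four time-aligned streams on a common
acquisition clock (seconds):

* a continuous multichannel extracellular voltage trace (microvolts),
* a per-trial stimulus log (condition, grid position, onset/offset),
* top-camera head keypoints (two points on the rostral-caudal axis),
* optional eye-camera pupil-outline keypoints plus a once-per-session
  socket annotation (socket outline points and visual-streak angle rho).

Formats: voltage as HDF5 (dataset ``voltage_uv``, attrs ``fs_hz``,
``t0_s``), trial log and keypoints as CSV, annotation as YAML.  Frame to
clock synchronisation is assumed done upstream; timestamps are trusted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ContinuousRecording",
    "TrialLog",
    "Keypoints",
    "EyeAnnotation",
    "SessionPaths",
    "AlignmentError",
    "save_session",
    "load_session",
]

TRIAL_COLUMNS = ["trial_index", "onset_s", "offset_s", "condition", "pos_col", "pos_row"]
KEYPOINT_COLUMNS = ["frame", "time_s", "point_name", "x_px", "y_px", "likelihood"]


class AlignmentError(ValueError):
    """A stream's timestamps fall outside the recording span."""


@dataclasses.dataclass
class ContinuousRecording:
    """Continuous voltage, ``channels x samples`` in microvolts.

    Sample ``k`` of every channel occurs at time ``t0 + k / fs``.
    """

    voltage: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.voltage = np.atleast_2d(np.asarray(self.voltage))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def time_to_sample(self, t: float) -> int:
        return int(round((t - self.t0) * self.fs))


class TrialLog:
    """Per-trial stimulus schedule with derived trial-group flags.

    Wraps a DataFrame with columns ``trial_index, onset_s, offset_s,
    condition, pos_col, pos_row`` and derives:

    * ``is_first10`` — one of the first ten trials of the session,
    * ``is_1after`` — a standard trial immediately following a deviant.
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy().reset_index(drop=True)
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial log missing columns: {missing}")
        onsets = df["onset_s"].to_numpy(float)
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        if np.any(df["offset_s"].to_numpy(float) <= onsets):
            raise ValueError("offset_s must exceed onset_s for every trial")
        bad = set(df["condition"]) - {"standard", "deviant"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        df["is_first10"] = np.arange(len(df)) < 10
        prev_dev = df["condition"].shift(1, fill_value="standard") == "deviant"
        df["is_1after"] = prev_dev & (df["condition"] == "standard")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def onsets(self) -> np.ndarray:
        return self.df["onset_s"].to_numpy(float)

    @property
    def offsets(self) -> np.ndarray:
        return self.df["offset_s"].to_numpy(float)

    @property
    def conditions(self) -> np.ndarray:
        return self.df["condition"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (col, row) grid indices."""
        return self.df[["pos_col", "pos_row"]].to_numpy(int)

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask over trials for a named group."""
        df = self.df
        if name == "Standard":
            return (df["condition"] == "standard").to_numpy()
        if name == "Deviant":
            return (df["condition"] == "deviant").to_numpy()
        if name == "First10":
            return df["is_first10"].to_numpy()
        if name == "1After":
            return df["is_1after"].to_numpy()
        raise KeyError(name)


@dataclasses.dataclass
class Keypoints:
    """Tracked keypoints, long format: one row per (frame, point)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in KEYPOINT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"keypoints missing columns: {missing}")
        lk = self.df["likelihood"].to_numpy(float)
        if np.any((lk < 0) | (lk > 1)):
            raise ValueError("likelihood must lie in [0, 1]")
        t = self.df.groupby("frame")["time_s"].first().to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def point(self, name: str, min_likelihood: float = 0.0) -> pd.DataFrame:
        """Frames of one named point, indexed by frame, low-likelihood rows dropped."""
        sel = self.df[self.df["point_name"] == name]
        sel = sel[sel["likelihood"] >= min_likelihood]
        return sel.set_index("frame")[["time_s", "x_px", "y_px", "likelihood"]]

    def point_names(self) -> list[str]:
        return sorted(self.df["point_name"].unique())

    @property
    def frame_times(self) -> np.ndarray:
        return self.df.groupby("frame")["time_s"].first().to_numpy()


@dataclasses.dataclass
class EyeAnnotation:
    """Once-per-session eye annotation: socket outline and visual-streak angle.

    ``rho_deg`` rotates the raw eye angles so that the eye's visual streak —
    the retinal specialisation kept roughly horizon-aligned — defines the
    horizontal axis.
    """

    socket_points: np.ndarray  # (n, 2) pixels
    rho_deg: float = 0.0

    def __post_init__(self) -> None:
        self.socket_points = np.asarray(self.socket_points, float)
        if self.socket_points.ndim != 2 or self.socket_points.shape[1] != 2:
            raise ValueError("socket_points must be (n, 2)")
        if len(self.socket_points) < 3:
            raise ValueError("socket annotation needs at least 3 points")


@dataclasses.dataclass
class SessionPaths:
    lfp: Path
    trials: Path
    head: Path
    eye: Optional[Path] = None
    annotation: Optional[Path] = None
    ground_truth: Optional[Path] = None

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is not None:
                setattr(self, f.name, Path(v))

    @classmethod
    def in_dir(cls, directory: Path, with_eye: bool = True) -> "SessionPaths":
        d = Path(directory)
        return cls(
            lfp=d / "lfp.h5",
            trials=d / "trials.csv",
            head=d / "head_keypoints.csv",
            eye=d / "eye_keypoints.csv" if with_eye else None,
            annotation=d / "eye_annotation.yaml" if with_eye else None,
            ground_truth=d / "ground_truth.json",
        )


# ---------------------------------------------------------------------------
# writers


def save_recording(path: Path, rec: ContinuousRecording) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("voltage_uv", data=rec.voltage)
        ds.attrs["fs_hz"] = rec.fs
        ds.attrs["t0_s"] = rec.t0


def load_recording(path: Path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        ds = f["voltage_uv"]
        return ContinuousRecording(ds[...], float(ds.attrs["fs_hz"]), float(ds.attrs["t0_s"]))


def save_trial_log(path: Path, log: TrialLog) -> None:
    log.df[TRIAL_COLUMNS].to_csv(path, index=False)


def load_trial_log(path: Path) -> TrialLog:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message carries line no
        raise ValueError(f"malformed trial log {path}: {exc}") from exc
    return TrialLog(df)


def save_keypoints(path: Path, kp: Keypoints) -> None:
    kp.df[KEYPOINT_COLUMNS].to_csv(path, index=False)


def load_keypoints(path: Path) -> Keypoints:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover
        raise ValueError(f"malformed keypoints {path}: {exc}") from exc
    return Keypoints(df)


def save_annotation(path: Path, ann: EyeAnnotation) -> None:
    payload = {
        "rho_deg": float(ann.rho_deg),
        "socket_points": [[float(x), float(y)] for x, y in ann.socket_points],
    }
    Path(path).write_text(yaml.safe_dump(payload))


def load_annotation(path: Path) -> EyeAnnotation:
    payload = yaml.safe_load(Path(path).read_text())
    return EyeAnnotation(np.asarray(payload["socket_points"], float), float(payload["rho_deg"]))


def save_session(
    paths: SessionPaths,
    rec: ContinuousRecording,
    log: TrialLog,
    head: Keypoints,
    eye: Optional[Keypoints] = None,
    annotation: Optional[EyeAnnotation] = None,
) -> None:
    save_recording(paths.lfp, rec)
    save_trial_log(paths.trials, log)
    save_keypoints(paths.head, head)
    if eye is not None:
        if paths.eye is None:
            raise ValueError("eye keypoints given but no eye path configured")
        save_keypoints(paths.eye, eye)
    if annotation is not None:
        if paths.annotation is None:
            raise ValueError("annotation given but no annotation path configured")
        save_annotation(paths.annotation, annotation)


def load_session(
    paths: SessionPaths,
) -> tuple[ContinuousRecording, TrialLog, Keypoints, Optional[Keypoints], Optional[EyeAnnotation]]:
    """Load all session streams and check they share the recording span.

    The eye stream is optional (head-only sessions).  Raises
    :class:`AlignmentError` if any trial onset or offset falls outside the
    recording.
    """
    rec = load_recording(paths.lfp)
    log = load_trial_log(paths.trials)
    t_end = rec.t0 + rec.duration
    if log.onsets[0] < rec.t0 or log.offsets[-1] > t_end:
        raise AlignmentError(
            f"trials span [{log.onsets[0]:.3f}, {log.offsets[-1]:.3f}] s but the "
            f"recording covers [{rec.t0:.3f}, {t_end:.3f}] s"
        )
    head = load_keypoints(paths.head)
    eye = load_keypoints(paths.eye) if paths.eye is not None and Path(paths.eye).exists() else None
    ann = (
        load_annotation(paths.annotation)
        if paths.annotation is not None and Path(paths.annotation).exists()
        else None
    )
    return rec, log, head, eye, ann
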