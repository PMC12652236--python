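"""Trial response-intensity scores from continuous LFP.

The response to each stimulus is summarised by projecting its response-window
waveform onto a single principal axis.  The axis is fit on class-balanced
subsets — all retained deviant trials plus an equal number of randomly drawn
standard trials — and averaged over many resamples, which keeps the abundant
standard trials from dominating the decomposition while stabilising the axis
against the small deviant count.  All trials are then scored on the averaged
axis, and group scores are normalised by the standard-trial distribution:

    nPC1_X = (mPC1_X - mPC1_Standard) / sPC1_Standard

with nPC1 > 2 conventionally treated as session-level significance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .session_io import ContinuousRecording, TrialLog

__all__ = [
    "ResponseMatrix",
    "PCModel",
    "ScoreTable",
    "ControlProjection",
    "DegenerateModelError",
    "extract_response_matrix",
    "select_channel",
    "fit_balanced_pc1",
    "project_scores",
    "project_control_session",
]

ARTIFACT_THRESHOLD_UV = 900.0
TARGET_FS = 400.0
DEFAULT_WINDOW = (0.080, 0.580)


class DegenerateModelError(ValueError):
    """The response matrix has no variance to decompose."""


@dataclasses.dataclass
class ResponseMatrix:
    """Retained-trial response windows, downsampled to 400 Hz.

    ``data`` has one row per retained trial (``trial_indices`` maps rows back
    to the trial log); ``artifact_mask`` is True for trials rejected because
    some sample in the window exceeded 900 uV in magnitude.
    """

    data: np.ndarray
    trial_indices: np.ndarray
    artifact_mask: np.ndarray  # over all trials in the log
    channel_id: int
    window: tuple[float, float]
    align: str = "onset"

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class PCModel:
    """Averaged, sign-oriented first principal axis for scoring trials."""

    center: np.ndarray
    axis: np.ndarray  # unit vector, sign of the first repeat
    orientation_sign: int  # +-1 so that oriented deviant mean >= standard mean
    n_repeats: int
    seed: Optional[int] = None

    def score(self, matrix: ResponseMatrix, oriented: bool = True) -> np.ndarray:
        if matrix.n_samples != len(self.axis):
            raise ValueError(
                f"matrix has {matrix.n_samples} columns but the model expects {len(self.axis)}"
            )
        raw = (matrix.data - self.center) @ self.axis
        return self.orientation_sign * raw if oriented else raw

    def to_json(self, path: Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "center": self.center.tolist(),
                    "axis": self.axis.tolist(),
                    "orientation_sign": int(self.orientation_sign),
                    "n_repeats": int(self.n_repeats),
                    "seed": self.seed,
                }
            )
        )

    @classmethod
    def from_json(cls, path: Path) -> "PCModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["center"]),
            np.asarray(d["axis"]),
            int(d["orientation_sign"]),
            int(d["n_repeats"]),
            d.get("seed"),
        )


@dataclasses.dataclass
class ScoreTable:
    """Per-trial scores plus named trial groups.

    ``scores`` is indexed by trial index (retained trials only).  The
    ``Standard`` group is the reference pool: standard trials excluding the
    first ten of the session.
    """

    scores: pd.Series
    groups: dict[str, np.ndarray]  # name -> trial indices

    def group_scores(self, name: str) -> np.ndarray:
        idx = [i for i in self.groups[name] if i in self.scores.index]
        return self.scores.loc[idx].to_numpy()

    def npc1(self, name: str) -> float:
        std = self.group_scores("Standard")
        s = std.std(ddof=1)
        if not s > 0:
            raise DegenerateModelError("standard-score SD is zero; nPC1 undefined")
        return float((self.group_scores(name).mean() - std.mean()) / s)

    def to_frame(self, log: TrialLog) -> pd.DataFrame:
        df = log.df.loc[self.scores.index, ["trial_index", "condition"]].copy()
        df["pc1_score"] = self.scores.to_numpy()
        for name, idx in self.groups.items():
            df[f"in_{name}"] = df["trial_index"].isin(idx)
        return df


def _window_slice(
    rec: ContinuousRecording, t_ref: float, window: tuple[float, float]
) -> tuple[int, int]:
    k0 = rec.time_to_sample(t_ref + window[0])
    k1 = rec.time_to_sample(t_ref + window[1])
    return k0, k1


def extract_response_matrix(
    rec: ContinuousRecording,
    log: TrialLog,
    channel: Optional[int] = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    align: str = "onset",
    artifact_threshold_uv: float = ARTIFACT_THRESHOLD_UV,
) -> ResponseMatrix:
    """Cut, artifact-screen and downsample per-trial response windows.

    The window (default 80-580 ms after stimulus onset) is cut from the raw
    trace for every trial, reduced to 400 Hz by averaging consecutive
    non-overlapping sample blocks (exact 200 columns for the default window),
    and trials containing any sample above the artifact threshold inside the
    window are masked out.  ``align="offset"`` measures the same window from
    stimulus offset instead (offset-response variant).

    If ``channel`` is None the analysis channel is chosen by
    :func:`select_channel`.
    """
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    factor = rec.fs / TARGET_FS
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"sampling rate {rec.fs} Hz is not a multiple of {TARGET_FS:g} Hz")
    factor = int(round(factor))
    n_out = int(round((window[1] - window[0]) * TARGET_FS))
    if n_out < 1:
        raise ValueError("window too short")
    n_raw = n_out * factor

    refs = log.onsets if align == "onset" else log.offsets
    starts = np.array([_window_slice(rec, t, window)[0] for t in refs])
    if starts.min() < 0 or (starts + n_raw).max() > rec.n_samples:
        raise ValueError("response window extends past the recording")

    if channel is None:
        channel = select_channel(rec, starts, n_raw)
    trace = rec.voltage[channel]
    idx = starts[:, None] + np.arange(n_raw)[None, :]
    raw = trace[idx]  # trials x n_raw
    artifact = np.abs(raw).max(axis=1) > artifact_threshold_uv
    data = raw.reshape(len(refs), n_out, factor).mean(axis=2)
    keep = ~artifact
    return ResponseMatrix(
        data=np.asarray(data[keep], float),
        trial_indices=log.df["trial_index"].to_numpy()[keep],
        artifact_mask=artifact,
        channel_id=int(channel),
        window=tuple(window),
        align=align,
    )


def select_channel(rec: ContinuousRecording, starts: np.ndarray, n_raw: int) -> int:
    """Pick the channel with the largest across-trial SD of the window mean.

    Deterministic stand-in for manual channel curation; ties break to the
    lowest channel index.
    """
    sds = np.empty(rec.n_channels)
    for ch in range(rec.n_channels):
        idx = starts[:, None] + np.arange(n_raw)[None, :]
        means = rec.voltage[ch][idx].mean(axis=1)
        sds[ch] = means.std()
    return int(np.argmax(sds))


def fit_balanced_pc1(
    matrix: ResponseMatrix,
    log: TrialLog,
    n_per_group: int = 20,
    n_repeats: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PCModel:
    """Fit the averaged balanced first principal axis.

    Each repeat takes all retained deviant trials plus an equally sized
    random subset of retained standard trials, centers those rows on their
    mean, and extracts the leading principal axis.  Axes are sign-aligned to
    the first repeat before averaging (PCA axes are sign-ambiguous), the
    average is renormalised, and the final orientation sign is chosen so the
    mean deviant score is at least the mean standard score.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cond = log.conditions[np.searchsorted(log.df["trial_index"].to_numpy(), matrix.trial_indices)]
    dev_rows = np.flatnonzero(cond == "deviant")
    std_rows = np.flatnonzero(cond == "standard")
    if len(dev_rows) < n_per_group:
        raise ValueError(f"need >= {n_per_group} retained deviant trials, have {len(dev_rows)}")
    if len(std_rows) < len(dev_rows):
        raise ValueError(
            f"need >= {len(dev_rows)} retained standard trials, have {len(std_rows)}"
        )
    if not matrix.data.std() > 0:
        raise DegenerateModelError("response matrix has zero variance")

    axes = np.empty((n_repeats, matrix.n_samples))
    centers = np.empty((n_repeats, matrix.n_samples))
    for r in range(n_repeats):
        pick = rng.choice(std_rows, size=len(dev_rows), replace=False)
        rows = matrix.data[np.concatenate([dev_rows, pick])]
        center = rows.mean(axis=0)
        centered = rows - center
        if not centered.std() > 0:
            raise DegenerateModelError("balanced subset has zero variance")
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        if r > 0 and axis @ axes[0] < 0:
            axis = -axis
        axes[r] = axis
        centers[r] = center
    mean_axis = axes.mean(axis=0)
    norm = np.linalg.norm(mean_axis)
    if not norm > 0:
        raise DegenerateModelError("averaged axis vanished")
    mean_axis /= norm
    center = centers.mean(axis=0)

    raw_scores = (matrix.data - center) @ mean_axis
    sign = 1 if raw_scores[dev_rows].mean() >= raw_scores[std_rows].mean() else -1
    return PCModel(center=center, axis=mean_axis, orientation_sign=sign, n_repeats=n_repeats, seed=seed)


def project_scores(
    matrix: ResponseMatrix,
    model: PCModel,
    log: TrialLog,
    extra_groups: Optional[Mapping[str, Sequence[int]]] = None,
) -> ScoreTable:
    """Score every retained trial and assemble the named trial groups.

    Base groups: ``Standard`` (standards minus the first ten trials),
    ``Deviant``, ``First10``, ``1After``.  ``extra_groups`` adds e.g. the
    gaze-derived Left / Right / FirstView groups (trial indices).
    """
    scores = pd.Series(model.score(matrix), index=pd.Index(matrix.trial_indices, name="trial_index"))
    ti = log.df["trial_index"].to_numpy()
    groups = {
        "Standard": ti[log.mask("Standard") & ~log.mask("First10")],
        "Deviant": ti[log.mask("Deviant")],
        "First10": ti[log.mask("First10")],
        "1After": ti[log.mask("1After")],
    }
    if extra_groups:
        for name, idx in extra_groups.items():
            groups[name] = np.asarray(list(idx), dtype=int)
    retained = set(matrix.trial_indices.tolist())
    groups = {k: np.asarray([i for i in v if i in retained], int) for k, v in groups.items()}
    return ScoreTable(scores=scores, groups=groups)


@dataclasses.dataclass
class ControlProjection:
    """Spatial-control projection of a uniform-position session."""

    position_means: dict[tuple[int, int], float]
    flipped: bool
    p_adjusted: float
    bias_explained: bool
    control_scores: pd.Series
    corrected_effect: float = float("nan")  # |deviant - standard| after correction


def project_control_session(
    control_matrix: ResponseMatrix,
    oddball_model: PCModel,
    oddball_matrix: ResponseMatrix,
    oddball_log: TrialLog,
    control_log: TrialLog,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> ControlProjection:
    """Test whether an oddball session's novelty effect is a spatial bias.

    Control trials are scored with the oddball session's axis; sessions whose
    raw (unoriented) novelty effect was negative have all control scores
    flipped — applying ``orientation_sign`` implements exactly that rule.
    Each oddball trial then has the control mean score at its own screen
    position subtracted, and the deviant-vs-standard permutation test is
    re-run on the corrected scores.  A session whose corrected effect loses
    significance (p > alpha) is flagged as bias-explained.
    """
    from .permutation import session_permutation_test

    control_scores = pd.Series(
        oddball_model.score(control_matrix),
        index=pd.Index(control_matrix.trial_indices, name="trial_index"),
    )
    cpos = control_log.positions[
        np.searchsorted(control_log.df["trial_index"].to_numpy(), control_matrix.trial_indices)
    ]
    position_means: dict[tuple[int, int], float] = {}
    for pos in {tuple(p) for p in cpos.tolist()}:
        sel = (cpos[:, 0] == pos[0]) & (cpos[:, 1] == pos[1])
        position_means[pos] = float(control_scores.to_numpy()[sel].mean())

    opos = oddball_log.positions[
        np.searchsorted(oddball_log.df["trial_index"].to_numpy(), oddball_matrix.trial_indices)
    ]
    missing = {tuple(p) for p in opos.tolist()} - set(position_means)
    if missing:
        raise ValueError(f"oddball positions absent from the control session: {sorted(missing)}")

    odd_scores = oddball_model.score(oddball_matrix)
    corrected = odd_scores - np.array([position_means[tuple(p)] for p in opos.tolist()])
    table = project_scores(oddball_matrix, oddball_model, oddball_log)
    table = ScoreTable(
        scores=pd.Series(corrected, index=pd.Index(oddball_matrix.trial_indices, name="trial_index")),
        groups=table.groups,
    )
    res = session_permutation_test(table, "Deviant", n_perm=n_perm, seed=seed)
    return ControlProjection(
        position_means=position_means,
        flipped=oddball_model.orientation_sign < 0,
        p_adjusted=res.p_value,
        bias_explained=bool(res.p_value > alpha),
        control_scores=control_scores,
        corrected_effect=res.observed,
    )
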