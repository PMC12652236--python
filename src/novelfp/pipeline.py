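"""End-to-end session and group analyses.

`run_oddball_analysis` composes the full chain: response-window extraction
-> balanced-PCA response intensities -> trial-group permutation tests ->
gaze table and angle-split tests -> movement-vs-stimulus magnitudes.  The
result is a JSON-serialisable `SessionResult` that is bit-reproducible from
(inputs, config, seed).  `run_group_analysis` aggregates normalised scores
across sessions and runs the session-label permutation tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import gaze as gz
from . import movement as mv
from .permutation import PermutationResult, group_permutation_test, session_permutation_test
from .response import (
    DEFAULT_WINDOW,
    ScoreTable,
    extract_response_matrix,
    fit_balanced_pc1,
    project_scores,
)
from .session_io import ContinuousRecording, EyeAnnotation, Keypoints, TrialLog

__all__ = ["AnalysisConfig", "SessionResult", "GroupResult", "run_oddball_analysis", "run_group_analysis"]


@dataclasses.dataclass
class AnalysisConfig:
    """Analysis defaults; values mirror the protocol constants.

    window 80-580 ms at 400 Hz, 900 uV artifact cut, 20-trial balanced PCA
    averaged over 100 repeats, 10,000 permutations, +-15 deg left/right
    split, 5 deg first-view distance, 200 ms / 50 ms sliding windows with
    80-480 ms stimulus exclusions.
    """

    window: tuple[float, float] = DEFAULT_WINDOW
    align: str = "onset"
    channel: Optional[int] = None
    artifact_threshold_uv: float = 900.0
    n_per_group: int = 20
    n_repeats: int = 100
    n_perm: int = 10_000
    min_likelihood: float = 0.9
    movement_k_sd: float = 2.0
    movement_min_separation_s: float = 1.0
    run_gaze: bool = True
    run_movement: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        return d

    @classmethod
    def from_yaml(cls, path: Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "window" in d:
            d["window"] = tuple(d["window"])
        return cls(**d)

    def hash(self) -> str:
        """Digest of the analysis parameters (seed excluded: it varies per
        session without making sessions incomparable)."""
        d = self.to_dict()
        d.pop("seed")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclasses.dataclass
class SessionResult:
    npc1: dict[str, float]
    tests: dict[str, PermutationResult]
    n_trials: int
    n_retained: int
    n_artifact: int
    channel: int
    gaze_summary: Optional[dict] = None
    movement_summary: Optional[dict] = None
    config_hash: str = ""
    seed: int = 0

    def significant(self, group: str = "Deviant", alpha: float = 0.05) -> bool:
        return self.tests[group].p_value < alpha

    def to_dict(self) -> dict:
        return {
            "npc1": self.npc1,
            "tests": {k: v.to_dict() for k, v in self.tests.items()},
            "n_trials": self.n_trials,
            "n_retained": self.n_retained,
            "n_artifact": self.n_artifact,
            "channel": self.channel,
            "gaze_summary": self.gaze_summary,
            "movement_summary": self.movement_summary,
            "config_hash": self.config_hash,
            "seed": self.seed,
        }

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _gaze_groups(table: gz.GazeTable, log: TrialLog) -> dict[str, np.ndarray]:
    """Left/Right/FirstView trial-index groups for score statistics.

    Group statistics use standard-condition trials only, excluding the
    first ten trials of the session — those form their own, unadapted group
    and would otherwise masquerade as an angle or first-view effect.
    """
    keep = set(
        log.df.loc[log.mask("Standard") & ~log.mask("First10"), "trial_index"].tolist()
    )
    groups = {}
    for name in ("Left", "Right", "FirstView"):
        idx = table.trial_indices(name)
        groups[name] = np.asarray([i for i in idx if i in keep], int)
    return groups


def run_oddball_analysis(
    rec: ContinuousRecording,
    log: TrialLog,
    head: Optional[Keypoints] = None,
    eye: Optional[Keypoints] = None,
    annotation: Optional[EyeAnnotation] = None,
    config: Optional[AnalysisConfig] = None,
) -> SessionResult:
    """Run the full single-session oddball analysis."""
    cfg = config or AnalysisConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_fit, rng_perm = [np.random.default_rng(s) for s in ss.spawn(2)]

    matrix = extract_response_matrix(
        rec, log, channel=cfg.channel, window=cfg.window, align=cfg.align,
        artifact_threshold_uv=cfg.artifact_threshold_uv,
    )
    model = fit_balanced_pc1(
        matrix, log, n_per_group=cfg.n_per_group, n_repeats=cfg.n_repeats, rng=rng_fit
    )

    gaze_summary = None
    extra_groups: dict[str, np.ndarray] = {}
    gaze_table = None
    if cfg.run_gaze and head is not None:
        gaze_table = gz.build_gaze_table(head, log, eye, annotation, cfg.min_likelihood)
        extra_groups = _gaze_groups(gaze_table, log)

    scores = project_scores(matrix, model, log, extra_groups=extra_groups)

    tests: dict[str, PermutationResult] = {}
    npc1: dict[str, float] = {}
    for name in ("Deviant", "First10", "1After"):
        if len(scores.groups.get(name, ())):
            tests[name] = session_permutation_test(scores, name, n_perm=cfg.n_perm, rng=rng_perm)
            npc1[name] = scores.npc1(name)
    npc1["Standard"] = scores.npc1("Standard")  # 0 by construction

    if gaze_table is not None:
        left = scores.group_scores("Left") if len(extra_groups.get("Left", ())) else np.array([])
        right = scores.group_scores("Right") if len(extra_groups.get("Right", ())) else np.array([])
        if len(left) and len(right):
            tests["LeftVsRight"] = group_permutation_test(left, right, n_perm=cfg.n_perm, rng=rng_perm)
            npc1["Left"] = scores.npc1("Left")
            npc1["Right"] = scores.npc1("Right")
        if len(extra_groups.get("FirstView", ())):
            tests["FirstView"] = session_permutation_test(scores, "FirstView", n_perm=cfg.n_perm, rng=rng_perm)
            npc1["FirstView"] = scores.npc1("FirstView")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gdf = gaze_table.df
            std_mask = log.mask("Standard")
            dev_mask = log.mask("Deviant")
            gaze_summary = {
                "n_left": int((gdf["angle_group"] == "left").sum()),
                "n_right": int((gdf["angle_group"] == "right").sum()),
                "n_first_view": int(len(extra_groups.get("FirstView", ()))),
                "theta_sd": float(np.nanstd(gdf["theta"])),
                # per-session mean speeds feed the paired t test across sessions
                "head_speed_standard": float(np.nanmean(gdf["head_speed"].to_numpy()[std_mask])),
                "head_speed_deviant": float(np.nanmean(gdf["head_speed"].to_numpy()[dev_mask])),
            }
            theta = gdf["theta"].to_numpy()
            phi_x = gdf["phi_x"].to_numpy()
            both = ~np.isnan(theta) & ~np.isnan(phi_x)
            if both.sum() >= 3 and np.std(theta[both]) > 0 and np.std(phi_x[both]) > 0:
                from .permutation import pearson_correlation

                r, p = pearson_correlation(theta[both], phi_x[both])
                gaze_summary["head_eye_pearson_r"] = r
                gaze_summary["head_eye_pearson_p"] = p

    movement_summary = None
    if cfg.run_movement and head is not None:
        movement_summary = _movement_block(rec, log, head, matrix.channel_id, cfg)

    return SessionResult(
        npc1=npc1,
        tests=tests,
        n_trials=len(log),
        n_retained=len(matrix.trial_indices),
        n_artifact=int(matrix.artifact_mask.sum()),
        channel=matrix.channel_id,
        gaze_summary=gaze_summary,
        movement_summary=movement_summary,
        config_hash=cfg.hash(),
        seed=cfg.seed,
    )


def _movement_block(
    rec: ContinuousRecording,
    log: TrialLog,
    head: Keypoints,
    channel: int,
    cfg: AnalysisConfig,
) -> dict:
    """Per-session movement and stimulus relative magnitudes."""
    rostral = head.point("rostral", cfg.min_likelihood)
    t, speed = gz.speed_trace(rostral)
    onsets = mv.detect_movement_onsets(
        speed, t, log, k_sd=cfg.movement_k_sd, min_separation_s=cfg.movement_min_separation_s
    )
    rels = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for on in onsets:
            epoch = mv.movement_relative_magnitude(
                rec, mv.MovementEpoch(float(on), "head"), log, all_movement_onsets=onsets,
                channel=channel,
            )
            if epoch is not None:
                rels.append(epoch.relative_magnitude)
    stim_rel = {}
    for cond in ("standard", "deviant"):
        idx = np.flatnonzero(log.conditions == cond)
        vals = []
        for i in idx:
            try:
                vals.append(mv.stimulus_relative_magnitude(rec, log, int(i), channel))
            except ValueError:
                continue
        stim_rel[cond] = float(np.mean(vals)) if vals else float("nan")
    return {
        "n_movement_epochs": len(rels),
        "movement_mean_uv": float(np.mean(rels)) if rels else float("nan"),
        "stimulus_standard_mean_uv": stim_rel["standard"],
        "stimulus_deviant_mean_uv": stim_rel["deviant"],
    }


@dataclasses.dataclass
class GroupResult:
    npc1_by_group: dict[str, list[float]]
    tests: dict[str, PermutationResult]
    movement: Optional[mv.MovementComparison] = None
    speed_ttest: Optional[dict] = None  # paired standard-vs-deviant head speed

    def to_dict(self) -> dict:
        return {
            "npc1_by_group": self.npc1_by_group,
            "tests": {k: v.to_dict() for k, v in self.tests.items()},
            "movement": self.movement.to_dict() if self.movement else None,
            "speed_ttest": self.speed_ttest,
        }


def run_group_analysis(
    results: Sequence[SessionResult],
    n_perm: int = 10_000,
    seed: int = 0,
) -> GroupResult:
    """Across-session aggregation and session-label permutation tests.

    Each session contributes its normalised (standard-SD-scaled) group
    scores; the Deviant/First10/1After groups are tested against the
    all-zero Standard reference, and the deviant effect is compared with the
    left-right and first-view effects where sessions report them.
    """
    if len(results) < 2:
        raise ValueError("group analysis needs at least 2 sessions")
    hashes = {r.config_hash for r in results}
    if len(hashes) > 1:
        warnings.warn("sessions analysed with heterogeneous configs", stacklevel=2)
    rng = np.random.default_rng(seed)

    by_group: dict[str, list[float]] = {}
    for r in results:
        for k, v in r.npc1.items():
            by_group.setdefault(k, []).append(v)

    tests: dict[str, PermutationResult] = {}
    std = by_group.get("Standard", [0.0] * len(results))
    for name in ("Deviant", "First10", "1After", "FirstView"):
        if name in by_group and len(by_group[name]) >= 2:
            tests[f"{name}VsStandard"] = group_permutation_test(by_group[name], std[: len(by_group[name])], n_perm=n_perm, rng=rng)
    # effect-size comparisons: deviant effect against angle-split effects
    if "Left" in by_group and "Right" in by_group:
        lr = [abs(l - r) for l, r in zip(by_group["Left"], by_group["Right"])]
        dev = [abs(d) for d, _ in zip(by_group.get("Deviant", []), lr)]
        if len(dev) >= 2:
            tests["DeviantEffectVsLeftRight"] = group_permutation_test(dev, lr, n_perm=n_perm, rng=rng)
    if "FirstView" in by_group:
        fv = [abs(v) for v in by_group["FirstView"]]
        dev = [abs(d) for d, _ in zip(by_group.get("Deviant", []), fv)]
        if len(dev) >= 2:
            tests["DeviantEffectVsFirstView"] = group_permutation_test(dev, fv, n_perm=n_perm, rng=rng)

    speed_ttest = None
    gz_sums = [r.gaze_summary for r in results]
    if all(g is not None and "head_speed_standard" in g for g in gz_sums):
        from scipy import stats as _stats

        a = np.array([g["head_speed_standard"] for g in gz_sums])
        b = np.array([g["head_speed_deviant"] for g in gz_sums])
        ok = ~np.isnan(a) & ~np.isnan(b)
        if ok.sum() >= 2 and np.ptp(b[ok] - a[ok]) > 0:
            t, p = _stats.ttest_rel(b[ok], a[ok])
            speed_ttest = {"t": float(t), "p": float(p), "n": int(ok.sum())}

    movement = None
    move = [r.movement_summary for r in results]
    if all(m is not None for m in move):
        try:
            movement = mv.compare_movement_vs_stimulus(
                [m["movement_mean_uv"] for m in move],
                [m["stimulus_standard_mean_uv"] for m in move],
                [m["stimulus_deviant_mean_uv"] for m in move],
            )
        except ValueError:
            movement = None
    return GroupResult(npc1_by_group=by_group, tests=tests, movement=movement, speed_ttest=speed_ttest)
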