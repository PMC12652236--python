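"""Repeated-session simulation studies built on the pipeline.

These runners regenerate synthetic sessions under controlled conditions and
push each one through the full analysis chain; they back the package's
calibration and validation claims:

* `null_calibration` — false-positive behaviour of the session test and of
  the nPC1 > 2 significance convention on effect-free sessions;
* `power_run` — detection rate as a function of the deviant/standard gain
  ratio;
* `regime_comparison` — allocentric versus retinotopic adaptation: does the
  angle-split analysis tell the two generative regimes apart;
* `movement_comparison_run` — stimulus-evoked versus movement-locked LFP
  magnitudes across sessions.

Simulated sessions use a 2 kHz LFP rate (any multiple of 400 Hz yields the
same 200-sample windows; see docs) and the generator's default schedule of
200 trials with ~10% deviants (20 deviant presentations).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .movement import MovementComparison
from .pipeline import AnalysisConfig, SessionResult, run_group_analysis, run_oddball_analysis
from .synthetic import SessionConfig, SyntheticSession, generate_oddball_session

__all__ = [
    "fast_session_config",
    "analyze_synthetic",
    "null_calibration",
    "power_run",
    "regime_comparison",
    "movement_comparison_run",
]

SIM_FS_LFP = 2000.0


def fast_session_config(seed: int = 0, **overrides) -> SessionConfig:
    """Default simulation conditions at the reduced 2 kHz LFP rate."""
    return dataclasses.replace(
        SessionConfig(fs_lfp=SIM_FS_LFP, include_eye=False, seed=seed), **overrides
    )


def _session_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=2 * n).reshape(n, 2)


def analyze_synthetic(
    config: SessionConfig,
    analysis: Optional[AnalysisConfig] = None,
) -> tuple[SyntheticSession, SessionResult]:
    session = generate_oddball_session(config)
    cfg = analysis or AnalysisConfig()
    result = run_oddball_analysis(
        session.recording,
        session.log,
        head=session.head if (cfg.run_gaze or cfg.run_movement) else None,
        eye=session.eye,
        annotation=session.annotation,
        config=cfg,
    )
    return session, result


def power_run(
    gain_ratio: float,
    n_sessions: int,
    seed: int = 0,
    n_perm: int = 10_000,
) -> dict:
    """Detection behaviour at a given deviant/standard asymptotic gain ratio.

    ``gain_ratio`` scales both the deviant gain and the unadapted
    first-presentation gain against a standard floor of 1; ratio 1 is the
    null (flat gains, no adaptation).  Returns per-session deviant p-values
    and nPC1 values plus the fraction significant at alpha = 0.05.
    """
    seeds = _session_seeds(seed, n_sessions)
    pvals = np.empty(n_sessions)
    npc1 = np.empty(n_sessions)
    for i, (s_gen, s_an) in enumerate(seeds):
        cfg = fast_session_config(
            seed=int(s_gen),
            gain_deviant=float(gain_ratio),
            gain_standard_initial=float(gain_ratio),
            gain_standard_floor=1.0,
        )
        an = AnalysisConfig(run_gaze=False, run_movement=False, n_perm=n_perm, seed=int(s_an))
        _, res = analyze_synthetic(cfg, an)
        pvals[i] = res.tests["Deviant"].p_value
        npc1[i] = res.npc1["Deviant"]
    return {
        "gain_ratio": gain_ratio,
        "p_values": pvals,
        "npc1_deviant": npc1,
        "fraction_significant": float((pvals < 0.05).mean()),
        "fraction_npc1_gt2": float((npc1 > 2.0).mean()),
    }


def null_calibration(n_sessions: int, seed: int = 0, n_perm: int = 10_000) -> dict:
    """False-positive rates on effect-free sessions (gain ratio 1)."""
    out = power_run(1.0, n_sessions, seed=seed, n_perm=n_perm)
    return {
        "n_sessions": n_sessions,
        "p_values": out["p_values"],
        "npc1_deviant": out["npc1_deviant"],
        "fraction_p_lt_05": out["fraction_significant"],
        "fraction_npc1_gt2": out["fraction_npc1_gt2"],
    }


def regime_comparison(
    adaptation_mode: str,
    n_sessions: int,
    seed: int = 0,
    n_perm: int = 2000,
) -> dict:
    """Angle-split analysis under a chosen adaptation regime.

    Sessions carry the default planted novelty effect; the head angle walks
    freely.  Reports, per session, significance of the deviant test, the
    left-vs-right comparison and the first-view test, and the corresponding
    nPC1 values.
    """
    seeds = _session_seeds(seed, n_sessions)
    rows = {k: [] for k in ("p_deviant", "p_left_right", "p_first_view",
                            "npc1_deviant", "npc1_first_view")}
    for s_gen, s_an in seeds:
        cfg = fast_session_config(seed=int(s_gen), adaptation_mode=adaptation_mode)
        an = AnalysisConfig(run_gaze=True, run_movement=False, n_perm=n_perm, seed=int(s_an))
        _, res = analyze_synthetic(cfg, an)
        rows["p_deviant"].append(res.tests["Deviant"].p_value)
        rows["p_left_right"].append(res.tests["LeftVsRight"].p_value if "LeftVsRight" in res.tests else np.nan)
        rows["p_first_view"].append(res.tests["FirstView"].p_value if "FirstView" in res.tests else np.nan)
        rows["npc1_deviant"].append(res.npc1["Deviant"])
        rows["npc1_first_view"].append(res.npc1.get("FirstView", np.nan))
    out = {k: np.asarray(v, float) for k, v in rows.items()}
    out["adaptation_mode"] = adaptation_mode
    out["fraction_deviant_significant"] = float((out["p_deviant"] < 0.05).mean())
    out["fraction_left_right_significant"] = float(np.nanmean(out["p_left_right"] < 0.05))
    out["fraction_first_view_significant"] = float(np.nanmean(out["p_first_view"] < 0.05))
    return out


def movement_comparison_run(
    n_sessions: int,
    seed: int = 0,
    movement_lfp_gain: float = 0.0,
) -> tuple[MovementComparison, list[SessionResult]]:
    """Movement-vs-stimulus comparison across synthetic sessions.

    With ``movement_lfp_gain = 0`` (the default) the simulated cortex is
    movement-silent: any detected movement-locked activity is background.
    """
    seeds = _session_seeds(seed, n_sessions)
    results = []
    for s_gen, s_an in seeds:
        cfg = fast_session_config(seed=int(s_gen), movement_lfp_gain=movement_lfp_gain)
        an = AnalysisConfig(run_gaze=False, run_movement=True, n_perm=2000, seed=int(s_an))
        _, res = analyze_synthetic(cfg, an)
        results.append(res)
    group = run_group_analysis(results, n_perm=2000, seed=seed)
    if group.movement is None:
        raise RuntimeError("no sessions with movement epochs")
    return group.movement, results
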