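"""Resampling inference for response-intensity scores.

Two layers of permutation test, both with 10,000 label shuffles by default
and the +1 finite-sample correction, so a reported p can never be exactly 0:

* within a session, a trial-group test: the observed absolute distance
  between the test group's mean score and the standard-pool mean is compared
  to the distances obtained by re-drawing a group of the same size from the
  pooled trials (shuffled trial identities);
* across sessions, a group test: the absolute difference between two sets
  of per-session scalars is compared against session-label shuffles.

The standard pool always excludes the first ten trials of the session and,
when the test group itself consists of standard trials (1After, FirstView),
those trials as well, so the two compared groups are disjoint.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .response import ScoreTable

__all__ = [
    "PermutationResult",
    "session_permutation_test",
    "group_permutation_test",
    "pearson_correlation",
]


@dataclasses.dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_permutations: int
    permuted_mean: float
    permuted_sd: float
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "permuted_mean": self.permuted_mean,
            "permuted_sd": self.permuted_sd,
            "seed": self.seed,
        }


def _subset_distance_null(
    pool: np.ndarray, m: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distances |mean(random m-subset) - mean(complement)|."""
    n = len(pool)
    total = pool.sum()
    u = rng.random((n_perm, n))
    sel = np.argpartition(u, m - 1, axis=1)[:, :m]
    sub = np.take(pool, sel).sum(axis=1)
    return np.abs(sub / m - (total - sub) / (n - m))


def _tie_aware_p(null: np.ndarray, observed: float, n_perm: int) -> float:
    """+1-corrected p counting numerical ties as exceedances.

    A permutation that redraws the observed grouping recomputes the same
    distance along a different floating-point path; a strict ``>=`` would
    then drop a true tie over a last-ulp difference, so ties are detected
    with a small relative tolerance.
    """
    thresh = observed - 1e-9 * abs(observed)
    return (1 + int((null >= thresh).sum())) / (1 + n_perm)


def session_permutation_test(
    scores: ScoreTable,
    test_group: str,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """Trial-shuffle test of one trial group against the standard pool.

    The null re-draws, per permutation, a random subset the size of the test
    group from the pooled trials and measures the same absolute mean
    distance; the subset size is therefore 20 for a 20-deviant session and
    10 for the First10 group, following the group's own size.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    test = scores.group_scores(test_group)
    # reference pool disjoint from the test group (no-op for Deviant/First10)
    overlap = set(scores.groups[test_group].tolist())
    keep = [i for i in scores.groups["Standard"] if i not in overlap]
    std = scores.scores.loc[[i for i in keep if i in scores.scores.index]].to_numpy()
    if len(test) == 0:
        raise ValueError(f"test group {test_group!r} is empty")
    if len(std) <= len(test):
        raise ValueError("standard pool must be larger than the test group")
    observed = abs(test.mean() - std.mean())
    pool = np.concatenate([std, test])
    null = _subset_distance_null(pool, len(test), n_perm, rng)
    p = _tie_aware_p(null, observed, n_perm)
    return PermutationResult(float(observed), float(p), n_perm, float(null.mean()), float(null.std(ddof=1)), seed)


def group_permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """Shuffle labels between two sets of per-session scalars.

    Paired designs (e.g. comparing a standard-vs-deviant difference against
    a left-vs-right difference over the same sessions) are handled by
    passing the two difference vectors.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) + len(b) < 2:
        raise ValueError("need at least two values in total")
    observed = abs(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    null = _subset_distance_null(pool, len(a), n_perm, rng)
    p = _tie_aware_p(null, observed, n_perm)
    return PermutationResult(float(observed), float(p), n_perm, float(null.mean()), float(null.std(ddof=1)), seed)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p via the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
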