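"""Scoring of delayed match-to-sample trials on the 8-shape stimulus ring.

Two discrimination measures are produced per participant x time point:

* **accuracy** — proportion of exact matches (hits);
* **relative distance error** — the trial-averaged ring distance between the
  target and the chosen stimulus, normalised by the expected ring distance of
  a uniform random responder.  Chance-level responding therefore scores ~1,
  perfect matching scores 0, and an anti-correlated responder can score
  slightly above 1.

Ring distances live on a weighted cycle: consecutive shapes 1-2, ..., 7-8 are
one step apart, while the edge between shapes 8 and 1 spans three steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .shapes import RING_SIZE, WRAP_STEPS

logger = logging.getLogger(__name__)

GROUPS = (
    "graphomotor-nondominant",
    "graphomotor-dominant",
    "visual-dynamic",
    "visual-static",
    "visual-template",
)
TIME_POINTS = ("pre", "post", "retention")


def ring_distance(i: int, j: int) -> int:
    """Shortest path (steps) between shapes ``i`` and ``j`` on the ring.

    The cycle has unit-weight edges (k, k+1) for k = 1..7 and a 3-step edge
    between 8 and 1.
    """
    if not (1 <= i <= RING_SIZE and 1 <= j <= RING_SIZE):
        raise ValueError(f"shape ids must be in 1..{RING_SIZE}, got ({i}, {j})")
    direct = abs(i - j)
    around = WRAP_STEPS + (min(i, j) - 1) + (RING_SIZE - max(i, j))
    return min(direct, around)


@lru_cache(maxsize=1)
def ring_distance_matrix() -> np.ndarray:
    """8x8 matrix of ring distances (index 0 = shape 1)."""
    d = np.zeros((RING_SIZE, RING_SIZE), dtype=int)
    for i in range(1, RING_SIZE + 1):
        for j in range(1, RING_SIZE + 1):
            d[i - 1, j - 1] = ring_distance(i, j)
    d.setflags(write=False)
    return d


@lru_cache(maxsize=1)
def chance_distance_error() -> float:
    """Expected ring distance for uniform random target and uniform choice.

    This is the normalisation constant of the relative distance error: a
    uniform random responder has expected (unnormalised) mean ring distance
    equal to this value, hence normalised error 1.0.
    """
    return float(ring_distance_matrix().mean())


@dataclass(frozen=True)
class AssessmentScore:
    """Scores of one participant x time-point assessment block."""

    accuracy: float
    distance_error: float
    n_trials: int


def score_assessment(target_ids, chosen_ids) -> AssessmentScore:
    """Score one assessment block (single participant x time point).

    Parameters are parallel sequences of target and chosen shape ids (1-8).
    Hits contribute distance 0 to the error average; the mean ring distance
    is divided by the uniform-responder expectation so chance scores ~1.
    """
    targets = np.asarray(target_ids, dtype=int)
    chosen = np.asarray(chosen_ids, dtype=int)
    if targets.size == 0:
        raise ValueError("empty trial list")
    if targets.shape != chosen.shape:
        raise ValueError("target and chosen id sequences differ in length")
    dmat = ring_distance_matrix()
    dists = dmat[targets - 1, chosen - 1]
    accuracy = float((dists == 0).mean())
    error = float(dists.mean() / chance_distance_error())
    return AssessmentScore(accuracy=accuracy, distance_error=error,
                           n_trials=int(targets.size))


def score_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Score a long trial log into per-participant x time-point measures.

    ``trials`` must carry participant_id, group, time_point, target_id,
    chosen_id.  Returns a tidy frame with accuracy and distance_error
    columns (one row per participant x time point).
    """
    rows = []
    for (pid, group, tp), block in trials.groupby(
            ["participant_id", "group", "time_point"], sort=False):
        score = score_assessment(block["target_id"], block["chosen_id"])
        rows.append({"participant_id": pid, "group": group, "time_point": tp,
                     "accuracy": score.accuracy,
                     "distance_error": score.distance_error,
                     "n_trials": score.n_trials})
    return pd.DataFrame(rows)


def baseline_adjust(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-participant baseline-adjusted changes at post and retention.

    For accuracy the change is ``measure(t) - measure(pre)`` (positive =
    improvement); for distance error it is ``error(pre) - error(t)`` so that
    a positive value again means improvement.  Participants missing any of
    the three time points are excluded (logged).
    """
    out = []
    for (pid, group), block in scores.groupby(["participant_id", "group"], sort=False):
        by_tp = block.set_index("time_point")
        if not set(TIME_POINTS).issubset(by_tp.index):
            logger.warning("participant %s missing time points %s; excluded",
                           pid, set(TIME_POINTS) - set(by_tp.index))
            continue
        for tp in ("post", "retention"):
            out.append({
                "participant_id": pid, "group": group, "time_point": tp,
                "delta_accuracy":
                    by_tp.loc[tp, "accuracy"] - by_tp.loc["pre", "accuracy"],
                "delta_distance_error":
                    by_tp.loc["pre", "distance_error"] - by_tp.loc[tp, "distance_error"],
            })
    return pd.DataFrame(out)
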