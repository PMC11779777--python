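"""Synthetic cohort generator: observers, trial schedules, and pen traces.

No raw data from the original experiments are available, so this module is
the study's stand-in data source.  Three generative pieces:

* an **observer model** for the match-to-sample task — a softmax confusion
  kernel over ring distance with a lapse rate.  The kernel sensitivity is
  calibrated by bisection so that the expected hit rate matches a requested
  accuracy, which lets group learning effects be injected directly on the
  accuracy scale using the published group means and SDs;
* **session schedules** — 64-trial assessment blocks (each of the 8 shapes
  a target 8 times), 200-trial training sessions (8 shapes x 25), and a
  familiarization block containing 16 catch trials (2 per shape);
* a **trace generator** — noisy template traversals whose lateral noise,
  speed, and speed ripple depend on hand and session, anchored to the
  directional findings for dominant vs non-dominant tracing (the dominant
  hand is quicker, spatially more accurate, and temporally smoother; across
  sessions only the non-dominant hand improves in spatial accuracy).

The observer model is a modelling stand-in, not a claim about participants'
actual decision process; see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .assessment import ring_distance_matrix
from .exceptions import InfeasibleTargetError
from .kinematics import Trace
from .shapes import RING_SIZE, ContourShape

#: Accuracies drawn for simulated participants are kept inside this range so
#: the sensitivity calibration stays feasible (observed post-training
#: accuracies spanned roughly 45-92%).
ACCURACY_BOUNDS = (0.13, 0.98)

#: Default lapse rate of the confusion kernel.
DEFAULT_LAPSE = 0.01

#: Trials per assessment block: each shape serves as target 8 times.
ASSESSMENT_TRIALS = 64
#: Training trials per session: 8 shapes x 25 repetitions.
TRAINING_TRIALS = 200
#: Repetitions per shape in a training session.
TRAINING_REPS = 25
#: Catch trials in the familiarization block, two per shape.
CATCH_TRIALS = 16
#: Familiarization block length (8 out-of-set shapes x 5, 2 of 5 catch).
FAMILIARIZATION_TRIALS = 40
#: Transient template-width change of a catch trial (mm, ms).
CATCH_WIDTH_MM = 5.0
CATCH_DURATION_MS = 1200.0


# ---------------------------------------------------------------------------
# Observer model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionKernel:
    """Softmax-over-ring-distance choice model with lapses.

    p(choice j | target t) = (1 - lapse) * softmax_j(-beta * d(t, j)) + lapse / 8
    """

    beta: float
    lapse: float = DEFAULT_LAPSE

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("sensitivity beta must be >= 0")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")


def choice_probabilities(target: int, kernel: ConfusionKernel) -> np.ndarray:
    """Choice probabilities over the 8 samples for one target id (1-8)."""
    return choice_probability_matrix(kernel)[target - 1]


def choice_probability_matrix(kernel: ConfusionKernel) -> np.ndarray:
    """8x8 matrix of p(choice j | target i)."""
    d = ring_distance_matrix().astype(float)
    logits = -kernel.beta * d
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    p = w / w.sum(axis=1, keepdims=True)
    return (1.0 - kernel.lapse) * p + kernel.lapse / RING_SIZE


def expected_accuracy(beta: float, lapse: float = DEFAULT_LAPSE) -> float:
    """Expected hit probability averaged over a uniform random target."""
    p = choice_probability_matrix(ConfusionKernel(beta=beta, lapse=lapse))
    return float(np.mean(np.diag(p)))


def calibrate_sensitivity(target_accuracy: float, lapse: float = DEFAULT_LAPSE,
                          tol: float = 1e-6, max_beta: float = 64.0) -> float:
    """Bisection for the beta whose expected hit rate equals ``target_accuracy``.

    Raises
    ------
    InfeasibleTargetError
        If the target is at/below chance (1/8) or above 1 - 7*lapse/8.
    """
    chance = expected_accuracy(0.0, lapse)
    ceiling = 1.0 - 7.0 * lapse / 8.0
    if not chance < target_accuracy < ceiling:
        raise InfeasibleTargetError(
            f"accuracy {target_accuracy:.4f} outside feasible ({chance:.4f}, "
            f"{ceiling:.4f}) for lapse {lapse}")
    lo, hi = 0.0, 1.0
    while expected_accuracy(hi, lapse) < target_accuracy:
        hi *= 2.0
        if hi > max_beta:
            raise InfeasibleTargetError("sensitivity search exceeded max_beta")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if expected_accuracy(mid, lapse) < target_accuracy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Group configurations (accuracy scale, fractions in [0, 1])
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupConfig:
    """Accuracy distribution of one training group.

    Baseline accuracy and the pre->post / pre->retention changes are drawn
    per participant from truncated normal distributions; defaults carry the
    published group statistics.
    """

    label: str
    n_participants: int = 10
    baseline_mean: float = 0.4563
    baseline_sd: float = 0.083
    d_post_mean: float = 0.207
    d_post_sd: float = 0.096
    d_retention_mean: float = 0.212
    d_retention_sd: float = 0.122


#: Experiment 1: four groups of 10.  Baseline is the pooled pre-training
#: accuracy (no group difference at baseline); the per-group changes carry
#: the published group means/SDs, whose averages are +20.7% (post) and
#: +21.2% (retention).
EXPERIMENT1_GROUPS = (
    GroupConfig("graphomotor-nondominant",
                d_post_mean=0.198, d_post_sd=0.1238,
                d_retention_mean=0.241, d_retention_sd=0.1383),
    GroupConfig("visual-dynamic",
                d_post_mean=0.211, d_post_sd=0.1004,
                d_retention_mean=0.212, d_retention_sd=0.0957),
    GroupConfig("visual-static",
                d_post_mean=0.241, d_post_sd=0.0791,
                d_retention_mean=0.262, d_retention_sd=0.0994),
    GroupConfig("visual-template",
                d_post_mean=0.177, d_post_sd=0.0783,
                d_retention_mean=0.134, d_retention_sd=0.1285),
)

#: Experiment 2: two graphomotor groups of 10 with different baselines.
EXPERIMENT2_GROUPS = (
    GroupConfig("graphomotor-nondominant",
                baseline_mean=0.514, baseline_sd=0.089,
                d_post_mean=0.197, d_post_sd=0.1294,
                d_retention_mean=0.218, d_retention_sd=0.0843),
    GroupConfig("graphomotor-dominant",
                baseline_mean=0.421, baseline_sd=0.078,
                d_post_mean=0.233, d_post_sd=0.130,
                d_retention_mean=0.221, d_retention_sd=0.1377),
)

TIME_POINTS = ("pre", "post", "retention")


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float, max_tries: int = 100) -> float:
    """Redraw-with-truncation sampling; clips after ``max_tries`` redraws."""
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _simulate_block(rng: np.random.Generator, accuracy: float,
                    lapse: float) -> tuple[np.ndarray, np.ndarray]:
    """One 64-trial assessment block at a calibrated accuracy level."""
    beta = calibrate_sensitivity(accuracy, lapse)
    pmat = choice_probability_matrix(ConfusionKernel(beta=beta, lapse=lapse))
    targets = np.repeat(np.arange(1, RING_SIZE + 1), RING_SIZE)
    rng.shuffle(targets)
    cum = np.cumsum(pmat[targets - 1], axis=1)
    u = rng.random(targets.size)
    chosen = (u[:, None] < cum).argmax(axis=1) + 1
    return targets, chosen


def simulate_cohort(experiment: int = 1, configs=None, seed: int = 0,
                    lapse: float = DEFAULT_LAPSE) -> pd.DataFrame:
    """Simulate assessment trial logs for a full cohort.

    Each participant draws a baseline accuracy and pre->post / pre->retention
    changes from their group's truncated normals, each time point's accuracy
    is mapped to a kernel sensitivity, and a 64-trial block is emitted per
    time point.  Deterministic given ``seed``; per-participant substreams are
    derived from (seed, participant index, time-point index).
    """
    if configs is None:
        if experiment == 1:
            configs = EXPERIMENT1_GROUPS
        elif experiment == 2:
            configs = EXPERIMENT2_GROUPS
        else:
            raise ValueError("experiment must be 1 or 2")
    lo, hi = ACCURACY_BOUNDS
    rows = []
    pidx = 0
    for cfg in configs:
        for _ in range(cfg.n_participants):
            pidx += 1
            pid = f"E{experiment}P{pidx:02d}"
            draw_rng = np.random.default_rng([seed, pidx, 0])
            base = _draw_truncated(draw_rng, cfg.baseline_mean, cfg.baseline_sd, lo, hi)
            d_post = draw_rng.normal(cfg.d_post_mean, cfg.d_post_sd)
            d_ret = draw_rng.normal(cfg.d_retention_mean, cfg.d_retention_sd)
            acc = {"pre": base,
                   "post": float(np.clip(base + d_post, lo, hi)),
                   "retention": float(np.clip(base + d_ret, lo, hi))}
            for ti, tp in enumerate(TIME_POINTS):
                block_rng = np.random.default_rng([seed, pidx, 1 + ti])
                targets, chosen = _simulate_block(block_rng, acc[tp], lapse)
                rts = block_rng.lognormal(math.log(1100.0), 0.35, targets.size)
                for k in range(targets.size):
                    rows.append((pid, cfg.label, tp, k, targets[k],
                                 chosen[k], rts[k]))
    return pd.DataFrame(rows, columns=[
        "participant_id", "group", "time_point", "trial_index",
        "target_id", "chosen_id", "rt_ms"])


# ---------------------------------------------------------------------------
# Session schedules
# ---------------------------------------------------------------------------

def schedule_training_session(group: str = "graphomotor-nondominant",
                              seed: int = 0) -> pd.DataFrame:
    """Ordered trial list for one training day.

    The familiarization block (40 trials on out-of-set shapes, shape_id 0 in
    the training set's numbering but tagged with familiarization ids) carries
    16 catch trials, two per shape; the training phase has 200 trials, each
    of the 8 shapes 25 times, in random order.  Catch-trial width-change
    parameters are recorded as metadata columns.
    """
    rng = np.random.default_rng([seed, 11])
    fam = []
    for shape in range(1, RING_SIZE + 1):
        fam += [(shape, True)] * 2 + [(shape, False)] * 3
    rng.shuffle(fam)
    rows = [{"phase": "familiarization", "shape_id": s, "is_catch": c}
            for s, c in fam]
    train = np.repeat(np.arange(1, RING_SIZE + 1), TRAINING_REPS)
    rng.shuffle(train)
    rows += [{"phase": "training", "shape_id": int(s), "is_catch": False}
             for s in train]
    df = pd.DataFrame(rows)
    df.insert(0, "trial_index", np.arange(len(df)))
    df["group"] = group
    df["catch_width_mm"] = np.where(df["is_catch"], CATCH_WIDTH_MM, np.nan)
    df["catch_duration_ms"] = np.where(df["is_catch"], CATCH_DURATION_MS, np.nan)
    return df


# ---------------------------------------------------------------------------
# Trace generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceGenParams:
    """Hand- and session-dependent kinematic parameters of the generator.

    ``noise_sd`` is the SD (cm) of the smooth lateral deviation along the
    contour normal; ``speed`` the mean traversal speed (cm/s); the ripple is
    a sinusoidal speed modulation producing high-frequency spectral content.
    Per-session multipliers encode day-1 -> day-2 learning.
    """

    hand: str = "non-dominant"
    noise_sd: float = 0.20
    noise_corr_cm: float = 1.0
    speed: float = 2.5
    ripple_amp: float = 0.35
    ripple_freq: float = 4.0
    day2_noise_mult: float = 0.75
    day2_speed_mult: float = 1.15
    day2_ripple_mult: float = 0.85
    fs: float = 100.0

    def for_day(self, session_day: int) -> "TraceGenParams":
        if session_day == 1:
            return self
        return replace(self,
                       noise_sd=self.noise_sd * self.day2_noise_mult,
                       speed=self.speed * self.day2_speed_mult,
                       ripple_amp=self.ripple_amp * self.day2_ripple_mult)


#: Defaults anchored to the published hand contrasts: the dominant hand is
#: quicker, more accurate and smoother; across days it speeds up and smooths
#: further but does NOT improve in spatial accuracy, while the non-dominant
#: hand improves on all three.
DOMINANT_PARAMS = TraceGenParams(hand="dominant", noise_sd=0.09,
                                 speed=5.0, ripple_amp=0.15, ripple_freq=3.0,
                                 day2_noise_mult=1.0, day2_speed_mult=1.3,
                                 day2_ripple_mult=0.65)
NONDOMINANT_PARAMS = TraceGenParams(hand="non-dominant")


def _periodic_smooth_noise(rng: np.random.Generator, n: int, corr_len: float,
                           total_len: float, sd: float) -> np.ndarray:
    """Periodic correlated noise: white noise circularly convolved with a
    Gaussian kernel in arc length, rescaled to the requested SD."""
    white = rng.normal(size=n)
    ds = total_len / n
    half = n // 2
    lag = (np.arange(n) + half) % n - half
    kernel = np.exp(-0.5 * (lag * ds / corr_len) ** 2)
    smooth = np.fft.irfft(np.fft.rfft(white) * np.fft.rfft(kernel), n)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def simulate_trace(template: ContourShape, params: TraceGenParams,
                   seed: int = 0, session_day: int = 1,
                   trial_id: int = 0) -> Trace:
    """One noisy traversal of a template contour.

    Start point and direction are drawn at random; the pen follows the
    contour with smooth correlated lateral noise, at a mean speed modulated
    by the configured sinusoidal ripple; samples are emitted at ``params.fs``.
    Deterministic given ``seed``.
    """
    p = params.for_day(session_day)
    rng = np.random.default_rng([seed, trial_id, session_day])
    pts = template.open_points
    n = pts.shape[0]
    closed = template.points
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s_knots = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_knots[-1]

    start = rng.uniform(0.0, total)
    direction = rng.choice([-1.0, 1.0])
    phase = rng.uniform(0.0, 2.0 * np.pi)

    duration = total / p.speed
    nt = int(math.ceil(duration * p.fs)) + 1
    t = np.arange(nt) / p.fs
    amp = min(p.ripple_amp, 0.95)
    v = p.speed * (1.0 + amp * np.sin(2.0 * np.pi * p.ripple_freq * t + phase))
    s_along = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) / p.fs)])[:nt]
    # stop after exactly one full cycle
    keep = s_along <= total
    keep[0] = True
    t, s_along = t[keep], s_along[keep]

    pos_s = np.mod(start + direction * s_along, total)
    x = np.interp(pos_s, s_knots, closed[:, 0], period=total)
    y = np.interp(pos_s, s_knots, closed[:, 1], period=total)

    # outward unit normals at the template knots, interpolated in arc length
    tangents = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])
    centroid = template.centroid
    flip = np.sign(np.einsum("ij,ij->i", pts - centroid, normals))
    flip[flip == 0] = 1.0
    normals *= flip[:, None]

    noise = _periodic_smooth_noise(rng, n, p.noise_corr_cm, total, p.noise_sd)
    eta = np.interp(pos_s, s_knots[:-1], noise, period=total)
    nx = np.interp(pos_s, s_knots[:-1], normals[:, 0], period=total)
    ny = np.interp(pos_s, s_knots[:-1], normals[:, 1], period=total)

    return Trace(t_ms=t * 1000.0, x_cm=x + eta * nx, y_cm=y + eta * ny,
                 pen_down=np.ones(t.size, dtype=bool), trial_id=trial_id,
                 shape_id=template.shape_id, hand=p.hand,
                 session_day=session_day)


def simulate_hand_session_traces(shape_set, hand_params: TraceGenParams,
                                 n_per_shape: int = 3, seed: int = 0,
                                 session_day: int = 1) -> list[Trace]:
    """Traces for one hand x session across all 8 templates."""
    traces = []
    tid = 0
    for shape in shape_set.shapes:
        for _ in range(n_per_shape):
            tid += 1
            traces.append(simulate_trace(shape, hand_params,
                                         seed=seed, session_day=session_day,
                                         trial_id=tid))
    return traces
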