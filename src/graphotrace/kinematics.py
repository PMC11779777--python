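"""Scoring of digitizer pen traces against their template contour.

Three outcome measures per valid trial:

* **tracing duration** (s) — first stylus contact to trial completion;
* **tracing accuracy** (cm^2) — the area enclosed between the template and
  the produced trace, computed as the area of the symmetric difference of the
  two enclosed regions (robust to the trace crossing the template);
* **smoothness** — spectral arc length (SPARC) of the speed profile: the
  negative arc length of the normalised magnitude spectrum over an adaptive
  low-frequency band.  Values are <= 0; nearer zero = smoother movement.

Trial validity mirrors the acquisition rules: a trial is aborted if the pen
stays still for longer than 400 ms or the trace exceeds the 15 s limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from scipy.signal import butter, filtfilt
from shapely.geometry import Polygon

from .exceptions import InvalidTraceError, UndefinedSmoothnessError
from .shapes import ContourShape

#: Pen displacement below this (cm) counts as "still" for pause detection.
STILL_THRESHOLD_CM = 0.05
#: Abort rule: stillness longer than this aborts the trial.
PAUSE_LIMIT_MS = 400.0
#: Abort rule: per-shape tracing time limit.
TIME_LIMIT_S = 15.0


@dataclass
class Trace:
    """One tracing trial: timestamped stylus samples.

    ``t_ms`` must be strictly increasing; at least two samples must be
    pen-down.
    """

    t_ms: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    pen_down: np.ndarray
    trial_id: int = 0
    shape_id: int = 0
    hand: str = "non-dominant"
    session_day: int = 1
    is_catch: bool = False

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        self.pen_down = np.asarray(self.pen_down, dtype=bool)
        n = self.t_ms.size
        if not (self.x_cm.size == self.y_cm.size == self.pen_down.size == n):
            raise InvalidTraceError("sample arrays differ in length")
        if n >= 2 and not np.all(np.diff(self.t_ms) > 0):
            raise InvalidTraceError("timestamps must be strictly increasing")
        if int(self.pen_down.sum()) < 2:
            raise InvalidTraceError("need at least 2 pen-down samples")

    def pen_points(self) -> np.ndarray:
        m = self.pen_down
        return np.column_stack([self.x_cm[m], self.y_cm[m]])

    def pen_times_s(self) -> np.ndarray:
        return self.t_ms[self.pen_down] / 1000.0


@dataclass(frozen=True)
class SpeedProfile:
    """Tangential speed on a uniform time grid."""

    t: np.ndarray
    v: np.ndarray
    fs: float


@dataclass(frozen=True)
class TraceMetrics:
    """Bundled outcome measures of one trial."""

    duration: float
    area_error: float
    sparc: float
    valid: bool
    abort_reason: str  # none | pause | timeout


#: A trailing stop shorter than this is not trimmed from the duration.
MIN_STILL_MS = 200.0


def tracing_duration(trace: Trace, *, trim_trailing_still: bool = True,
                     still_threshold_cm: float = STILL_THRESHOLD_CM,
                     min_still_ms: float = MIN_STILL_MS) -> float:
    """Tracing time in seconds, first pen contact to trial completion.

    Trial completion is the last pen-down sample; with
    ``trim_trailing_still`` (default) a terminal movement stop — a trailing
    segment over which the pen path advances less than
    ``still_threshold_cm`` and that lasts longer than ``min_still_ms`` — is
    trimmed, so a stop before stylus lift does not inflate the duration.
    """
    t = trace.pen_times_s()
    if t.size < 2:
        raise InvalidTraceError("no pen-down interval")
    end = t[-1]
    if trim_trailing_still:
        pts = trace.pen_points()
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        remaining = s[-1] - s
        still = np.nonzero(remaining < still_threshold_cm)[0]
        start = t[still[0]] if still.size else end
        if (end - start) * 1000.0 > min_still_ms:
            end = start
    return float(end - t[0])


def check_validity(trace: Trace, *, pause_limit_ms: float = PAUSE_LIMIT_MS,
                   time_limit_s: float = TIME_LIMIT_S,
                   still_threshold_cm: float = STILL_THRESHOLD_CM) -> tuple[bool, str]:
    """Apply the acquisition abort rules; returns (valid, abort_reason).

    A pause is any window longer than ``pause_limit_ms`` over which the pen
    path advances less than ``still_threshold_cm``.
    """
    t_ms = trace.t_ms[trace.pen_down]
    pts = trace.pen_points()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # for each sample, first later sample beyond the pause limit; a pause is
    # a window longer than the limit with path advance below threshold
    j = np.searchsorted(t_ms, t_ms + pause_limit_ms, side="right")
    has_window = j < t_ms.size
    i_idx = np.nonzero(has_window)[0]
    if i_idx.size and np.any(s[j[i_idx]] - s[i_idx] < still_threshold_cm):
        return False, "pause"
    if (t_ms[-1] - t_ms[0]) / 1000.0 > time_limit_s:
        return False, "timeout"
    return True, "none"


def _as_region(points: np.ndarray):
    """Closed polygon region from a vertex path, repaired if self-intersecting."""
    poly = Polygon(points)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    return poly


def area_error(trace_or_points, template: ContourShape) -> float:
    """Area (cm^2) enclosed between template and trace.

    The trace is closed by joining its endpoint to its start point; both
    curves are treated as closed polygons and the area of their symmetric
    difference (union minus intersection of enclosed regions) is returned.
    Self-intersecting trace polygons are repaired by even-odd region
    construction.
    """
    if isinstance(trace_or_points, Trace):
        pts = trace_or_points.pen_points()
    else:
        pts = np.asarray(trace_or_points, dtype=float)
    if pts.shape[0] < 3:
        raise InvalidTraceError("need at least 3 pen-down samples for area")
    region_trace = _as_region(pts)
    region_template = _as_region(template.open_points)
    return float(region_trace.symmetric_difference(region_template).area)


def speed_profile(trace: Trace, fs: float = 100.0,
                  cutoff_hz: Optional[float] = 10.0) -> SpeedProfile:
    """Resample pen positions to a uniform grid and differentiate to speed.

    Positions are linearly interpolated at ``fs``, optionally zero-phase
    low-pass filtered (2nd-order Butterworth applied forward-backward), and
    differentiated with central differences.
    """
    t = trace.pen_times_s()
    pts = trace.pen_points()
    n = int(math.floor((t[-1] - t[0]) * fs)) + 1
    if n < 3:
        raise InvalidTraceError("trace shorter than 3 samples at fs")
    tg = t[0] + np.arange(n) / fs
    x = np.interp(tg, t, pts[:, 0])
    y = np.interp(tg, t, pts[:, 1])
    if cutoff_hz is not None and cutoff_hz < fs / 2.0:
        b, a = butter(2, cutoff_hz / (fs / 2.0))
        padlen = 3 * (max(len(a), len(b)) - 1)
        if n > padlen:
            x = filtfilt(b, a, x)
            y = filtfilt(b, a, y)
    vx = np.gradient(x, 1.0 / fs)
    vy = np.gradient(y, 1.0 / fs)
    return SpeedProfile(t=tg - tg[0], v=np.hypot(vx, vy), fs=fs)


def sparc(speed: SpeedProfile, fc: float = 10.0, amp_threshold: float = 0.05,
          pad_factor: int = 4) -> float:
    """Spectral arc length of a speed profile (dimensionless, <= 0).

    The magnitude spectrum of the speed signal is normalised by its value at
    zero frequency; an adaptive cutoff selects the band up to the last
    frequency <= ``fc`` at which the normalised magnitude still reaches
    ``amp_threshold``; the negative arc length of the normalised spectrum over
    that band (frequency axis normalised by the band width) is returned.
    """
    v = np.asarray(speed.v, dtype=float)
    if v.size < 8:
        raise InvalidTraceError("need at least 8 speed samples for SPARC")
    if np.allclose(v, 0.0):
        raise UndefinedSmoothnessError("all-zero speed profile")
    nfft = 2 ** int(math.ceil(math.log2(pad_factor * v.size)))
    mf = np.abs(np.fft.rfft(v, nfft))
    mf = mf / mf[0]
    freq = np.fft.rfftfreq(nfft, d=1.0 / speed.fs)
    within = freq <= fc
    f_sel, m_sel = freq[within], mf[within]
    above = np.nonzero(m_sel >= amp_threshold)[0]
    hi = max(int(above[-1]) + 1, 2) if above.size else 2
    f_band, m_band = f_sel[:hi], m_sel[:hi]
    span = f_band[-1] - f_band[0]
    return float(-np.sum(np.sqrt((np.diff(f_band) / span) ** 2
                                 + np.diff(m_band) ** 2)))


def score_trace(trace: Trace, template: ContourShape, *,
                fs: float = 100.0, cutoff_hz: Optional[float] = 10.0,
                fc: float = 10.0, amp_threshold: float = 0.05,
                pause_limit_ms: float = PAUSE_LIMIT_MS,
                time_limit_s: float = TIME_LIMIT_S) -> TraceMetrics:
    """Bundle duration, area error, SPARC and validity for one trial.

    Invalid (aborted) trials carry NaN metrics and are excluded from session
    means downstream.
    """
    valid, reason = check_validity(trace, pause_limit_ms=pause_limit_ms,
                                   time_limit_s=time_limit_s)
    if not valid:
        return TraceMetrics(float("nan"), float("nan"), float("nan"),
                            valid=False, abort_reason=reason)
    duration = tracing_duration(trace)
    area = area_error(trace, template)
    sp = speed_profile(trace, fs=fs, cutoff_hz=cutoff_hz)
    smooth = sparc(sp, fc=fc, amp_threshold=amp_threshold)
    return TraceMetrics(duration=duration, area_error=area, sparc=smooth,
                        valid=True, abort_reason="none")


def score_trace_table(traces: list[Trace], shape_set) -> pd.DataFrame:
    """Score a list of traces against their templates into a tidy frame."""
    rows = []
    for tr in traces:
        template = shape_set.shape(tr.shape_id)
        m = score_trace(tr, template)
        rows.append({"trial_id": tr.trial_id, "shape_id": tr.shape_id,
                     "hand": tr.hand, "session_day": tr.session_day,
                     "is_catch": tr.is_catch, "duration": m.duration,
                     "area_error": m.area_error, "sparc": m.sparc,
                     "valid": m.valid, "abort_reason": m.abort_reason})
    return pd.DataFrame(rows)


def session_means(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean duration / area error / SPARC per hand x session.

    Only valid non-catch trials enter the means.
    """
    usable = metrics[metrics["valid"] & ~metrics["is_catch"]]
    return (usable.groupby(["hand", "session_day"])
            [["duration", "area_error", "sparc"]].mean().reset_index())
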