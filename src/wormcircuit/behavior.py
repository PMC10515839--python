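"""Reversal and turning-angle metrics from worm centroid tracks.

A centroid track lacks an explicit body axis, so forward/backward motion is
classified against a heading estimate: the centroid velocity smoothed over
one undulation period, held consistent through backward excursions so that
a reversal does not flip the inferred body axis.  Turning angles follow the
crawling-assay convention: five sinusoidal undulation waves form one
movement step, the interior angle between successive step displacement
vectors is the turning angle, 180 deg means straight, below 180 deg is a
dorsal turn and above 180 deg is ventral.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (DegenerateStepError, DomainError, InsufficientTrackError,
                     InvalidConfigError, UndefinedTestError)

logger = logging.getLogger(__name__)

__all__ = [
    "WormTrack",
    "MovementStep",
    "ReversalRecord",
    "detect_reversals",
    "segment_movement_steps",
    "turning_angles",
    "welch_t_test",
    "track_metrics",
]


@dataclass
class WormTrack:
    """Time-stamped 2-D centroid path in micrometers.

    ``dorsal_side`` resolves which turning direction is dorsal: +1 if the
    dorsal side lies to the left of the heading (counterclockwise turns are
    dorsal), -1 if to the right.
    """

    timestamps: np.ndarray
    positions: np.ndarray      # (n, 2) micrometers
    dorsal_side: int
    frame_rate: float

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InvalidConfigError("positions must be (n, 2)")
        if self.timestamps.size != self.positions.shape[0]:
            raise InvalidConfigError("timestamps and positions disagree")
        if self.timestamps.size >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise InvalidConfigError("timestamps must be strictly increasing")
        if not np.isfinite(self.positions).all():
            raise InvalidConfigError("positions must be finite")
        if self.dorsal_side not in (-1, 1):
            raise InvalidConfigError("dorsal_side must be +1 or -1")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class MovementStep:
    """Five undulation periods of travel, summarized by one displacement."""

    start_index: int
    end_index: int
    displacement: np.ndarray      # (2,) micrometers
    n_undulation_periods: int = 5


@dataclass
class ReversalRecord:
    """Detected forward-to-backward transitions within an assay window."""

    onsets: np.ndarray            # seconds
    durations: np.ndarray         # seconds
    window_s: float
    count_in_window: int
    no_motion: bool = False


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge shrinkage, column-wise."""
    width = max(int(width), 1)
    if x.ndim == 1:
        x = x[:, None]
        squeeze = True
    else:
        squeeze = False
    n = x.shape[0]
    kernel = np.ones(width)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    out = np.column_stack([
        np.convolve(x[:, j], kernel, mode="same") / counts
        for j in range(x.shape[1])])
    return out[:, 0] if squeeze else out


def detect_reversals(track: WormTrack, window_s: float = 120.0,
                     undulation_period_s: float = 2.0,
                     min_duration_s: float = 0.5,
                     speed_threshold_um_s: float = 5.0,
                     axis_window_periods: float = 5.0) -> ReversalRecord:
    """Count forward-to-backward transitions in the assay window.

    Velocity is projected on a slowly varying body-axis estimate: the
    centroid velocity averaged over one movement step (five undulation
    periods by default).  Averaging over that long a window keeps the axis
    pointing along the overall direction of travel through reversals lasting
    up to about half the window, so backward episodes show up as a negative
    projection rather than dragging the axis around with them.  A
    forward-to-backward transition that persists at least ``min_duration_s``
    counts as one reversal; its duration runs to the backward-to-forward
    transition.
    """
    t = track.timestamps
    if track.duration + 1.0 / track.frame_rate < window_s:
        raise InvalidConfigError(
            f"track ({track.duration:.1f} s) shorter than window {window_s} s")
    dt = 1.0 / track.frame_rate
    vel = np.gradient(track.positions, t, axis=0)
    width = int(round(undulation_period_s * track.frame_rate))
    smooth_vel = _moving_average(vel, width)
    # gate on the smoothed speed so localization jitter is not "motion"
    smooth_speed = np.linalg.norm(smooth_vel, axis=1)
    if np.mean(smooth_speed > speed_threshold_um_s) < 0.5:
        warnings.warn("track speed below threshold for most samples; "
                      "reporting zero reversals", stacklevel=2)
        return ReversalRecord(np.empty(0), np.empty(0), window_s, 0,
                              no_motion=True)

    axis_width = int(round(axis_window_periods * undulation_period_s
                           * track.frame_rate))
    axis = _moving_average(vel, axis_width)
    norms = np.linalg.norm(axis, axis=1)
    norms[norms < 1e-12] = 1.0
    axis = axis / norms[:, None]

    signed_speed = np.einsum("ij,ij->i", vel, axis)
    backward = signed_speed < 0

    min_run = max(int(round(min_duration_s * track.frame_rate)), 1)
    onsets, durations = [], []
    i = 0
    n = len(t)
    while i < n:
        if not backward[i]:
            i += 1
            continue
        j = i
        while j < n and backward[j]:
            j += 1
        if (j - i) >= min_run and i > 0:   # ignore a track starting backward
            onsets.append(t[i])
            durations.append((j - i) * dt)
        i = j
    onsets = np.asarray(onsets)
    durations = np.asarray(durations)
    count = int(np.sum(onsets <= t[0] + window_s)) if onsets.size else 0
    return ReversalRecord(onsets=onsets, durations=durations,
                          window_s=window_s, count_in_window=count)


def segment_movement_steps(track: WormTrack,
                           undulation_period_s: float = 2.0,
                           waves_per_step: int = 5) -> list[MovementStep]:
    """Group every ``waves_per_step`` undulation periods into one step.

    The lateral deviation of the centroid from its smoothed path crosses
    zero twice per undulation wave; successive same-sign crossings bound one
    period.  The trailing partial step is discarded.
    """
    width = int(round(undulation_period_s * track.frame_rate))
    smooth = _moving_average(track.positions, width)
    tangent = np.gradient(smooth, track.timestamps, axis=0)
    norms = np.linalg.norm(tangent, axis=1)
    norms[norms < 1e-12] = 1.0
    tangent = tangent / norms[:, None]
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    lateral = np.einsum("ij,ij->i", track.positions - smooth, normal)

    sign = np.sign(lateral)
    crossings = np.nonzero(np.diff(sign > 0))[0]
    if crossings.size < 10:
        raise InsufficientTrackError(
            f"only {crossings.size} lateral zero crossings; undulation not "
            "detectable")
    # every second crossing starts a new period (same-sign crossings)
    period_starts = crossings[::2]
    n_periods = period_starts.size - 1
    n_steps = n_periods // waves_per_step
    if n_steps < 2:
        raise InsufficientTrackError(
            f"only {n_steps} complete movement steps; need at least 2")
    steps = []
    for s in range(n_steps):
        i0 = int(period_starts[waves_per_step * s])
        i1 = int(period_starts[waves_per_step * (s + 1)])
        disp = smooth[i1] - smooth[i0]
        steps.append(MovementStep(start_index=i0, end_index=i1,
                                  displacement=disp,
                                  n_undulation_periods=waves_per_step))
    return steps


def turning_angles(steps: list[MovementStep], dorsal_side: int) -> np.ndarray:
    """Interior angles between successive movement steps, in degrees.

    180 deg is straight; angles below 180 deg are dorsal turns and above
    180 deg ventral, regardless of which physical side is dorsal
    (``dorsal_side`` +1 means dorsal lies to the left of the heading).
    Angles lie in (0, 360).
    """
    if dorsal_side not in (-1, 1):
        raise DomainError("dorsal_side must be +1 or -1")
    if len(steps) < 2:
        raise InsufficientTrackError("need at least 2 steps for an angle")
    angles = []
    for prev, cur in zip(steps[:-1], steps[1:]):
        u, v = prev.displacement, cur.displacement
        if np.linalg.norm(u) < 1e-12 or np.linalg.norm(v) < 1e-12:
            raise DegenerateStepError("zero-length step displacement")
        cross = u[0] * v[1] - u[1] * v[0]
        dot = float(np.dot(u, v))
        signed = np.degrees(np.arctan2(cross, dot))   # CCW positive
        angle = 180.0 - dorsal_side * signed
        angles.append(angle % 360.0)
    return np.asarray(angles)


def welch_t_test(sample_a: np.ndarray, sample_b: np.ndarray):
    """Unpaired two-tailed Welch's t test (unequal variances).

    Returns (t, Satterthwaite df, two-tailed p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedTestError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise UndefinedTestError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def track_metrics(track: WormTrack, window_s: float = 120.0,
                  undulation_period_s: float = 2.0,
                  waves_per_step: int = 5) -> dict:
    """Per-track summary: reversal counts/durations and turning angles."""
    rec = detect_reversals(track, window_s, undulation_period_s)
    try:
        steps = segment_movement_steps(track, undulation_period_s,
                                       waves_per_step)
        angles = turning_angles(steps, track.dorsal_side)
        mean_angle = float(angles.mean())
        n_steps = len(steps)
    except InsufficientTrackError:
        mean_angle, n_steps = float("nan"), 0
    return {
        "n_reversals": rec.count_in_window,
        "mean_duration_s": float(rec.durations.mean()) if rec.durations.size
        else float("nan"),
        "mean_turning_angle_deg": mean_angle,
        "n_steps": n_steps,
    }
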