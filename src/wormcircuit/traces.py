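"""Calcium-trace extraction and correction from two-channel movies.

The per-voxel signal in each channel is modeled as three multiplying terms
plus a time-independent noise term: the fluorophore signal itself, a
double-exponential photobleaching decay, and a multiplicative artifact
shared between the red and green channels.  The red fluorophore is
calcium-insensitive, so its signal term is constant; fitting a double
exponential to the red trace therefore estimates the product of the first
two terms, and dividing the noise-subtracted red trace by that fit isolates
the shared artifact.  The artifact is then divided out of the green
channel, a second bleach fit (restricted to event-free timepoints) removes
green photobleaching, and the result is rescaled to a unit non-event median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (DegenerateFitError, DomainError, FitConvergenceError,
                     InsufficientBaselineError, InvalidConfigError)
from .events import EventTrain
from .synthetic import double_exponential

logger = logging.getLogger(__name__)

__all__ = [
    "TwoChannelMovie",
    "RawTrace",
    "BleachFit",
    "CorrectedTrace",
    "extract_raw_trace",
    "estimate_noise",
    "fit_double_exponential",
    "compute_artifact",
    "correct_trace",
    "extract_corrected_traces",
    "DEFAULT_REGION",
    "DEFAULT_TOP_K",
]

DEFAULT_REGION = (11, 11, 5)   # (x, y, z) voxels around the annotated center
DEFAULT_TOP_K = 40             # brightest voxels averaged per volume


@dataclass
class TwoChannelMovie:
    """Time-ordered voxel volumes for the red and green channels.

    Arrays are indexed (t, z, y, x); both channels must share a shape.
    """

    red_volumes: np.ndarray
    green_volumes: np.ndarray
    frame_rate: float
    voxel_size: tuple[float, float, float] = (0.4, 0.4, 1.2)

    def __post_init__(self):
        self.red_volumes = np.asarray(self.red_volumes)
        self.green_volumes = np.asarray(self.green_volumes)
        if self.red_volumes.shape != self.green_volumes.shape:
            raise InvalidConfigError(
                f"channel shapes differ: red {self.red_volumes.shape} vs "
                f"green {self.green_volumes.shape}")
        if self.red_volumes.ndim != 4:
            raise InvalidConfigError("volumes must be 4-D (t, z, y, x)")
        if self.frame_rate <= 0:
            raise InvalidConfigError("frame_rate must be positive")

    def channel(self, name: str) -> np.ndarray:
        if name == "red":
            return self.red_volumes
        if name == "green":
            return self.green_volumes
        raise InvalidConfigError(f"unknown channel {name!r}")

    @property
    def n_volumes(self) -> int:
        return self.red_volumes.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(self.n_volumes) / self.frame_rate


@dataclass
class RawTrace:
    """Sorted-voxel intensity trace for one neuron in one channel."""

    neuron_id: str
    channel: str
    values: np.ndarray            # one value per volume; NaN where missing
    region_shape: tuple[int, int, int] = DEFAULT_REGION
    top_k: int = DEFAULT_TOP_K
    n_interpolated: int = 0
    n_missing: int = 0


@dataclass
class BleachFit:
    """Double-exponential fit a1*exp(-l1 t) + a2*exp(-l2 t)."""

    a1: float
    lam1: float
    a2: float
    lam2: float
    fitted_curve: np.ndarray
    residual_norm: float
    offset: float = 0.0

    @property
    def rates(self) -> tuple[float, float]:
        return (self.lam1, self.lam2)


@dataclass
class CorrectedTrace:
    """Artifact- and bleach-corrected, normalized green trace."""

    neuron_id: str
    values: np.ndarray
    noise_estimate: float
    artifact_series: np.ndarray
    bleach_fit: BleachFit | None = None


def _interpolate_short_gaps(values: np.ndarray, max_gap: int = 3):
    """Linearly fill NaN runs of <= max_gap interior samples.

    Small annotation-tracking gaps should not break event alignment; longer
    runs are left missing.  Returns (filled values, n_interpolated).
    """
    values = values.astype(float).copy()
    isnan = np.isnan(values)
    if not isnan.any():
        return values, 0
    n = values.size
    filled = 0
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        run = j - i
        if run <= max_gap and i > 0 and j < n:
            left, right = values[i - 1], values[j]
            values[i:j] = left + (np.arange(1, run + 1) / (run + 1)) * (right - left)
            filled += run
        i = j
    return values, filled


def extract_raw_trace(movie: TwoChannelMovie, annotations: pd.DataFrame,
                      neuron_id: str, channel: str,
                      region: tuple[int, int, int] = DEFAULT_REGION,
                      top_k: int = DEFAULT_TOP_K,
                      max_interp_gap: int = 3) -> RawTrace:
    """Mean of the brightest ``top_k`` voxels around the annotated neuron.

    Per volume, voxels in an ``region``-shaped box centered on the
    annotation (clipped to the volume bounds) are sorted by intensity in
    descending order and the mean of the first ``top_k`` is taken; if the
    clipped region holds fewer voxels, all of them are averaged.  Volumes
    with no annotation yield NaN; interior gaps of up to ``max_interp_gap``
    volumes are filled by linear interpolation.
    """
    data = movie.channel(channel)
    n_t, n_z, n_y, n_x = data.shape
    rx, ry, rz = region
    hx, hy, hz = rx // 2, ry // 2, rz // 2

    ann = annotations[annotations["neuron_id"] == neuron_id]
    ann = ann.set_index("t_index")
    values = np.full(n_t, np.nan)
    n_missing = 0
    for ti in range(n_t):
        if ti not in ann.index:
            n_missing += 1
            logger.debug("neuron %s: no annotation for volume %d", neuron_id, ti)
            continue
        row = ann.loc[ti]
        x, y, z = int(row["x_vox"]), int(row["y_vox"]), int(row["z_vox"])
        if not (0 <= x < n_x and 0 <= y < n_y and 0 <= z < n_z):
            raise InvalidConfigError(
                f"annotation for {neuron_id} at volume {ti} outside bounds")
        box = data[ti,
                   max(0, z - hz):min(n_z, z + hz + 1),
                   max(0, y - hy):min(n_y, y + hy + 1),
                   max(0, x - hx):min(n_x, x + hx + 1)].ravel()
        k = min(top_k, box.size)
        # partition is equivalent to a full descending sort for a top-k mean
        top = np.partition(box, box.size - k)[box.size - k:]
        values[ti] = top.mean()
    if n_missing:
        logger.warning("neuron %s: %d volumes lack annotations", neuron_id,
                       n_missing)
    values, n_interp = _interpolate_short_gaps(values, max_interp_gap)
    return RawTrace(neuron_id=neuron_id, channel=channel, values=values,
                    region_shape=region, top_k=top_k,
                    n_interpolated=n_interp, n_missing=n_missing)


def estimate_noise(movie: TwoChannelMovie, channel: str,
                   quantile: float = 0.8) -> float:
    """Time-independent additive noise level of a channel.

    The 0.8 quantile over all voxels is taken per volume (linear
    interpolation convention) and the per-volume values are aggregated by
    their median, which is robust to bleaching trends across the recording.
    """
    data = movie.channel(channel)
    if data.shape[0] == 0:
        raise InvalidConfigError("movie has no volumes")
    if not 0 < quantile < 1:
        raise DomainError("quantile must be in (0, 1)")
    per_volume = np.quantile(data.reshape(data.shape[0], -1), quantile, axis=1)
    return float(np.median(per_volume))


def _loglinear_init(t: np.ndarray, v: np.ndarray):
    """Starting point from log-linear fits to the first and last thirds."""
    n = t.size
    third = max(n // 3, 2)
    tail_t, tail_v = t[-third:], v[-third:]
    head_t, head_v = t[:third], v[:third]
    eps = max(v.max(), 1.0) * 1e-12

    span = max(t[-1] - t[0], 1.0)
    slope2, icept2 = np.polyfit(tail_t, np.log(np.maximum(tail_v, eps)), 1)
    lam2 = float(np.clip(-slope2, 0.0, 10.0))
    a2 = float(np.clip(np.exp(icept2), eps, 2.0 * v.max()))
    resid = head_v - a2 * np.exp(-lam2 * head_t)
    pos = resid > 0.01 * v.max()
    if pos.sum() >= 2:
        slope1, icept1 = np.polyfit(head_t[pos], np.log(resid[pos]), 1)
        lam1 = float(np.clip(-slope1, 1.0 / span, 10.0))
        a1 = float(np.clip(np.exp(icept1), eps, 2.0 * v.max()))
    else:
        lam1 = 10.0 / span
        a1 = max(v[0] - a2, 0.1 * a2)
    return np.array([max(a1, eps), lam1, max(a2, eps), lam2])


def fit_double_exponential(times: np.ndarray, values: np.ndarray,
                           include_mask: np.ndarray | None = None,
                           max_nfev: int = 10_000) -> BleachFit:
    """Least-squares fit of a1*exp(-l1 t) + a2*exp(-l2 t).

    Only points selected by ``include_mask`` (and finite) enter the fit;
    the fitted curve is evaluated at all input times.  Rates are constrained
    non-negative and components are ordered so lam1 >= lam2 on output.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = np.ones(times.size, dtype=bool) if include_mask is None \
        else np.asarray(include_mask, dtype=bool)
    mask = mask & np.isfinite(values)
    t_fit, v_fit = times[mask], values[mask]
    if t_fit.size < 5:
        raise InvalidConfigError("need at least 5 included points to fit")
    if np.any(v_fit <= 0):
        raise InvalidConfigError("included values must be positive")

    x0 = _loglinear_init(t_fit, v_fit)

    def residuals(params):
        a1, lam1, a2, lam2 = params
        return double_exponential(t_fit, a1, lam1, a2, lam2) - v_fit

    scale = float(v_fit.mean())
    bounds = ([0.0, 0.0, 0.0, 0.0], [np.inf] * 4)
    span = max(t_fit[-1] - t_fit[0], 1.0)
    generic = np.array([0.5 * v_fit[0], 5.0 / span, 0.5 * v_fit[0],
                        0.5 / span])
    result = None
    for start in (x0, generic):
        candidate = least_squares(residuals, start, bounds=bounds,
                                  max_nfev=max_nfev,
                                  x_scale=[scale, 0.01, scale, 0.01])
        if result is None or candidate.cost < result.cost:
            result = candidate
    if not result.success:
        raise FitConvergenceError(
            f"double-exponential fit did not converge: {result.message}",
            best_params=tuple(result.x),
            diagnostics={"cost": float(result.cost), "nfev": result.nfev})
    a1, lam1, a2, lam2 = result.x
    if lam1 < lam2:   # report the faster component first
        a1, lam1, a2, lam2 = a2, lam2, a1, lam1
    curve = double_exponential(times, a1, lam1, a2, lam2)
    return BleachFit(a1=float(a1), lam1=float(lam1), a2=float(a2),
                     lam2=float(lam2), fitted_curve=curve,
                     residual_norm=float(np.linalg.norm(result.fun)))


def compute_artifact(red_raw: RawTrace, red_fit: BleachFit,
                     red_noise: float, divisor_tol: float = 1e-9,
                     ) -> np.ndarray:
    """Shared multiplicative artifact from the calcium-insensitive channel.

    artifact(t) = (red_raw(t) - red_noise) / red_fit(t), renormalized to
    mean 1 over the finite samples.
    """
    curve = red_fit.fitted_curve
    bad = np.nonzero(curve <= divisor_tol)[0]
    if bad.size:
        raise DegenerateFitError(
            f"fitted red curve not positive at time index {int(bad[0])}",
            time_index=int(bad[0]))
    artifact = (red_raw.values - red_noise) / curve
    finite = np.isfinite(artifact)
    mean = artifact[finite].mean()
    if mean <= 0:
        raise DegenerateFitError("artifact series has non-positive mean")
    return artifact / mean


def correct_trace(green_raw: RawTrace, artifact: np.ndarray,
                  green_noise: float, events: EventTrain, frame_rate: float,
                  event_pad_pre_s: float = 1.0,
                  event_pad_post_s: float = 3.0) -> CorrectedTrace:
    """Artifact removal, bleach correction and normalization of the green trace.

    g1(t) = (green(t) - noise) / artifact(t); a double exponential is fitted
    to g1 using only timepoints outside padded event windows
    [onset - 1 s, onset + duration + 3 s] (excluding the calcium rise and
    decay tails); the output g1 / fit is rescaled so that its non-event
    median equals 1.
    """
    values = green_raw.values
    times = np.arange(values.size) / frame_rate
    g1 = (values - green_noise) / artifact
    outside = ~events.mask_within_events(times, event_pad_pre_s,
                                         event_pad_post_s)
    usable = outside & np.isfinite(g1) & (g1 > 0)
    if not usable.any():
        raise InsufficientBaselineError(
            "all timepoints fall within event windows; cannot fit bleaching")
    fit = fit_double_exponential(times, g1, include_mask=usable)
    corrected = g1 / fit.fitted_curve
    baseline = np.nanmedian(corrected[outside])
    if not np.isfinite(baseline) or baseline <= 0:
        raise InsufficientBaselineError("non-event median is not positive")
    corrected = corrected / baseline
    return CorrectedTrace(neuron_id=green_raw.neuron_id, values=corrected,
                          noise_estimate=green_noise,
                          artifact_series=artifact, bleach_fit=fit)


def extract_corrected_traces(movie: TwoChannelMovie,
                             annotations: pd.DataFrame, events: EventTrain,
                             region: tuple[int, int, int] = DEFAULT_REGION,
                             top_k: int = DEFAULT_TOP_K,
                             noise_quantile: float = 0.8) -> dict:
    """Full correction pipeline for every annotated neuron.

    Returns a dict with per-neuron raw red/green traces, the per-neuron
    artifact series, corrected traces, and the channel noise estimates.
    """
    red_noise = estimate_noise(movie, "red", noise_quantile)
    green_noise = estimate_noise(movie, "green", noise_quantile)
    times = movie.times()
    out = {"red_noise": red_noise, "green_noise": green_noise,
           "neurons": {}}
    for neuron_id in sorted(annotations["neuron_id"].unique()):
        red_raw = extract_raw_trace(movie, annotations, neuron_id, "red",
                                    region, top_k)
        green_raw = extract_raw_trace(movie, annotations, neuron_id, "green",
                                      region, top_k)
        red_fit = fit_double_exponential(times, red_raw.values - red_noise)
        artifact = compute_artifact(red_raw, red_fit, red_noise)
        corrected = correct_trace(green_raw, artifact, green_noise, events,
                                  movie.frame_rate)
        out["neurons"][neuron_id] = {
            "raw_red": red_raw, "raw_green": green_raw,
            "red_fit": red_fit, "artifact": artifact,
            "corrected": corrected,
        }
    return out
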