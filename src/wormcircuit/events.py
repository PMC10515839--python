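"""Event trains and reversal-triggered analysis of calcium traces.

Reversal onsets define time zero for every analysis here: traces are cropped
into windows locked to each onset, expressed as a change ratio relative to a
pre-event baseline, and averaged across events (an event-triggered average).
A per-event normalized variant supports "spaghetti" overlays, and pairwise
Pearson correlations summarize how similar two neurons' activity is within
an animal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateBaselineError, DomainError, InvalidConfigError,
                     UndefinedCorrelationError)

logger = logging.getLogger(__name__)

__all__ = [
    "EventTrain",
    "AlignedWindowSet",
    "EventTriggeredAverage",
    "CorrelationSummary",
    "align_to_events",
    "event_triggered_average",
    "normalize_spaghetti",
    "pairwise_correlation",
    "compare_pair_classes",
]


@dataclass(frozen=True)
class EventTrain:
    """Reversal onsets and durations on a recording timeline (seconds)."""

    onsets: np.ndarray
    durations: np.ndarray
    recording_length: float

    def __post_init__(self):
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=float))
        object.__setattr__(self, "durations",
                           np.asarray(self.durations, dtype=float))
        if self.onsets.shape != self.durations.shape or self.onsets.ndim != 1:
            raise InvalidConfigError("onsets and durations must be equal-length "
                                     "1-D arrays")
        if self.recording_length <= 0:
            raise InvalidConfigError("recording_length must be positive")
        if self.onsets.size:
            if np.any(np.diff(self.onsets) <= 0):
                raise InvalidConfigError("onsets must be strictly increasing")
            if np.any(self.durations <= 0):
                raise InvalidConfigError("durations must be positive")
            if np.any(self.onsets < 0):
                raise InvalidConfigError("onsets must be non-negative")
            if np.any(self.onsets + self.durations > self.recording_length + 1e-9):
                raise InvalidConfigError("events must end within the recording")

    def __len__(self) -> int:
        return self.onsets.size

    def intervals(self, pad_pre: float = 0.0, pad_post: float = 0.0):
        """(start, stop) windows around each event, optionally padded."""
        return [(o - pad_pre, o + d + pad_post)
                for o, d in zip(self.onsets, self.durations)]

    def mask_within_events(self, times: np.ndarray, pad_pre: float = 0.0,
                           pad_post: float = 0.0) -> np.ndarray:
        """Boolean mask of timepoints inside any (padded) event window."""
        times = np.asarray(times, dtype=float)
        mask = np.zeros(times.shape, dtype=bool)
        for start, stop in self.intervals(pad_pre, pad_post):
            mask |= (times >= start) & (times <= stop)
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset_s": self.onsets, "duration_s": self.durations})


@dataclass
class AlignedWindowSet:
    """Per-event trace segments on a common relative time axis."""

    segments: np.ndarray          # (n_events, n_samples)
    rel_time: np.ndarray          # seconds relative to onset
    event_indices: np.ndarray     # indices into the source EventTrain
    n_dropped: int                # events whose window fell out of bounds
    baseline_interval: tuple[float, float] = (-3.0, 0.0)

    @property
    def n_events(self) -> int:
        return self.segments.shape[0]

    def is_empty(self) -> bool:
        return self.n_events == 0


@dataclass
class EventTriggeredAverage:
    """Mean change ratio and SEM per timepoint relative to event onset."""

    rel_time: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int


@dataclass
class CorrelationSummary:
    """Per-animal pairwise Pearson coefficients grouped into pair classes."""

    records: pd.DataFrame         # animal, pair_class, neuron_a, neuron_b, r
    class_means: pd.Series        # mean r per class across animals
    per_animal_class_means: pd.DataFrame
    n_excluded: int


def align_to_events(values: np.ndarray, frame_rate: float, events: EventTrain,
                    pre_s: float = 3.0, post_s: float = 3.0,
                    baseline_interval: tuple[float, float] = (-3.0, 0.0),
                    ) -> AlignedWindowSet:
    """Crop one window per event, locked to its onset.

    Onsets are snapped to the nearest sample (at 4 Hz sampling,
    sub-sample interpolation is unwarranted).  Events whose window would
    extend past either end of the recording are dropped and counted.
    """
    if pre_s <= 0 or post_s <= 0:
        raise DomainError("pre_s and post_s must be positive")
    values = np.asarray(values, dtype=float)
    n = values.size
    n_pre = int(round(pre_s * frame_rate))
    n_post = int(round(post_s * frame_rate))
    rel_time = np.arange(-n_pre, n_post + 1) / frame_rate

    segments, kept = [], []
    n_dropped = 0
    for i, onset in enumerate(events.onsets):
        center = int(round(onset * frame_rate))
        lo, hi = center - n_pre, center + n_post
        if lo < 0 or hi >= n:
            n_dropped += 1
            continue
        segments.append(values[lo:hi + 1])
        kept.append(i)
    if n_dropped:
        logger.info("align_to_events: dropped %d/%d out-of-bounds events",
                    n_dropped, len(events))
    if not segments:
        warnings.warn("no events retained after boundary filtering",
                      stacklevel=2)
        seg = np.empty((0, rel_time.size))
    else:
        seg = np.stack(segments)
    return AlignedWindowSet(segments=seg, rel_time=rel_time,
                            event_indices=np.asarray(kept, dtype=int),
                            n_dropped=n_dropped,
                            baseline_interval=baseline_interval)


def event_triggered_average(windows: AlignedWindowSet) -> EventTriggeredAverage:
    """Average change ratio across events.

    Per event, the baseline F0 is the mean over the baseline interval
    (default [-3 s, 0 s]); the change ratio is (F(t) - F0) / F0.  The mean
    and its standard error are taken across events per relative timepoint.
    """
    if windows.is_empty():
        raise DomainError("cannot average an empty window set")
    lo, hi = windows.baseline_interval
    base_mask = (windows.rel_time >= lo) & (windows.rel_time <= hi)
    if not base_mask.any():
        raise DomainError("baseline interval lies outside the window")
    f0 = windows.segments[:, base_mask].mean(axis=1)
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        raise DegenerateBaselineError(
            f"non-positive baseline F0 for event index "
            f"{int(windows.event_indices[bad[0]])}",
            event_index=int(windows.event_indices[bad[0]]))
    ratio = (windows.segments - f0[:, None]) / f0[:, None]
    mean = ratio.mean(axis=0)
    n = windows.n_events
    sem = (ratio.std(axis=0, ddof=1) / np.sqrt(n)) if n >= 2 \
        else np.zeros_like(mean)
    return EventTriggeredAverage(rel_time=windows.rel_time, mean=mean,
                                 sem=sem, n_events=n)


def normalize_spaghetti(values: np.ndarray, frame_rate: float,
                        events: EventTrain, pre_s: float = 3.0,
                        post_s: float = 7.0) -> AlignedWindowSet:
    """Per-event normalized windows for overlay ("spaghetti") plots.

    Crops a window from ``pre_s`` before to ``post_s`` after each onset and
    divides each segment by its own baseline F0, the mean of the first
    ``pre_s`` seconds of the segment.
    """
    windows = align_to_events(values, frame_rate, events, pre_s=pre_s,
                              post_s=post_s, baseline_interval=(-pre_s, 0.0))
    if windows.is_empty():
        return windows
    base_mask = windows.rel_time < 0
    f0 = windows.segments[:, base_mask].mean(axis=1)
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        raise DegenerateBaselineError(
            f"non-positive baseline F0 for event index "
            f"{int(windows.event_indices[bad[0]])}",
            event_index=int(windows.event_indices[bad[0]]))
    windows.segments = windows.segments / f0[:, None]
    return windows


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise UndefinedCorrelationError("fewer than 3 overlapping timepoints")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance trace")
    return float(stats.pearsonr(x, y).statistic)


def pairwise_correlation(traces_by_animal: Mapping[str, Mapping[str, np.ndarray]],
                         pair_classes: Mapping[str, Sequence[tuple[str, str]]],
                         ) -> CorrelationSummary:
    """Pearson correlation per neuron pair per animal, grouped into classes.

    ``pair_classes`` maps a class name (e.g. ``"left-right"`` or
    ``"normal-undead"``) to the neuron-label pairs belonging to it.  Pairs
    missing from an animal, or undefined (zero variance / too little
    overlap), are excluded and counted.  Correlations use full overlapping
    traces.  Class means are taken across animals (each animal first
    averaged over its pairs in the class).
    """
    rows = []
    n_excluded = 0
    for animal, traces in traces_by_animal.items():
        for cls, pairs in pair_classes.items():
            for a, b in pairs:
                if a not in traces or b not in traces:
                    continue
                try:
                    r = _pearson(np.asarray(traces[a], float),
                                 np.asarray(traces[b], float))
                except UndefinedCorrelationError as exc:
                    logger.warning("excluding pair (%s, %s) in animal %s: %s",
                                   a, b, animal, exc)
                    n_excluded += 1
                    continue
                rows.append({"animal": animal, "pair_class": cls,
                             "neuron_a": a, "neuron_b": b, "r": r})
    records = pd.DataFrame(rows, columns=["animal", "pair_class", "neuron_a",
                                          "neuron_b", "r"])
    if records.empty:
        per_animal = pd.DataFrame(columns=["animal", "pair_class", "r"])
        class_means = pd.Series(dtype=float)
    else:
        per_animal = (records.groupby(["animal", "pair_class"], as_index=False)
                      ["r"].mean())
        class_means = per_animal.groupby("pair_class")["r"].mean()
    return CorrelationSummary(records=records, class_means=class_means,
                              per_animal_class_means=per_animal,
                              n_excluded=n_excluded)


def compare_pair_classes(summary: CorrelationSummary, class_a: str,
                         class_b: str):
    """Welch's t test on per-animal class-mean coefficients."""
    from .behavior import welch_t_test

    pa = summary.per_animal_class_means
    xa = pa.loc[pa.pair_class == class_a, "r"].to_numpy()
    xb = pa.loc[pa.pair_class == class_b, "r"].to_numpy()
    return welch_t_test(xa, xb)
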