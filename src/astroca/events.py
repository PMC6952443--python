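"""Per-ROI Ca²⁺ event statistics and peri-stimulus averaging.

From thresholded activity vectors this module derives the imaging
metrics of interest: active time (% of time the Ca²⁺ signal is
elevated), event frequency (events · min⁻¹) and mean event duration per
epoch (baseline / stimulus / post), a responder classification
comparing stimulus against baseline epochs, and peri-stimulus averages
(mean ± SEM across traces) aligned to stimulus onset or offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class EventInterval:
    """Half-open frame interval [start, end) of one event."""

    start: int
    end: int
    duration: float   # seconds

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")


@dataclass
class EventStats:
    """Summary of one ROI's events inside one epoch."""

    active_time: float            # % of epoch frames active
    frequency: float              # events/min (onsets inside the epoch)
    mean_duration: float | None   # s; None when no events
    n_events: int
    epoch_minutes: float = 0.0
    epoch: str = ""


@dataclass
class PeristimulusAverage:
    """Mean ± SEM of traces aligned to a stimulus onset or offset."""

    time_axis: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    alignment: str = "onset"


def intervals_from_mask(activity: np.ndarray, frame_interval: float,
                        min_duration: int = 2) -> list[EventInterval]:
    """Maximal runs of True, discarding runs shorter than ``min_duration``."""
    activity = np.asarray(activity, dtype=bool)
    if activity.size == 0:
        return []
    padded = np.concatenate([[False], activity, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [EventInterval(int(s), int(e), (e - s) * frame_interval)
            for s, e in zip(starts, ends) if e - s >= min_duration]


def active_time(intervals: list[EventInterval], n_frames: int) -> float:
    """Percent of frames covered by (disjoint) event intervals."""
    if n_frames <= 0:
        raise ValueError("n_frames must be > 0")
    covered = sum(iv.end - iv.start for iv in intervals)
    return 100.0 * covered / n_frames


def event_stats(intervals: list[EventInterval],
                epoch: tuple[int, int], frame_interval: float,
                label: str = "") -> EventStats:
    """Event statistics restricted to an epoch [start, end) of frames.

    Frequency counts events whose *onset* lies inside the epoch, per
    minute of epoch duration; mean duration is over those events;
    active time counts epoch frames covered by any interval.
    """
    e0, e1 = epoch
    if e1 <= e0:
        raise ValueError("epoch window is empty")
    minutes = (e1 - e0) * frame_interval / 60.0
    inside = [iv for iv in intervals if e0 <= iv.start < e1]
    covered = sum(min(iv.end, e1) - max(iv.start, e0)
                  for iv in intervals if iv.end > e0 and iv.start < e1)
    return EventStats(
        active_time=100.0 * covered / (e1 - e0),
        frequency=len(inside) / minutes,
        mean_duration=(float(np.mean([iv.duration for iv in inside]))
                       if inside else None),
        n_events=len(inside),
        epoch_minutes=minutes,
        epoch=label,
    )


@dataclass
class ResponderCriterion:
    """Rule deciding whether an ROI responded to the stimulus.

    An ROI is a responder when (a) its stimulus-epoch event frequency
    exceeds baseline by at least ``min_relative_increase`` (relative),
    and (b) the event-count increase is statistically credible: under
    the null hypothesis of a constant event rate, the stimulus-epoch
    share of events follows a binomial law with success probability
    equal to the stimulus share of the combined epoch duration, and the
    one-sided p-value must fall below ``alpha``.  At least one
    stimulus-epoch event is always required.
    """

    min_relative_increase: float = 0.2
    alpha: float = 0.05


def classify_responder(baseline: EventStats, stimulus: EventStats,
                       criterion: ResponderCriterion | None = None) -> bool:
    from scipy.stats import binomtest

    if criterion is None:
        criterion = ResponderCriterion()
    if stimulus.n_events == 0:
        return False
    k = 1.0 + criterion.min_relative_increase
    if stimulus.frequency < k * baseline.frequency:
        return False
    n = baseline.n_events + stimulus.n_events
    total_min = baseline.epoch_minutes + stimulus.epoch_minutes
    p_null = stimulus.epoch_minutes / total_min if total_min > 0 else 0.5
    p = binomtest(stimulus.n_events, n, p_null, alternative="greater").pvalue
    return bool(p < criterion.alpha)


def peristimulus_average(traces: list[np.ndarray],
                         alignment_times: list[float],
                         sample_intervals: float | list[float],
                         window: tuple[float, float],
                         dt_out: float | None = None,
                         alignment: str = "onset") -> PeristimulusAverage:
    """Average traces on a common time axis around their alignment times.

    Each trace i is assumed uniformly sampled with its
    ``sample_intervals[i]`` starting at t = 0; it is linearly resampled
    to a common axis spanning ``window`` (seconds, e.g. (-60, 120))
    around its alignment time, which maps to t = 0.  Traces that do not
    cover the window are excluded with a warning.  SEM uses the n−1
    standard deviation.
    """
    if np.isscalar(sample_intervals):
        sample_intervals = [float(sample_intervals)] * len(traces)
    if dt_out is None:
        dt_out = min(sample_intervals)
    t_axis = np.arange(window[0], window[1] + 0.5 * dt_out, dt_out)

    rows = []
    for trace, t0, dt in zip(traces, alignment_times, sample_intervals):
        trace = np.asarray(trace, dtype=np.float64)
        t_local = t_axis + t0
        if t_local[0] < 0 or t_local[-1] > (len(trace) - 1) * dt:
            warnings.warn("trace does not cover the window: excluded",
                          stacklevel=2)
            continue
        rows.append(np.interp(t_local, np.arange(len(trace)) * dt, trace))
    if not rows:
        raise ValueError("no trace covers the requested window")
    m = np.vstack(rows)
    mean = m.mean(axis=0)
    if m.shape[0] > 1:
        sem = m.std(axis=0, ddof=1) / np.sqrt(m.shape[0])
    else:
        sem = np.zeros_like(mean)
    return PeristimulusAverage(time_axis=t_axis, mean=mean, sem=sem,
                               n=m.shape[0], alignment=alignment)


def epoch_windows(onset_frame: int, offset_frame: int, n_frames: int
                  ) -> dict[str, tuple[int, int]]:
    """Baseline / stimulus / post epochs around one stimulus.

    Baseline and post windows match the stimulus duration where the
    recording allows, and are clipped to the recording otherwise.
    """
    dur = offset_frame - onset_frame
    if dur <= 0:
        raise ValueError("offset must exceed onset")
    return {
        "baseline": (max(0, onset_frame - dur), onset_frame),
        "stimulus": (onset_frame, offset_frame),
        "post": (offset_frame, min(n_frames, offset_frame + dur)),
    }
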