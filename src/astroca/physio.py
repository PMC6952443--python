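"""Hemodynamic and sympathetic-nerve signal processing.

Implements the physiology side of the perfusion-challenge analysis:

* cerebral perfusion pressure, CPP = MAP − ICP;
* MAP and heart rate extraction from the arterial pressure waveform;
* renal sympathetic nerve activity (RSNA): rectification, first-order
  exponential smoothing (τ = 100 ms), and normalization between resting
  activity (100%) and the post-ganglionic-blockade floor (0%);
* stimulus-locked response features: onset delay relative to the ICP
  step, epoch-mean deltas, and persistence of the response beyond the
  stimulus offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d


@dataclass
class PhysioRecording:
    """Uniformly sampled ICP/ABP/RSNA recording.

    ``abp`` is the pulsatile arterial waveform (mmHg); ``rsna_raw`` is
    the band-limited raw nerve signal (volts).  ``cvp`` is an optional
    constant central venous pressure, ignored by default.
    """

    time: np.ndarray
    icp: np.ndarray
    abp: np.ndarray
    rsna_raw: np.ndarray
    sample_rate: float
    cvp: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.icp = np.asarray(self.icp, dtype=np.float64)
        self.abp = np.asarray(self.abp, dtype=np.float64)
        self.rsna_raw = np.asarray(self.rsna_raw, dtype=np.float64)
        n = len(self.time)
        if not (len(self.icp) == len(self.abp) == len(self.rsna_raw) == n):
            raise ValueError("all channels must have the same length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass
class StimulusProtocol:
    """Timing of one raised-ICP stimulus epoch."""

    onset: float
    offset: float
    target_delta_icp: float | None = None

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must be > onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PhysioResponse:
    """Stimulus-locked response features (epoch-mean deltas by default)."""

    delta_map: float
    delta_hr: float
    delta_rsna: float
    response_delay: float | None
    persistence: float | None
    peak_delta_map: float = float("nan")


def compute_cpp(map_trace: np.ndarray, icp_trace: np.ndarray,
                cvp: float | np.ndarray | None = None) -> np.ndarray:
    """Cerebral perfusion pressure, CPP = MAP − ICP (mmHg).

    When ``cvp`` is supplied, the downstream pressure is taken as
    ``max(ICP, CVP)`` elementwise; by default CVP is ignored, matching
    the operative definition CPP = MAP − ICP.
    """
    map_trace = np.asarray(map_trace, dtype=np.float64)
    icp_trace = np.asarray(icp_trace, dtype=np.float64)
    if map_trace.shape != icp_trace.shape:
        raise ValueError("MAP and ICP traces must have equal length")
    downstream = icp_trace
    if cvp is not None:
        downstream = np.maximum(icp_trace, cvp)
    return map_trace - downstream


def map_and_hr(abp: np.ndarray, sample_rate: float,
               map_window: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Extract MAP and heart rate from the arterial pressure waveform.

    MAP is a ``map_window``-second sliding mean of the waveform.  HR is
    60 / interbeat interval from detected systolic peaks (refractory
    period 0.25 × median interbeat interval), linearly interpolated to
    the full time axis.  A pulseless waveform yields an all-NaN HR trace
    with a warning.

    Parameters
    ----------
    abp : ndarray
        Arterial pressure waveform, mmHg.
    sample_rate : float
        Hz; must resolve individual pulses (≥ ~50 Hz).
    """
    abp = np.asarray(abp, dtype=np.float64)
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    win = max(1, int(round(map_window * sample_rate)))
    map_trace = uniform_filter1d(abp, size=win, mode="nearest")

    pulse_amp = np.percentile(abp - map_trace, 99)
    hr_trace = np.full_like(abp, np.nan)
    if pulse_amp < 1e-6:
        warnings.warn("pulseless waveform: heart rate undefined", stacklevel=2)
        return map_trace, hr_trace

    # first pass without refractory constraint to learn the beat interval
    peaks, _ = sps.find_peaks(abp - map_trace, height=0.3 * pulse_amp)
    if len(peaks) < 3:
        warnings.warn("too few pulses detected: heart rate undefined", stacklevel=2)
        return map_trace, hr_trace
    ibi = float(np.median(np.diff(peaks)))
    peaks, _ = sps.find_peaks(abp - map_trace, height=0.3 * pulse_amp,
                              distance=max(1, int(0.25 * ibi)))
    t_peaks = peaks / sample_rate
    inst_hr = 60.0 / np.diff(t_peaks)
    t_mid = 0.5 * (t_peaks[1:] + t_peaks[:-1])
    t = np.arange(len(abp)) / sample_rate
    hr_trace = np.interp(t, t_mid, inst_hr)
    return map_trace, hr_trace


def rectify_smooth_rsna(rsna_raw: np.ndarray, sample_rate: float,
                        tau: float = 0.1) -> np.ndarray:
    """Rectify and smooth raw RSNA with a first-order filter.

    The raw signal is full-wave rectified and passed through a
    first-order exponential smoother with time constant ``tau``
    (default 100 ms), giving the mean level of sympathetic activity.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    x = np.abs(np.asarray(rsna_raw, dtype=np.float64))
    # exact discrete first-order lag: y[n] = a*y[n-1] + (1-a)*x[n]
    a = np.exp(-1.0 / (tau * sample_rate))
    y = sps.lfilter([1.0 - a], [1.0, -a], x)
    return y


def normalize_rsna(smoothed: np.ndarray, resting_level: float,
                   blockade_floor: float = 0.0) -> np.ndarray:
    """Express smoothed RSNA in percent of resting activity.

    100% corresponds to ``resting_level`` and 0% to the activity floor
    measured under complete ganglionic blockade.
    """
    if resting_level <= blockade_floor:
        raise ValueError("resting_level must exceed blockade_floor")
    x = np.asarray(smoothed, dtype=np.float64)
    return 100.0 * (x - blockade_floor) / (resting_level - blockade_floor)


def response_delay(icp: np.ndarray, response: np.ndarray, sample_rate: float,
                   protocol: StimulusProtocol, k: float = 2.0,
                   m: int | None = None,
                   baseline_window: float | None = None,
                   search_beyond_offset: float = 60.0) -> float | None:
    """Delay from ICP stimulus onset to the response onset, in seconds.

    The response onset is the first time the response exceeds its
    pre-stimulus baseline mean by ``k`` baseline standard deviations for
    at least ``m`` consecutive samples (default: one second's worth —
    smoothed hemodynamic traces are strongly autocorrelated, so a
    sample-count rule must span a physiological duration to reject
    noise bumps).  Returns ``None`` (with a warning) when no sustained
    crossing occurs before ``protocol.offset + search_beyond_offset``.
    """
    response = np.asarray(response, dtype=np.float64)
    n = len(response)
    if m is None:
        m = max(5, int(round(sample_rate)))
    i_on = int(round(protocol.onset * sample_rate))
    if not (0 < i_on < n):
        raise ValueError("protocol onset outside the recording")
    if baseline_window is None:
        i0 = 0
    else:
        i0 = max(0, i_on - int(round(baseline_window * sample_rate)))
    base = response[i0:i_on]
    mu, sd = float(np.mean(base)), float(np.std(base, ddof=1))
    thresh = mu + k * max(sd, 1e-12)
    i_end = min(n, int(round((protocol.offset + search_beyond_offset) * sample_rate)))
    above = response[i_on:i_end] > thresh
    # first run of >= m consecutive supra-threshold samples
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= m:
            onset_idx = i_on + i - m + 1
            return onset_idx / sample_rate - protocol.onset
    warnings.warn("no sustained response onset detected", stacklevel=2)
    return None


def _epoch_mean(x: np.ndarray, sample_rate: float, t0: float, t1: float) -> float:
    i0 = max(0, int(round(t0 * sample_rate)))
    i1 = min(len(x), int(round(t1 * sample_rate)))
    if i1 <= i0:
        raise ValueError("empty epoch window")
    return float(np.nanmean(x[i0:i1]))


def response_summary(recording: PhysioRecording, protocol: StimulusProtocol,
                     rsna_resting_level: float | None = None,
                     rsna_blockade_floor: float = 0.0,
                     delay_kwargs: dict | None = None) -> PhysioResponse:
    """Epoch-mean response deltas and timing features for one stimulus.

    Baseline epoch = window of the stimulus duration immediately before
    onset; stimulus epoch = onset..offset.  Deltas are stimulus-epoch
    mean minus baseline-epoch mean.  Persistence is the time after
    offset until MAP returns below baseline mean + 1 sd.  RSNA resting
    level defaults to its baseline-epoch mean.
    """
    fs = recording.sample_rate
    dur = protocol.duration
    t_base0 = max(0.0, protocol.onset - dur)

    map_trace, hr_trace = map_and_hr(recording.abp, fs)
    rsna = rectify_smooth_rsna(recording.rsna_raw, fs)
    if rsna_resting_level is None:
        rsna_resting_level = _epoch_mean(rsna, fs, t_base0, protocol.onset)
    rsna_pct = normalize_rsna(rsna, rsna_resting_level, rsna_blockade_floor)

    deltas = {}
    for name, trace in (("map", map_trace), ("hr", hr_trace), ("rsna", rsna_pct)):
        b = _epoch_mean(trace, fs, t_base0, protocol.onset)
        s = _epoch_mean(trace, fs, protocol.onset, protocol.offset)
        deltas[name] = s - b

    delay = response_delay(recording.icp, map_trace, fs, protocol,
                           baseline_window=dur, **(delay_kwargs or {}))

    # persistence: decay time constant of the post-offset MAP elevation
    # (time until the elevation falls to 1/e of its offset-time level)
    b_mu = _epoch_mean(map_trace, fs, t_base0, protocol.onset)
    i_off = int(round(protocol.offset * fs))
    elev_off = float(map_trace[i_off] - b_mu)
    persistence: float | None = None
    if elev_off > 0:
        below = map_trace[i_off:] - b_mu <= elev_off / np.e
        idx = np.flatnonzero(below)
        if idx.size:
            persistence = float(idx[0] / fs)

    i_s0, i_s1 = int(round(protocol.onset * fs)), int(round(protocol.offset * fs))
    base_map = _epoch_mean(map_trace, fs, t_base0, protocol.onset)
    peak_dmap = float(np.nanmax(map_trace[i_s0:i_s1]) - base_map)

    return PhysioResponse(delta_map=deltas["map"], delta_hr=deltas["hr"],
                          delta_rsna=deltas["rsna"], response_delay=delay,
                          persistence=persistence, peak_delta_map=peak_dmap)
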