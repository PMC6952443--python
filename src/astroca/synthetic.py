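"""Ground-truth generators for two-channel movies and physiology.

The movie generator emulates the statistical structure the imaging
analysis assumes: astrocyte-shaped ROIs (somas, processes, perivascular
endfeet) on a uniform field of view, planted exponential-kinetics Ca²⁺
transients multiplicative on a slowly drifting low-rank baseline,
lateral motion (rigid random walk + smooth non-rigid fields), and
shot-like noise.  The physiology generator emulates a raised-ICP step
stimulus with a delayed pressor response, an HR response, and an
amplitude-modulated raw sympathetic nerve signal.

Everything planted is recorded in a :class:`GroundTruth` /
:class:`PhysioGroundTruth` object so each downstream stage can be scored
against known truth.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d, map_coordinates

from astroca.core import TwoChannelMovie
from astroca.physio import PhysioRecording

COMPARTMENTS = ("soma", "process", "endfoot")


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class SyntheticMovieParams:
    """Conditions for one synthetic two-channel movie.

    Defaults describe a desk-scale recording: a 128 × 128 field of view
    at 2 Hz for 150 s, sparse astrocyte transients (1.5 events · min⁻¹
    per ROI, ΔF/F₀ amplitude 0.5, rise 1 s / decay 4 s), rank-3
    multiplicative drift of ±10%, a ~2 px rigid motion random walk with
    ~1 px smooth non-rigid deformation, and Gaussian noise.
    """

    height: int = 128
    width: int = 128
    n_frames: int = 300
    frame_interval: float = 0.5
    n_somas: int = 8
    n_processes: int = 10
    n_endfeet: int = 6
    transient_rate: float = 1.5          # events/min per ROI
    transient_amplitude: float = 0.5     # ΔF/F₀ units
    rise_tau: float = 1.0                # s
    decay_tau: float = 4.0               # s
    drift_rank: int = 3
    drift_amplitude: float = 0.1         # fraction of baseline
    rigid_shift_amplitude: float = 2.0   # px
    nonrigid_amplitude: float = 1.0      # px
    noise_sd: float = 5.0                # intensity units
    noise_model: str = "gaussian"        # or "poisson"
    support_fraction: float = 0.1        # event support = kernel >= this * peak
    seed: int = 0

    def validate(self) -> None:
        for name in ("height", "width", "n_frames", "n_somas", "n_processes",
                     "n_endfeet", "drift_rank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.height < 16 or self.width < 16 or self.n_frames < 2:
            raise ValueError("height/width must be >= 16 and n_frames >= 2")
        for name in ("rise_tau", "decay_tau", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_sd", "transient_rate", "transient_amplitude",
                     "drift_amplitude", "rigid_shift_amplitude",
                     "nonrigid_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drift_rank >= min(self.n_frames, self.height * self.width):
            raise ValueError("drift_rank must be < min(n_frames, n_pixels)")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if not 0 < self.support_fraction < 1:
            raise ValueError("support_fraction must be in (0, 1)")


@dataclass
class GroundTruth:
    """Everything planted in a synthetic movie.

    ``label_image`` is 0 = background, 1..n = ROIs; ``compartments[i]``
    is the class of label ``i+1``.  ``motion_shifts``/``motion_fields``
    use the moving → fixed convention, so they are exactly what a
    perfect motion-correction stage would estimate.
    ``transient_intervals`` are half-open frame intervals where an ROI's
    planted signal exceeds ``support_fraction`` of the event amplitude.
    """

    label_image: np.ndarray                       # (H, W) int
    compartments: list[str]
    vessel_mask: np.ndarray                       # (H, W) bool
    transient_intervals: list[list[tuple[int, int]]]
    roi_signals: np.ndarray                       # (n_rois, n_frames) ΔF/F₀
    baseline_movie: np.ndarray                    # (T, H, W)
    motion_shifts: np.ndarray                     # (T, 2)
    motion_fields: np.ndarray | None              # (T, 2, H, W) non-rigid part
    noise_sd: float
    planted_active_time: np.ndarray               # (n_rois,) percent

    @property
    def n_rois(self) -> int:
        return int(self.label_image.max())

    def activity_mask(self) -> np.ndarray:
        """Boolean (T, H, W) pixel-frame activity from planted intervals."""
        n_frames = self.roi_signals.shape[1]
        out = np.zeros((n_frames,) + self.label_image.shape, dtype=bool)
        for lbl, ivals in enumerate(self.transient_intervals, start=1):
            m = self.label_image == lbl
            for s, e in ivals:
                out[s:e][:, m] = True
        return out

    def frame_activity(self) -> np.ndarray:
        """Boolean (n_rois, n_frames) per-ROI activity."""
        n_frames = self.roi_signals.shape[1]
        act = np.zeros((len(self.transient_intervals), n_frames), dtype=bool)
        for i, ivals in enumerate(self.transient_intervals):
            for s, e in ivals:
                act[i, s:e] = True
        return act


@dataclass
class SyntheticPhysioParams:
    """Conditions for one synthetic raised-ICP physiology recording.

    Defaults follow the experimental stimulus: a 10–15 mmHg ICP step
    held for 5 minutes, a ~20 mmHg pressor (MAP) response starting
    ~30 s after stimulus onset, persisting ~2 min past offset at desk
    scale, and an RSNA envelope tracking the pressor response.
    """

    duration: float = 900.0
    sample_rate: float = 100.0
    icp_baseline: float = 5.0
    icp_step: float = 12.0
    step_onset: float = 180.0
    step_duration: float = 300.0
    map_baseline: float = 100.0
    pressor_amplitude: float = 20.0
    response_delay: float = 30.0
    response_persistence: float = 120.0   # post-offset decay constant, s
    response_rise_tau: float = 5.0
    hr_baseline: float = 360.0            # bpm
    hr_delta: float = 25.0                # bpm
    pulse_pressure: float = 30.0          # mmHg peak-to-trough
    rsna_gain: float = 2.0                # % resting per mmHg of MAP rise
    rsna_resting_envelope: float = 0.05   # volts
    icp_noise_sd: float = 0.2
    abp_noise_sd: float = 1.0
    icp_rise_tau: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.response_delay < 0:
            raise ValueError("response_delay must be >= 0")
        if self.step_onset + self.step_duration > self.duration:
            raise ValueError("step_onset + step_duration must be <= duration")


@dataclass
class PhysioGroundTruth:
    """Planted response features of a synthetic physiology recording."""

    icp_onset: float
    icp_offset: float
    icp_step: float
    response_delay: float
    pressor_amplitude: float
    hr_delta: float
    persistence: float
    rsna_percent_increase: float
    rsna_resting_envelope: float


# --------------------------------------------------------------------------
# ROI geometry
# --------------------------------------------------------------------------

def _stamp_disks(mask: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                 radius: float) -> None:
    """Rasterize a thick curve by stamping disks along dense samples."""
    h, w = mask.shape
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy ** 2 + xx ** 2) <= radius ** 2
    for y, x in zip(np.round(ys).astype(int), np.round(xs).astype(int)):
        y0, y1 = max(0, y - r), min(h, y + r + 1)
        x0, x1 = max(0, x - r), min(w, x + r + 1)
        if y1 <= y0 or x1 <= x0:
            continue
        mask[y0:y1, x0:x1] |= disk[y0 - (y - r):y1 - (y - r),
                                   x0 - (x - r):x1 - (x - r)]


def _vessel_path(h: int, w: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Smooth curve crossing the field of view left to right."""
    xs = np.linspace(2, w - 3, 4 * w)
    ctrl = rng.uniform(0.3 * h, 0.7 * h, size=5)
    ys = np.interp(xs, np.linspace(2, w - 3, 5), ctrl)
    ys = gaussian_filter1d(ys, sigma=40, mode="nearest")
    return ys, xs


def _soma_mask(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    cy, cx = rng.uniform(10, h - 10), rng.uniform(10, w - 10)
    a, b = rng.uniform(4, 8), rng.uniform(4, 8)
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _process_mask(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    # curved polyline: random-heading walk, dilated to width 2–3 px
    n_pts = 200
    length = rng.uniform(20, 35)
    y, x = rng.uniform(8, h - 8), rng.uniform(8, w - 8)
    heading = rng.uniform(0, 2 * np.pi)
    curvature = rng.normal(0, 0.02, size=n_pts).cumsum()
    step = length / n_pts
    ys, xs = np.empty(n_pts), np.empty(n_pts)
    for i in range(n_pts):
        ys[i], xs[i] = y, x
        y += step * np.sin(heading + curvature[i])
        x += step * np.cos(heading + curvature[i])
    ys, xs = np.clip(ys, 1, h - 2), np.clip(xs, 1, w - 2)
    mask = np.zeros((h, w), dtype=bool)
    _stamp_disks(mask, ys, xs, radius=rng.uniform(1.0, 1.5))
    return mask


def _endfoot_mask(h: int, w: int, vessel_dist: np.ndarray,
                  path_ys: np.ndarray, path_xs: np.ndarray,
                  vessel_radius: float, rng: np.random.Generator) -> np.ndarray:
    # annular arc hugging the vessel: band of path-distance just outside
    # the lumen, restricted to an arc around a random anchor and to ONE
    # side of the vessel so the ROI stays contiguous
    i = rng.integers(int(0.1 * len(path_xs)), int(0.9 * len(path_xs)))
    ay, ax = path_ys[i], path_xs[i]
    arc_len = rng.uniform(8, 14)
    side = 1 if rng.random() < 0.5 else -1
    yy, xx = np.mgrid[0:h, 0:w]
    near_anchor = (yy - ay) ** 2 + (xx - ax) ** 2 <= arc_len ** 2
    band = (vessel_dist > vessel_radius) & (vessel_dist <= vessel_radius + 3)
    path_y_of_x = np.interp(np.arange(w), path_xs, path_ys)
    on_side = side * (yy - path_y_of_x[None, :]) > 0
    return band & near_anchor & on_side


def _place_rois(params: SyntheticMovieParams, rng: np.random.Generator
                ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Disjoint labeled ROIs plus the vessel lumen mask."""
    h, w = params.height, params.width
    path_ys, path_xs = _vessel_path(h, w, rng)
    vessel_radius = 3.5
    yy, xx = np.mgrid[0:h, 0:w]
    # distance from each pixel to the (densely sampled) vessel path
    d2 = np.full((h, w), np.inf)
    for y0, x0 in zip(path_ys[::8], path_xs[::8]):
        d2 = np.minimum(d2, (yy - y0) ** 2 + (xx - x0) ** 2)
    vessel_dist = np.sqrt(d2)
    vessel_mask = vessel_dist <= vessel_radius

    label = np.zeros((h, w), dtype=np.int32)
    compartments: list[str] = []
    taken = vessel_mask.copy()

    def try_place(make, kind: str) -> None:
        for _ in range(40):
            m = make()
            if m.sum() < 6:
                continue
            if not (m & taken).any():
                from skimage.morphology import label as _sklabel
                if _sklabel(m, connectivity=2).max() != 1:
                    continue      # keep every ROI a single contiguous region
                label[m] = len(compartments) + 1
                compartments.append(kind)
                # 2-px moat keeps ROIs from merging under adaptive blocks
                grown = m.copy()
                for _ in range(2):
                    g = grown.copy()
                    g[:-1] |= grown[1:]; g[1:] |= grown[:-1]
                    g[:, :-1] |= grown[:, 1:]; g[:, 1:] |= grown[:, :-1]
                    g[:-1, :-1] |= grown[1:, 1:]; g[1:, 1:] |= grown[:-1, :-1]
                    g[:-1, 1:] |= grown[1:, :-1]; g[1:, :-1] |= grown[:-1, 1:]
                    grown = g
                taken[grown] = True
                return

    for _ in range(params.n_somas):
        try_place(lambda: _soma_mask(h, w, rng), "soma")
    for _ in range(params.n_processes):
        try_place(lambda: _process_mask(h, w, rng), "process")
    for _ in range(params.n_endfeet):
        try_place(lambda: _endfoot_mask(h, w, vessel_dist, path_ys, path_xs,
                                        vessel_radius, rng), "endfoot")
    return label, compartments, vessel_mask


# --------------------------------------------------------------------------
# temporal structure
# --------------------------------------------------------------------------

def transient_kernel(n_frames: int, frame_interval: float, rise_tau: float,
                     decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, peak-normalized to 1."""
    t = np.arange(n_frames) * frame_interval
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    peak = k.max()
    if peak <= 0:  # rise_tau >= decay_tau degenerates; fall back to decay
        k = np.exp(-t / decay_tau)
        peak = 1.0
    return k / peak


def sample_event_onsets(rate_per_min: float, n_frames: int,
                        frame_interval: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Poisson event onset frames over the movie duration."""
    duration_min = n_frames * frame_interval / 60.0
    n = rng.poisson(rate_per_min * duration_min)
    return np.sort(rng.integers(0, n_frames, size=n))


def _intervals_from_signal(signal: np.ndarray, level: float) -> list[tuple[int, int]]:
    above = signal >= level
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [len(signal)]
    return list(zip(starts, ends))


def generate_roi_signal(params: SyntheticMovieParams, rng: np.random.Generator
                        ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """One ROI's planted ΔF/F₀ signal and its support intervals."""
    kernel = transient_kernel(params.n_frames, params.frame_interval,
                              params.rise_tau, params.decay_tau)
    onsets = sample_event_onsets(params.transient_rate, params.n_frames,
                                 params.frame_interval, rng)
    s = np.zeros(params.n_frames)
    for o in onsets:
        nk = params.n_frames - o
        s[o:] += params.transient_amplitude * kernel[:nk]
    level = params.support_fraction * params.transient_amplitude
    intervals = _intervals_from_signal(s, level) if len(onsets) else []
    return s, intervals


def _lowrank_drift(params: SyntheticMovieParams, rng: np.random.Generator
                   ) -> np.ndarray:
    """Multiplicative drift field (T, H, W): 1 + sum of smooth outer products."""
    T, h, w = params.n_frames, params.height, params.width
    drift = np.ones((T, h, w))
    if params.drift_rank == 0 or params.drift_amplitude == 0:
        return drift
    t = np.linspace(0, 1, T)
    for k in range(params.drift_rank):
        if k == 0:
            temporal = t - 0.5                       # slow linear ramp
        else:
            freq = 0.5 * k
            phase = rng.uniform(0, 2 * np.pi)
            temporal = 0.5 * np.sin(2 * np.pi * freq * t + phase)
        spatial = gaussian_filter(rng.standard_normal((h, w)),
                                  sigma=0.25 * min(h, w))
        spatial /= max(np.abs(spatial).max(), 1e-12)
        amp = params.drift_amplitude / params.drift_rank
        drift += amp * temporal[:, None, None] * spatial[None]
    return drift


def _motion(params: SyntheticMovieParams, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray | None]:
    """Rigid shifts (T, 2) and optional non-rigid fields (T, 2, H, W)."""
    T, h, w = params.n_frames, params.height, params.width
    shifts = np.zeros((T, 2))
    if params.rigid_shift_amplitude > 0:
        walk = rng.standard_normal((T, 2)).cumsum(axis=0)
        walk = gaussian_filter1d(walk, sigma=5, axis=0)
        walk -= walk[0]
        scale = np.abs(walk).max()
        if scale > 0:
            shifts = walk / scale * params.rigid_shift_amplitude

    fields = None
    if params.nonrigid_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        ky = 2 * np.pi / h
        kx = 2 * np.pi / w
        phase_y, phase_x = rng.uniform(0, 2 * np.pi, size=2)
        base_dy = np.sin(ky * yy + phase_y) * np.cos(kx * xx)
        base_dx = np.cos(ky * yy) * np.sin(kx * xx + phase_x)
        t = np.arange(T) * params.frame_interval
        period = max(20.0, T * params.frame_interval / 3)
        mod = np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
        mod -= mod[0]  # first frame is the reference: zero motion
        scale = np.abs(mod).max()
        if scale > 0:
            mod /= scale
        fields = np.empty((T, 2, h, w))
        fields[:, 0] = params.nonrigid_amplitude * mod[:, None, None] * base_dy
        fields[:, 1] = params.nonrigid_amplitude * mod[:, None, None] * base_dx
    if params.rigid_shift_amplitude > 0:
        shifts[0] = 0.0
    return shifts, fields


def warp_frame(frame: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    """Warp so that ``out(p) = frame(p - d(p))`` (content moved by +d).

    The inverse operation — sampling at ``p + d(p)`` — is what the
    correction stage applies; see :mod:`astroca.motion`.
    """
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([yy - displacement[0], xx - displacement[1]])
    return map_coordinates(frame, coords, order=1, mode="nearest")


# --------------------------------------------------------------------------
# movie generation
# --------------------------------------------------------------------------

def generate_movie(params: SyntheticMovieParams
                   ) -> tuple[TwoChannelMovie, GroundTruth]:
    """Generate a two-channel movie and the full ground truth.

    Functional channel = baseline drift × (1 + planted transients),
    warped by the planted motion, plus noise; structural channel =
    static marker texture warped by the same motion, plus noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w, T = params.height, params.width, params.n_frames

    label, compartments, vessel_mask = _place_rois(params, rng)
    n_rois = len(compartments)

    # static base images: smooth texture gives the registration something
    # to lock onto; ROIs are bright in both channels
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
    texture /= max(np.abs(texture).max(), 1e-12)
    roi_fg = label > 0
    func_base = 30.0 + 15.0 * texture + 60.0 * roi_fg + 25.0 * vessel_mask
    struct_base = 20.0 + 10.0 * texture + 90.0 * roi_fg

    drift = _lowrank_drift(params, rng)
    baseline_movie = drift * func_base[None]

    signals = np.zeros((max(n_rois, 1), T))
    intervals: list[list[tuple[int, int]]] = []
    gain = np.ones((T, h, w))
    for i in range(n_rois):
        s, ivals = generate_roi_signal(params, rng)
        signals[i] = s
        intervals.append(ivals)
        gain[:, label == i + 1] += s[:, None]

    clean_func = baseline_movie * gain
    shifts, fields = _motion(params, rng)

    functional = np.empty((T, h, w))
    structural = np.empty((T, h, w))
    any_motion = params.rigid_shift_amplitude > 0 or params.nonrigid_amplitude > 0
    for t in range(T):
        if any_motion:
            d = np.zeros((2, h, w))
            d[0] += shifts[t, 0]
            d[1] += shifts[t, 1]
            if fields is not None:
                d += fields[t]
            functional[t] = warp_frame(clean_func[t], d)
            structural[t] = warp_frame(struct_base, d)
        else:
            functional[t] = clean_func[t]
            structural[t] = struct_base

    if params.noise_model == "poisson":
        # scale so that variance at the mean functional level ~ noise_sd^2
        mean_level = max(functional.mean(), 1e-9)
        g = params.noise_sd ** 2 / mean_level if params.noise_sd > 0 else 0.0
        if g > 0:
            functional = g * rng.poisson(functional / g)
            structural = g * rng.poisson(structural / g)
    elif params.noise_sd > 0:
        functional = functional + rng.normal(0, params.noise_sd, size=(T, h, w))
        structural = structural + rng.normal(0, params.noise_sd, size=(T, h, w))
    functional = np.maximum(functional, 0.0)
    structural = np.maximum(structural, 0.0)

    act = np.zeros(max(n_rois, 1))
    for i, ivals in enumerate(intervals):
        act[i] = 100.0 * sum(e - s for s, e in ivals) / T

    movie = TwoChannelMovie(functional=functional, structural=structural,
                            frame_interval=params.frame_interval)
    truth = GroundTruth(label_image=label, compartments=compartments,
                        vessel_mask=vessel_mask,
                        transient_intervals=intervals,
                        roi_signals=signals[:n_rois] if n_rois else signals[:0],
                        baseline_movie=baseline_movie,
                        motion_shifts=shifts, motion_fields=fields,
                        noise_sd=params.noise_sd,
                        planted_active_time=act[:n_rois] if n_rois else act[:0])
    return movie, truth


def generate_dff_movie(params: SyntheticMovieParams
                       ) -> tuple[np.ndarray, GroundTruth]:
    """Synthetic movie directly in ΔF/F₀ units (no drift/motion/baseline).

    Planted ROI signals plus iid Gaussian noise of exactly
    ``params.noise_sd`` (ΔF/F₀ units), so the signal-to-noise ratio is
    ``transient_amplitude / noise_sd`` by construction.  Used to
    characterize the detection stage in isolation.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w, T = params.height, params.width, params.n_frames
    label, compartments, vessel_mask = _place_rois(params, rng)
    n_rois = len(compartments)
    signals = np.zeros((max(n_rois, 1), T))
    intervals: list[list[tuple[int, int]]] = []
    dff = np.zeros((T, h, w))
    for i in range(n_rois):
        s, ivals = generate_roi_signal(params, rng)
        signals[i] = s
        intervals.append(ivals)
        dff[:, label == i + 1] += s[:, None]
    if params.noise_sd > 0:
        dff += rng.normal(0, params.noise_sd, size=(T, h, w))
    act = np.array([100.0 * sum(e - s for s, e in iv) / T for iv in intervals]
                   or [0.0])
    truth = GroundTruth(label_image=label, compartments=compartments,
                        vessel_mask=vessel_mask,
                        transient_intervals=intervals,
                        roi_signals=signals[:n_rois],
                        baseline_movie=np.zeros((1, h, w)),
                        motion_shifts=np.zeros((T, 2)), motion_fields=None,
                        noise_sd=params.noise_sd,
                        planted_active_time=act[:n_rois])
    return dff, truth


# --------------------------------------------------------------------------
# trace-level generation (long-duration event statistics)
# --------------------------------------------------------------------------

def generate_roi_trace(rate_per_min: float, duration: float,
                       frame_interval: float, amplitude: float,
                       rise_tau: float, decay_tau: float, noise_sd: float,
                       rng: np.random.Generator,
                       support_fraction: float = 0.2,
                       rate_stimulus: float | None = None,
                       stimulus_window: tuple[float, float] | None = None,
                       ) -> tuple[np.ndarray, list[tuple[int, int]], np.ndarray]:
    """A single long ΔF/F₀ trace with planted events.

    Used for event-rate and responder statistics where a full movie
    would be wasteful.  Optionally plants a different event rate inside
    ``stimulus_window`` (seconds).  Returns (trace, support intervals,
    onset frames).
    """
    n = int(round(duration / frame_interval))
    t = np.arange(n) * frame_interval
    rate = np.full(n, rate_per_min)
    if rate_stimulus is not None and stimulus_window is not None:
        in_stim = (t >= stimulus_window[0]) & (t < stimulus_window[1])
        rate[in_stim] = rate_stimulus
    # thinned Bernoulli-per-frame Poisson process
    p = rate * frame_interval / 60.0
    onsets = np.flatnonzero(rng.random(n) < p)
    kernel = transient_kernel(n, frame_interval, rise_tau, decay_tau)
    s = np.zeros(n)
    for o in onsets:
        s[o:] += amplitude * kernel[:n - o]
    intervals = (_intervals_from_signal(s, support_fraction * amplitude)
                 if len(onsets) else [])
    trace = s + rng.normal(0, noise_sd, size=n) if noise_sd > 0 else s.copy()
    return trace, intervals, onsets


# --------------------------------------------------------------------------
# physiology generation
# --------------------------------------------------------------------------

def synthesize_abp(map_trace: np.ndarray, hr_bpm: np.ndarray,
                   pulse_pressure: float, sample_rate: float) -> np.ndarray:
    """Pulsatile arterial waveform with given MAP and heart-rate profiles."""
    hr_hz = np.asarray(hr_bpm, dtype=np.float64) / 60.0
    phase = 2 * np.pi * np.cumsum(hr_hz) / sample_rate
    return np.asarray(map_trace) + 0.5 * pulse_pressure * np.sin(phase)


def _response_kernel(t: np.ndarray, onset: float, offset: float,
                     rise_tau: float, persistence: float) -> np.ndarray:
    """0→1 delayed-rise / sustained / exponential-release response shape."""
    r = np.zeros_like(t)
    rising = (t >= onset) & (t < offset)
    r[rising] = 1.0 - np.exp(-(t[rising] - onset) / rise_tau)
    after = t >= offset
    level_at_off = 1.0 - np.exp(-max(offset - onset, 0.0) / rise_tau)
    r[after] = level_at_off * np.exp(-(t[after] - offset) / max(persistence, 1e-9))
    return r


def generate_physio(params: SyntheticPhysioParams
                    ) -> tuple[PhysioRecording, PhysioGroundTruth]:
    """Synthetic raised-ICP challenge recording plus planted response truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs

    onset, offset = params.step_onset, params.step_onset + params.step_duration

    # ICP: boxcar smoothed by a short rise constant
    icp_shape = _response_kernel(t, onset, offset, params.icp_rise_tau,
                                 persistence=params.icp_rise_tau)
    icp = params.icp_baseline + params.icp_step * icp_shape
    if params.icp_noise_sd > 0:
        icp = icp + rng.normal(0, params.icp_noise_sd, size=n)

    # MAP: delayed pressor response with post-offset persistence
    resp = _response_kernel(t, onset + params.response_delay,
                            offset, params.response_rise_tau,
                            params.response_persistence)
    map_slow = params.map_baseline + params.pressor_amplitude * resp
    hr = params.hr_baseline + params.hr_delta * resp

    abp = synthesize_abp(map_slow, hr, params.pulse_pressure, fs)
    if params.abp_noise_sd > 0:
        abp = abp + rng.normal(0, params.abp_noise_sd, size=n)

    # RSNA: amplitude-modulated noise; envelope follows the MAP response
    envelope = params.rsna_resting_envelope * (
        1.0 + params.rsna_gain / 100.0 * params.pressor_amplitude * resp)
    rsna_raw = envelope * rng.standard_normal(n)

    rec = PhysioRecording(time=t, icp=icp, abp=abp, rsna_raw=rsna_raw,
                          sample_rate=fs)
    truth = PhysioGroundTruth(
        icp_onset=onset, icp_offset=offset, icp_step=params.icp_step,
        response_delay=params.response_delay,
        pressor_amplitude=params.pressor_amplitude,
        hr_delta=params.hr_delta,
        persistence=params.response_persistence,
        rsna_percent_increase=params.rsna_gain * params.pressor_amplitude,
        rsna_resting_envelope=params.rsna_resting_envelope)
    return rec, truth


# --------------------------------------------------------------------------
# persistence to disk
# --------------------------------------------------------------------------

def save_movie(movie: TwoChannelMovie, path_functional: str | Path,
               path_structural: str | Path | None = None,
               interleaved: bool = False) -> None:
    """Write a two-channel movie as multi-page TIFF.

    With ``interleaved=True`` both channels go to ``path_functional``
    as alternating pages (functional, structural, functional, ...).
    """
    import tifffile

    func = movie.functional.astype(np.float32)
    struct = movie.structural.astype(np.float32)
    if interleaved:
        inter = np.empty((2 * movie.n_frames,) + movie.frame_shape,
                         dtype=np.float32)
        inter[0::2], inter[1::2] = func, struct
        tifffile.imwrite(str(path_functional), inter)
        return
    if path_structural is None:
        raise ValueError("path_structural required unless interleaved")
    tifffile.imwrite(str(path_functional), func)
    tifffile.imwrite(str(path_structural), struct)


def save_ground_truth(truth: GroundTruth, json_path: str | Path,
                      label_tiff_path: str | Path) -> None:
    """Ground truth as a JSON summary plus a label-image TIFF."""
    import tifffile

    tifffile.imwrite(str(label_tiff_path), truth.label_image.astype(np.int32))
    payload = {
        "compartments": list(truth.compartments),
        "transient_intervals": [[[int(s), int(e)] for s, e in ivals]
                                for ivals in truth.transient_intervals],
        "planted_active_time": truth.planted_active_time.tolist(),
        "motion_shifts": truth.motion_shifts.tolist(),
        "noise_sd": truth.noise_sd,
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))


def save_physio(rec: PhysioRecording, truth: PhysioGroundTruth,
                csv_path: str | Path, sidecar_path: str | Path) -> None:
    """Recording as CSV (time, icp, abp, rsna) + JSON sidecar."""
    df = pd.DataFrame({"time": rec.time, "icp": rec.icp, "abp": rec.abp,
                       "rsna": rec.rsna_raw})
    df.to_csv(csv_path, index=False)
    payload = {"sample_rate": rec.sample_rate, "ground_truth": asdict(truth)}
    Path(sidecar_path).write_text(json.dumps(payload, indent=1))


def load_physio(csv_path: str | Path, sidecar_path: str | Path
                ) -> tuple[PhysioRecording, dict]:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(sidecar_path).read_text())
    rec = PhysioRecording(time=df["time"].to_numpy(),
                          icp=df["icp"].to_numpy(), abp=df["abp"].to_numpy(),
                          rsna_raw=df["rsna"].to_numpy(),
                          sample_rate=meta["sample_rate"])
    return rec, meta.get("ground_truth", {})
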