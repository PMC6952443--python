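"""Selective-averaging denoising and Ca²⁺ transient detection.

Pixel-by-pixel ΔF/F₀ traces are noisy, while plain spatial binning
costs resolution.  The compromise implemented here: in a moving window,
all ΔF/F₀ traces are projected onto the first few principal components
and clustered; the cluster containing the window's center pixel is
selected and its member traces averaged.  The average is accumulated
into every member pixel with a weight inversely proportional to the
pixel's distance from the cluster centroid in PC space, so pixels that
belong to different clusters in different (overlapping) windows receive
multiple estimates which are finally aggregated by their recorded
weights.  Transients are detected on the aggregated traces: a
temporally smoothed signal is thresholded at ``threshold_sd`` (default
2) standard deviations of the noise, with the noise SD estimated
robustly per trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.cluster import KMeans

_EPS_WEIGHT = 1e-6
_MAD_TO_SD = 1.4826


@dataclass
class DetectionParams:
    """Knobs of the selective-averaging detector.

    ``window_size``/``window_stride`` define the moving square window
    grid (stride ≤ size so windows overlap); ``n_pcs`` the number of
    principal components kept; ``n_clusters`` the k-means k;
    ``smoothing_width`` the FWHM (frames) of the Gaussian temporal
    smoothing applied before thresholding; ``threshold_sd`` the
    noise-SD multiplier of the detection threshold.
    """

    window_size: int = 16
    window_stride: int = 8
    n_pcs: int = 5
    n_clusters: int = 3
    smoothing_width: float = 3.0
    threshold_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.window_stride > self.window_size:
            raise ValueError("window_stride must be <= window_size")
        if self.window_stride < 1 or self.window_size < 2:
            raise ValueError("window sizes must be positive")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be > 0")


@dataclass
class DenoisedResult:
    """Aggregated denoised movie with detection byproducts."""

    denoised: np.ndarray          # (T, H, W) ΔF/F₀
    transient_mask: np.ndarray    # (T, H, W) bool
    weight_sum: np.ndarray        # (H, W)
    noise_sd_map: np.ndarray      # (H, W)


def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust noise SD of a temporal signal.

    Median absolute first difference scaled to the SD of white Gaussian
    noise; first-differencing cancels slow trends and the median
    ignores sparse transients.  A constant trace returns 0.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or len(trace) < 10:
        raise ValueError("trace must be 1-D with length >= 10")
    d = np.diff(trace)
    return float(_MAD_TO_SD * np.median(np.abs(d - np.median(d))) / np.sqrt(2))


def smooth_trace(trace: np.ndarray, width: float) -> np.ndarray:
    """Gaussian temporal smoothing; ``width`` is the FWHM in frames."""
    sigma = width / 2.3548
    if sigma <= 0:
        return np.asarray(trace, dtype=np.float64)
    return gaussian_filter1d(np.asarray(trace, dtype=np.float64), sigma,
                             axis=-1, mode="nearest")


def detect_transients(trace: np.ndarray, noise_sd: float,
                      params: DetectionParams | None = None,
                      refine_edges: bool = True) -> np.ndarray:
    """Boolean activity vector: smoothed trace above threshold × noise SD.

    Detection runs on the temporally smoothed trace for robustness; with
    ``refine_edges`` each detected run is then trimmed to the frames
    where the unsmoothed trace itself exceeds the threshold, so the
    smoothing kernel does not pad event durations at both ends.
    """
    if params is None:
        params = DetectionParams()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    trace = np.asarray(trace, dtype=np.float64)
    thresh = params.threshold_sd * noise_sd
    smoothed = smooth_trace(trace, params.smoothing_width)
    mask = smoothed > thresh
    if not refine_edges or not mask.any():
        return mask
    raw_above = trace > thresh
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    edges = np.diff(padded)
    out = np.zeros_like(mask)
    for s, e in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
        idx = np.flatnonzero(raw_above[s:e])
        if idx.size:
            # an event spans first to last raw threshold crossing of the
            # run; brief interior dips stay part of the event
            out[s + idx[0]:s + idx[-1] + 1] = True
    return out


def denoise_window(patch: np.ndarray, params: DetectionParams | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Selective averaging of one window of ΔF/F₀ signals.

    ``patch`` has shape (T, h, w).  Each pixel's trace is projected on
    the patch's first ``n_pcs`` principal components and the projections
    are k-means clustered; the cluster containing the center pixel is
    selected.  Returns (average trace over the selected cluster, flat
    indices of member pixels, member weights ``1/(ε + d)`` with d the
    PC-space distance to the cluster centroid).

    Windows with fewer distinct signals than clusters fall back to
    whole-window averaging with a warning.
    """
    if params is None:
        params = DetectionParams()
    t, h, w = patch.shape
    x = patch.reshape(t, h * w).T           # (pixels, time)
    center = (h // 2) * w + w // 2

    xc = x - x.mean(axis=1, keepdims=True)
    n_distinct = np.unique(np.round(xc, 12), axis=0).shape[0]
    if n_distinct < params.n_clusters:
        warnings.warn("window has too few distinct signals; averaging all",
                      stacklevel=2)
        members = np.arange(h * w)
        weights = np.ones(h * w)
        return x.mean(axis=0), members, weights

    # PCA of the patch: project traces onto the top temporal components
    n_pcs = min(params.n_pcs, t, h * w)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    proj = u[:, :n_pcs] * s[:n_pcs]         # (pixels, n_pcs)

    km = KMeans(n_clusters=params.n_clusters, n_init=3,
                random_state=params.seed)
    labels = km.fit_predict(proj)
    sel = labels[center]
    members = np.flatnonzero(labels == sel)
    d = np.linalg.norm(proj[members] - km.cluster_centers_[sel], axis=1)
    weights = 1.0 / (_EPS_WEIGHT + d)
    avg = x[members].mean(axis=0)
    return avg, members, weights


def _window_starts(extent: int, size: int, stride: int) -> list[int]:
    starts = list(range(0, max(extent - size, 0) + 1, stride))
    if starts[-1] != max(extent - size, 0):
        starts.append(max(extent - size, 0))
    return sorted(set(starts))


def selective_average_movie(dff: np.ndarray,
                            params: DetectionParams | None = None
                            ) -> DenoisedResult:
    """Run selective averaging over the full movie and detect transients.

    Overlapping windows are placed on a regular grid (last windows are
    clamped to the border so every pixel is covered).  Each pixel's
    aggregated trace is the weight-normalized average of all
    cluster-average traces it received.  The transient mask is the
    2-SD rule applied to each aggregated trace with its own robust
    noise-SD estimate.
    """
    if params is None:
        params = DetectionParams()
    params.validate()
    dff = np.asarray(dff, dtype=np.float64)
    T, h, w = dff.shape
    size = params.window_size
    if h < size or w < size:
        raise ValueError("movie must be at least one window in each dimension")

    acc = np.zeros((h * w, T))
    wsum = np.zeros(h * w)
    flat = dff.reshape(T, h * w)
    for y0 in _window_starts(h, size, params.window_stride):
        for x0 in _window_starts(w, size, params.window_stride):
            patch = dff[:, y0:y0 + size, x0:x0 + size]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                avg, members, weights = denoise_window(patch, params)
            yy = y0 + members // size
            xx = x0 + members % size
            idx = yy * w + xx
            acc[idx] += weights[:, None] * avg[None, :]
            wsum[idx] += weights

    uncovered = wsum == 0
    if uncovered.any():
        # pixels never selected keep their raw trace (weight 1)
        acc[uncovered] = flat.T[uncovered]
        wsum[uncovered] = 1.0
    denoised = (acc / wsum[:, None]).T.reshape(T, h, w)

    noise_map = np.empty(h * w)
    mask = np.empty((T, h * w), dtype=bool)
    den_flat = denoised.reshape(T, h * w)
    for p in range(h * w):
        noise_map[p] = estimate_noise_sd(den_flat[:, p])
        # intersect with the raw rule so mask ⇒ trace above threshold
        mask[:, p] = detect_transients(den_flat[:, p], noise_map[p], params) \
            & (den_flat[:, p] > params.threshold_sd * noise_map[p])
    noise_map = noise_map.reshape(h, w)
    mask = mask.reshape(T, h, w)
    return DenoisedResult(denoised=denoised, transient_mask=mask,
                          weight_sum=wsum.reshape(h, w),
                          noise_sd_map=noise_map)
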