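"""ROI segmentation, compartment classification and trace extraction.

Bright regions of the structural (marker) channel are segmented by
adaptive thresholding in small pixel blocks (default 11 × 11) in each
frame; contiguous regions that are foreground in more than 50% of
frames (strict) become ROIs.  ROIs are classified into astrocyte
compartments — somas (compact, solid), processes (elongated), and
perivascular endfeet (adjacent to a vessel mask) — by shape heuristics,
and used as masks to extract denoised ΔF/F₀ traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.measure import label as sk_label, regionprops

log = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    """Adaptive-threshold segmentation settings.

    ``block_size`` is the odd side of the sliding local-mean
    neighbourhood; a pixel is foreground when it exceeds the local mean
    by ``contrast_floor``.  A pixel must be foreground in strictly more
    than ``persistence_fraction`` of frames to survive.
    """

    block_size: int = 11
    persistence_fraction: float = 0.5
    connectivity: int = 8
    min_roi_area: int = 6
    contrast_floor: float = 5.0

    def validate(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError("block_size must be odd and >= 3")
        if not 0 < self.persistence_fraction < 1:
            raise ValueError("persistence_fraction must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_roi_area < 1:
            raise ValueError("min_roi_area must be >= 1")


@dataclass
class ROISet:
    """Labeled contiguous ROI masks with compartment classes."""

    label_image: np.ndarray              # (H, W) int, 0 = background
    compartments: list[str]              # per ROI, label order
    areas: np.ndarray
    centroids: np.ndarray                # (n, 2) (y, x)

    @property
    def n_rois(self) -> int:
        return len(self.compartments)

    def mask(self, label: int) -> np.ndarray:
        return self.label_image == label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": np.arange(1, self.n_rois + 1),
            "compartment": self.compartments,
            "area": self.areas,
            "centroid_y": self.centroids[:, 0],
            "centroid_x": self.centroids[:, 1],
        })


def adaptive_foreground(frame: np.ndarray, params: SegmentationParams
                        ) -> np.ndarray:
    """Per-frame foreground: pixel > sliding local mean + contrast floor."""
    frame = np.asarray(frame, dtype=np.float64)
    local_mean = uniform_filter(frame, size=params.block_size, mode="nearest")
    return frame > local_mean + params.contrast_floor


def segment_rois(structural: np.ndarray,
                 params: SegmentationParams | None = None) -> ROISet:
    """Segment persistent bright regions of the structural channel.

    Foreground is computed per frame by local adaptive thresholding;
    the persistence map (fraction of frames foreground) is thresholded
    strictly above ``persistence_fraction``; contiguous regions are
    labeled and filtered by ``min_roi_area``.  A degenerate uniform
    stack simply yields zero ROIs.
    """
    if params is None:
        params = SegmentationParams()
    params.validate()
    structural = np.asarray(structural, dtype=np.float64)
    if structural.ndim != 3 or structural.shape[0] < 2:
        raise ValueError("structural stack must be (n_frames, H, W), >= 2 frames")

    persistence = np.zeros(structural.shape[1:])
    for frame in structural:
        persistence += adaptive_foreground(frame, params)
    persistence /= structural.shape[0]

    fg = persistence > params.persistence_fraction   # strict >
    conn = 2 if params.connectivity == 8 else 1
    lab = sk_label(fg, connectivity=conn)

    keep_labels = [p.label for p in regionprops(lab)
                   if p.area >= params.min_roi_area]
    out = np.zeros_like(lab)
    for new, old in enumerate(keep_labels, start=1):
        out[lab == old] = new
    props = regionprops(out)
    areas = np.array([p.area for p in props], dtype=int)
    cents = (np.array([p.centroid for p in props])
             if props else np.empty((0, 2)))
    return ROISet(label_image=out,
                  compartments=["unclassified"] * len(props),
                  areas=areas, centroids=cents)


def classify_compartments(rois: ROISet, vessel_map: np.ndarray | None = None,
                          soma_min_area: int = 40,
                          soma_min_solidity: float = 0.85,
                          process_min_eccentricity: float = 0.93,
                          vessel_margin: int = 3,
                          vessel_fraction: float = 0.5) -> ROISet:
    """Assign compartment classes to segmented ROIs by shape heuristics.

    * endfoot — at least ``vessel_fraction`` of the ROI's pixels lie
      within ``vessel_margin`` pixels of the vessel mask (class
      unavailable without a vessel map);
    * soma — compact: area ≥ ``soma_min_area`` and solidity ≥
      ``soma_min_solidity``;
    * process — elongated: eccentricity ≥ ``process_min_eccentricity``
      or a large skeleton-like extent;
    * everything else stays "unclassified"; the marker-negative class
    is reserved for externally supplied masks of marker-negative cells.
    """
    if rois.n_rois == 0:
        raise ValueError("cannot classify an empty ROI set")
    near_vessel = None
    if vessel_map is not None:
        near_vessel = np.asarray(vessel_map, dtype=bool)
        for _ in range(vessel_margin):
            g = near_vessel.copy()
            g[:-1] |= near_vessel[1:]; g[1:] |= near_vessel[:-1]
            g[:, :-1] |= near_vessel[:, 1:]; g[:, 1:] |= near_vessel[:, :-1]
            near_vessel = g
    else:
        log.info("no vessel map supplied: endfoot class unavailable")

    classes: list[str] = []
    for p in regionprops(rois.label_image):
        m = rois.label_image == p.label
        if near_vessel is not None and \
                (m & near_vessel).sum() >= vessel_fraction * m.sum():
            classes.append("endfoot")
        elif p.area >= soma_min_area and p.solidity >= soma_min_solidity:
            classes.append("soma")
        elif p.eccentricity >= process_min_eccentricity or \
                (p.area / max(p.equivalent_diameter_area, 1e-9) > 4
                 and p.solidity < 0.6):
            classes.append("process")
        else:
            classes.append("unclassified")
    rois.compartments = classes
    return rois


def extract_traces(denoised: np.ndarray, rois: ROISet) -> np.ndarray:
    """Per-ROI mean denoised ΔF/F₀ traces, (n_rois, n_frames), label order."""
    denoised = np.asarray(denoised, dtype=np.float64)
    if denoised.ndim != 3 or denoised.shape[1:] != rois.label_image.shape:
        raise ValueError("denoised movie and ROI label image shapes differ")
    T = denoised.shape[0]
    flat = denoised.reshape(T, -1)
    lab = rois.label_image.reshape(-1)
    traces = np.empty((rois.n_rois, T))
    for i in range(1, rois.n_rois + 1):
        idx = np.flatnonzero(lab == i)
        if idx.size == 0:
            raise ValueError(f"ROI {i} is empty")
        traces[i - 1] = flat[:, idx].mean(axis=1)
    return traces


def bulk_trace(movie: np.ndarray, mask: np.ndarray,
               prestimulus_frames: int | tuple[int, int] = 10) -> np.ndarray:
    """Bulk ΔF/F₀ trace of a region (e.g. microprobe field).

    Mean fluorescence over the mask per frame, expressed relative to the
    mean of a pre-stimulus window (first ``prestimulus_frames`` frames,
    or an explicit (start, end) frame window).
    """
    movie = np.asarray(movie, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    raw = movie[:, mask].mean(axis=1)
    if isinstance(prestimulus_frames, tuple):
        s, e = prestimulus_frames
    else:
        s, e = 0, int(prestimulus_frames)
    if e <= s or e > len(raw):
        raise ValueError("pre-stimulus window empty or out of range")
    f0 = raw[s:e].mean()
    if f0 == 0:
        raise ValueError("pre-stimulus baseline is zero")
    return (raw - f0) / f0
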