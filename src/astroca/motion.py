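"""Lateral motion correction for two-channel movies.

Motion is estimated on the structural (marker) channel — which carries
no activity-driven intensity changes — and the identical geometric
transform is applied to both channels.  Correction is sequential:

1. rigid-body shifts by FFT phase cross-correlation against a temporal
   median template, with subpixel refinement;
2. dense residual motion by combined local-global (CLG) optical flow:
   a Lucas–Kanade-style structure-tensor data term combined with a
   Horn–Schunck-style global smoothness term, solved by fixed-point
   (Jacobi) iteration on a coarse-to-fine pyramid.

Displacements use the moving → fixed convention throughout:
``corrected(p) = moving(p + u(p))``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

from astroca.core import MotionField, TwoChannelMovie

__all__ = [
    "estimate_rigid_shifts",
    "estimate_clg_flow",
    "apply_correction",
    "estimate_motion",
    "correct_movie",
]


def _resolve_reference(stack: np.ndarray, reference: int | str) -> np.ndarray:
    if isinstance(reference, str):
        if reference != "template":
            raise ValueError("reference must be a frame index or 'template'")
        return np.median(stack, axis=0)
    return stack[int(reference)]


def estimate_rigid_shifts(structural: np.ndarray,
                          reference: int | str = "template",
                          upsample_factor: int = 10) -> np.ndarray:
    """Per-frame rigid (dy, dx) shifts against a reference frame.

    The reference defaults to the temporal median frame, which is robust
    to transient brightness changes.  Returned shifts satisfy
    ``corrected(p) = frame(p + shift)``; the reference frame itself gets
    (0, 0).  Constant frames produce zero shifts with a warning.

    Parameters
    ----------
    structural : ndarray, (n_frames, H, W)
    upsample_factor : int
        Subpixel refinement factor for phase cross-correlation
        (1 = integer-pixel).
    """
    structural = np.asarray(structural, dtype=np.float64)
    if structural.ndim != 3 or structural.shape[0] < 2:
        raise ValueError("need a stack with >= 2 frames")
    ref = _resolve_reference(structural, reference)
    shifts = np.zeros((structural.shape[0], 2))
    if ref.std() == 0:
        warnings.warn("constant reference frame: returning zero shifts",
                      stacklevel=2)
        return shifts
    for t, frame in enumerate(structural):
        if frame.std() == 0:
            warnings.warn(f"constant frame {t}: shift undefined, set to 0",
                          stacklevel=2)
            continue
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None)
        # phase_cross_correlation returns the shift registering the frame
        # onto the reference under scipy.ndimage.shift; our sampling
        # convention is its negative
        shifts[t] = -shift
    return shifts


# --------------------------------------------------------------------------
# CLG optical flow
# --------------------------------------------------------------------------

def _clg_level(fixed: np.ndarray, moving: np.ndarray, u: np.ndarray,
               regularization: float, n_iter: int, n_warp: int,
               rho: float) -> np.ndarray:
    """Run CLG fixed-point iterations at one pyramid level, warm-started."""
    h, w = fixed.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    alpha = regularization
    for _ in range(n_warp):
        coords = np.stack([yy + u[0], xx + u[1]])
        warped = map_coordinates(moving, coords, order=1, mode="nearest")
        iy, ix = np.gradient(warped)
        it = warped - fixed
        # Gaussian-smoothed structure tensor of (ix, iy, it)
        j11 = gaussian_filter(ix * ix, rho)
        j12 = gaussian_filter(ix * iy, rho)
        j22 = gaussian_filter(iy * iy, rho)
        j13 = gaussian_filter(ix * it, rho)
        j23 = gaussian_filter(iy * it, rho)

        dv = np.zeros_like(u[0])   # increment along y
        du = np.zeros_like(u[1])   # increment along x
        det = (alpha + j11) * (alpha + j22) - j12 * j12
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        for _ in range(n_iter):
            du_bar = _neighbor_mean(du)
            dv_bar = _neighbor_mean(dv)
            # joint 2x2 solve per pixel (Jacobi on the coupled system)
            bu = alpha * du_bar - j13
            bv = alpha * dv_bar - j23
            du = (bu * (alpha + j22) - j12 * bv) / det
            dv = ((alpha + j11) * bv - j12 * bu) / det
        u = u + np.stack([dv, du])
    return u


def _neighbor_mean(a: np.ndarray) -> np.ndarray:
    """4-neighbour mean with edge replication (discrete Laplacian stencil)."""
    p = np.pad(a, 1, mode="edge")
    return 0.25 * (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:])


def estimate_clg_flow(fixed: np.ndarray, moving: np.ndarray,
                      regularization: float = 0.02, n_iter: int = 60,
                      pyramid_levels: int = 3, n_warp: int = 2,
                      rho: float = 3.0) -> np.ndarray:
    """Dense displacement field aligning ``moving`` onto ``fixed``.

    Minimizes the CLG energy: a local structure-tensor data term
    (gradients and temporal difference smoothed over a Gaussian window
    of scale ``rho``) plus ``regularization`` × a global first-order
    smoothness term, by Jacobi fixed-point iteration coarse-to-fine.

    Returns ``u`` with shape (2, H, W) such that
    ``moving(p + u(p)) ≈ fixed(p)``; (u[0], u[1]) = (dy, dx).
    Intensities are standardized internally, so ``regularization`` is
    scale-free.

    Zero-variance inputs yield a zero field with a warning.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape or fixed.ndim != 2:
        raise ValueError("fixed and moving must be 2-D frames of equal shape")
    if regularization <= 0:
        raise ValueError("regularization must be > 0")
    if fixed.std() == 0 or moving.std() == 0:
        warnings.warn("zero-variance frame: returning zero flow", stacklevel=2)
        return np.zeros((2,) + fixed.shape)

    mu, sd = fixed.mean(), fixed.std()
    fixed = (fixed - mu) / sd
    moving = (moving - mu) / sd

    # coarse-to-fine pyramid
    pyr_f, pyr_m = [fixed], [moving]
    for _ in range(pyramid_levels - 1):
        prev = pyr_f[-1]
        if min(prev.shape) < 16:
            break
        shape = (prev.shape[0] // 2, prev.shape[1] // 2)
        pyr_f.append(resize(pyr_f[-1], shape, anti_aliasing=True))
        pyr_m.append(resize(pyr_m[-1], shape, anti_aliasing=True))

    u = np.zeros((2,) + pyr_f[-1].shape)
    for lvl in range(len(pyr_f) - 1, -1, -1):
        f, m = pyr_f[lvl], pyr_m[lvl]
        if u.shape[1:] != f.shape:
            scale_y = f.shape[0] / u.shape[1]
            scale_x = f.shape[1] / u.shape[2]
            u = np.stack([resize(u[0], f.shape) * scale_y,
                          resize(u[1], f.shape) * scale_x])
        u = _clg_level(f, m, u, regularization, n_iter, n_warp, rho)
    return u


# --------------------------------------------------------------------------
# applying motion
# --------------------------------------------------------------------------

def _warp_by(frame: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([yy + displacement[0], xx + displacement[1]])
    # bilinear with edge replication: no zero borders to bias thresholds
    return map_coordinates(frame, coords, order=1, mode="nearest")


def apply_correction(movie: TwoChannelMovie, motion: MotionField
                     ) -> TwoChannelMovie:
    """Resample both channels through the estimated motion.

    Each output pixel p takes the input value at p + rigid + flow
    (bilinear, edges replicated), so both channels receive the identical
    geometric transform.  Output shape equals input shape.
    """
    if motion.n_frames != movie.n_frames:
        raise ValueError("motion field and movie disagree on n_frames")
    if motion.flow_fields is not None and \
            motion.flow_fields.shape[2:] != movie.frame_shape:
        raise ValueError("flow field shape does not match the movie")
    func = np.empty_like(movie.functional)
    struct = np.empty_like(movie.structural)
    for t in range(movie.n_frames):
        d = motion.total_displacement(t, movie.frame_shape)
        func[t] = _warp_by(movie.functional[t], d)
        struct[t] = _warp_by(movie.structural[t], d)
    return TwoChannelMovie(functional=func, structural=struct,
                           frame_interval=movie.frame_interval,
                           pixel_size=movie.pixel_size)


def estimate_motion(movie: TwoChannelMovie,
                    reference: int | str = "template",
                    upsample_factor: int = 10,
                    clg: bool = True,
                    regularization: float = 0.02,
                    n_iter: int = 60,
                    pyramid_levels: int = 3) -> MotionField:
    """Full two-stage motion estimate from the structural channel.

    Rigid shifts are estimated first and compensated; residual dense
    motion is then estimated per frame by CLG flow against the temporal
    median of the rigid-corrected structural channel.
    """
    struct = movie.structural
    shifts = estimate_rigid_shifts(struct, reference, upsample_factor)
    rigid_corrected = np.stack([
        _warp_by(struct[t], np.broadcast_to(
            shifts[t][:, None, None], (2,) + movie.frame_shape))
        for t in range(movie.n_frames)])
    flows = None
    if clg:
        template = _resolve_reference(rigid_corrected, reference)
        flows = np.empty((movie.n_frames, 2) + movie.frame_shape)
        for t in range(movie.n_frames):
            flows[t] = estimate_clg_flow(
                template, rigid_corrected[t], regularization=regularization,
                n_iter=n_iter, pyramid_levels=pyramid_levels)
    return MotionField(rigid_shifts=shifts, flow_fields=flows,
                       reference_frame=reference)


def correct_movie(movie: TwoChannelMovie, **kwargs
                  ) -> tuple[TwoChannelMovie, MotionField]:
    """Estimate motion on the structural channel and correct both channels."""
    motion = estimate_motion(movie, **kwargs)
    return apply_correction(movie, motion), motion
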