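"""Time-varying baseline F₀(t) estimation and ΔF/F₀.

The baseline is estimated in two stages.  First, low-rank slow trends
are extracted by projecting the movie — reshaped to a (Nf × Npx) matrix
``F`` with one unraveled frame per row — onto a truncated singular
value decomposition F = UΣV*, where columns of V are spatial principal
components and columns of U the corresponding temporal signals.  The
leading temporal signals are cleaned of short transient upswings by
asymmetric iteratively-reweighted least-squares (IRLS) smoothing before
the truncated projection back into image space (first r components,
default r = 20).  Second, small local deviations from the low-rank
dynamics are corrected by temporal smoothing of spatially averaged
residuals in small overlapping windows, blended with partition-of-unity
weights.

ΔF/F₀ = (F − F₀) / max(F₀, floor), with the floor keeping dark pixels
finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve


@dataclass
class FluorescenceMatrix:
    """Movie as a (Nf × Npx) matrix plus its truncated SVD factors."""

    F: np.ndarray
    U: np.ndarray | None = None
    s: np.ndarray | None = None
    Vt: np.ndarray | None = None
    r: int | None = None

    @classmethod
    def from_stack(cls, stack: np.ndarray) -> "FluorescenceMatrix":
        stack = np.asarray(stack, dtype=np.float64)
        return cls(F=stack.reshape(stack.shape[0], -1))

    def decompose(self, r: int) -> None:
        nf, npx = self.F.shape
        if not 1 <= r <= min(nf, npx):
            raise ValueError("rank r must satisfy 1 <= r <= min(Nf, Npx)")
        if min(nf, npx) <= 512:
            u, s, vt = np.linalg.svd(self.F, full_matrices=False)
        else:
            from sklearn.utils.extmath import randomized_svd
            u, s, vt = randomized_svd(self.F, n_components=min(r + 10,
                                                               min(nf, npx)),
                                      random_state=0)
        self.U, self.s, self.Vt, self.r = u[:, :r], s[:r], vt[:r], r


def _second_diff(n: int) -> sparse.csc_matrix:
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    return d.tocsc()


def irls_smooth(signal: np.ndarray, n_iter: int = 10, p: float = 0.1,
                lam: float | None = None) -> np.ndarray:
    """Asymmetric IRLS smoothing of a temporal trace.

    Penalized (second-difference) least squares with iteratively
    reweighted asymmetric weights: residuals above the fit get weight
    ``p``, residuals below get ``1 − p``, so short positive excursions
    (transient upswings) are ignored while the slow component — and any
    exactly linear trend, which lies in the penalty's null space — is
    preserved.

    Parameters
    ----------
    lam : float, optional
        Smoothness penalty; defaults to ``(n/20)**4``, which passes
        full-trace-scale oscillations while flattening features shorter
        than a few percent of the trace.
    """
    y = np.asarray(signal, dtype=np.float64)
    if y.ndim != 1 or len(y) < 5:
        raise ValueError("signal must be 1-D with length >= 5")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite samples")
    if not 0 < p < 1:
        raise ValueError("asymmetry p must be in (0, 1)")
    n_orig = len(y)
    if lam is None:
        lam = (n_orig / 20.0) ** 4
    # odd-reflection padding continues the end slopes, avoiding the
    # flattening the penalty's natural boundary conditions would impose
    pad = min(n_orig - 1, max(int(4 * lam ** 0.25), 2))
    y = np.pad(y, pad, mode="reflect", reflect_type="odd")
    n = len(y)
    d = _second_diff(n)
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        a = sparse.diags(w) + penalty
        z = spsolve(a.tocsc(), w * y)
        resid = y - z
        # margin at the scale of the below-fit residuals: smooth signals
        # (residuals symmetric, noise-sized) keep symmetric weights, while
        # genuine upswings stand clear of the margin and are down-weighted
        neg = resid[resid < 0]
        margin = float(np.std(neg)) if neg.size else 0.0
        w = np.where(resid > margin, p, 1.0 - p)
    return z[pad:pad + n_orig]


def _align_component_sign(u: np.ndarray, v: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Flip (u, v) so positive-intensity transients appear as upswings in u."""
    resid = u - np.median(u)
    skew = np.mean(resid ** 3)
    if skew < 0:
        return -u, -v
    return u, v


def _robust_noise_sd(F: np.ndarray) -> float:
    """Movie-level noise SD from median absolute temporal differences."""
    d = np.abs(np.diff(F, axis=0))
    return float(1.4826 * np.median(d) / np.sqrt(2))


def lowrank_trend(fm: FluorescenceMatrix | np.ndarray, r: int = 20,
                  irls_iter: int = 10, irls_p: float = 0.1,
                  irls_lam: float | None = None, n_outer: int = 3,
                  active_dilation: int = 4) -> np.ndarray:
    """Rank-r slow trend of the fluorescence matrix.

    The first ``r`` temporal components are IRLS-smoothed (upswing
    rejection) and the truncated product ŨΣV* is returned; its matrix
    rank is ≤ r by construction.  Because one SVD component can mix
    transients of several ROIs with opposite spatial signs, the
    reweighting is also applied at the matrix level: samples more than
    two robust noise SDs above the current trend are replaced by the
    trend and the decomposition repeated (``n_outer`` passes), so
    transient upswings cannot tilt the slow components.  A constant
    matrix is returned unchanged.
    """
    if not isinstance(fm, FluorescenceMatrix):
        fm = FluorescenceMatrix(F=np.asarray(fm, dtype=np.float64))
    if r < 1:
        raise ValueError("rank r must be >= 1")
    if fm.F.std() == 0:
        return fm.F.copy()
    noise_sd = _robust_noise_sd(fm.F)
    work = fm
    trend = None
    for outer in range(max(n_outer, 1)):
        if work.r != r or work.U is None:
            work.decompose(r)
        # components whose singular value sits inside the random-matrix
        # noise bulk carry no trend signal; dropping them removes most of
        # the rank-r noise capture (output rank stays <= r)
        nf, npx = work.F.shape
        edge = 1.05 * noise_sd * (np.sqrt(nf) + np.sqrt(npx))
        keep = max(int(np.sum(work.s > edge)), 1)
        u_smooth = np.zeros_like(work.U)
        vt = work.Vt.copy()
        for k in range(keep):
            uk, vk = _align_component_sign(work.U[:, k], vt[k])
            vt[k] = vk
            u_smooth[:, k] = irls_smooth(uk, n_iter=irls_iter, p=irls_p,
                                         lam=irls_lam)
        trend = (u_smooth * work.s) @ vt
        if outer < n_outer - 1:
            active = fm.F - trend > 2.0 * noise_sd
            if active_dilation > 0:
                # grow the mask in time so sub-threshold transient tails
                # do not anchor the interpolation
                from scipy.ndimage import binary_dilation
                active = binary_dilation(
                    active, np.ones((2 * active_dilation + 1, 1), bool))
            work = FluorescenceMatrix(F=_inpaint_active(fm.F, active))
    return trend


def _inpaint_active(F: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Replace flagged samples by temporal interpolation of quiet frames.

    Interpolating across an event (rather than substituting the current
    trend) removes the event's elevation from the matrix entirely, so
    the reweighted decomposition converges to the quiet-period baseline
    instead of a fixed point part-way up the transients.
    """
    out = F.copy()
    t = np.arange(F.shape[0])
    cols = np.flatnonzero(active.any(axis=0))
    for j in cols:
        quiet = ~active[:, j]
        if quiet.sum() < 2:
            continue
        out[active[:, j], j] = np.interp(t[active[:, j]], t[quiet],
                                         F[quiet, j])
    return out


@dataclass
class BaselineEstimate:
    """Per-pixel time-varying baseline F₀(t)."""

    F0: np.ndarray                       # (T, H, W)
    components_used: int
    local_window: tuple[int, int]        # (frames, pixels)


def _bump(n: int) -> np.ndarray:
    """Strictly positive triangular blending profile of length n."""
    x = (np.arange(n) + 0.5) / n
    return 1.0 - np.abs(2 * x - 1) * (1 - 1e-3) + 1e-3


def _window_starts(extent: int, size: int, stride: int) -> list[int]:
    starts = list(range(0, max(extent - size, 0) + 1, stride))
    if starts[-1] != extent - size:
        starts.append(max(extent - size, 0))
    return sorted(set(starts))


def local_correction(residual: np.ndarray, trend: np.ndarray,
                     window: tuple[int, int] = (30, 16),
                     irls_p: float = 0.1) -> BaselineEstimate:
    """Correct the trend with windowed local baseline deviations.

    The residual movie is spatially averaged in overlapping windows
    (``window`` = frames × pixels, 50% overlap), each average trace is
    asymmetrically smoothed, and the smoothed local offsets are blended
    back onto the trend with weights normalized to unity everywhere.
    """
    residual = np.asarray(residual, dtype=np.float64)
    trend = np.asarray(trend, dtype=np.float64)
    if residual.shape != trend.shape or residual.ndim != 3:
        raise ValueError("residual and trend must be (T, H, W) of equal shape")
    t_win, s_win = window
    T, h, w = residual.shape
    if not (1 <= t_win <= T and 1 <= s_win <= min(h, w)):
        raise ValueError("window larger than movie")

    # upswing rejection at the sample level: positive residual excursions
    # are transients, not baseline, so winsorize them before averaging
    sd = _robust_noise_sd(residual.reshape(T, -1))
    residual = np.minimum(residual, 2.0 * sd)

    corr = np.zeros_like(residual)
    wsum = np.zeros_like(residual)
    t_starts = _window_starts(T, t_win, max(t_win // 2, 1))
    y_starts = _window_starts(h, s_win, max(s_win // 2, 1))
    x_starts = _window_starts(w, s_win, max(s_win // 2, 1))
    bt, bs = _bump(t_win), _bump(s_win)
    for t0 in t_starts:
        for y0 in y_starts:
            for x0 in x_starts:
                block = residual[t0:t0 + t_win, y0:y0 + s_win, x0:x0 + s_win]
                trace = block.mean(axis=(1, 2))
                if t_win >= 5:
                    trace = irls_smooth(trace, n_iter=5, p=irls_p,
                                        lam=(t_win / 2.0) ** 4)
                wgt = (bt[:, None, None] * bs[None, :, None]
                       * bs[None, None, :])
                corr[t0:t0 + t_win, y0:y0 + s_win, x0:x0 + s_win] += \
                    wgt * trace[:, None, None]
                wsum[t0:t0 + t_win, y0:y0 + s_win, x0:x0 + s_win] += wgt
    corr /= wsum
    f0 = trend + corr
    return BaselineEstimate(F0=f0, components_used=-1,
                            local_window=(t_win, s_win))


@dataclass
class DeltaFOverF:
    """ΔF/F₀ stack with the floor policy that produced it."""

    dff: np.ndarray
    floor: float


def compute_dff(movie: np.ndarray, f0: BaselineEstimate | np.ndarray,
                floor: float | None = None) -> DeltaFOverF:
    """ΔF/F₀ = (F − F₀) / max(F₀, floor).

    ``floor`` defaults to 1% of the movie's global mean, keeping ΔF/F₀
    finite in dark regions.
    """
    movie = np.asarray(movie, dtype=np.float64)
    f0_arr = f0.F0 if isinstance(f0, BaselineEstimate) else np.asarray(f0)
    if movie.shape != f0_arr.shape:
        raise ValueError("movie and F0 shapes differ")
    if floor is None:
        floor = 0.01 * float(movie.mean())
    if floor <= 0:
        raise ValueError("floor must be > 0")
    denom = np.maximum(f0_arr, floor)
    return DeltaFOverF(dff=(movie - f0_arr) / denom, floor=floor)


def estimate_baseline(stack: np.ndarray, r: int = 20,
                      window: tuple[int, int] = (30, 16),
                      irls_iter: int = 10, irls_p: float = 0.1,
                      floor_fraction: float = 0.01) -> BaselineEstimate:
    """Two-stage F₀(t) estimate for a movie stack (T, H, W)."""
    stack = np.asarray(stack, dtype=np.float64)
    T, h, w = stack.shape
    fm = FluorescenceMatrix.from_stack(stack)
    r_eff = min(r, T, h * w)
    trend = lowrank_trend(fm, r=r_eff, irls_iter=irls_iter, irls_p=irls_p)
    trend_stack = trend.reshape(T, h, w)
    residual = stack - trend_stack
    est = local_correction(residual, trend_stack, window=window,
                           irls_p=irls_p)
    floor = floor_fraction * float(stack.mean())
    est.F0 = np.maximum(est.F0, floor)
    est.components_used = r_eff
    return est
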