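# Methods

This note documents the models, parameter choices, and numerical
decisions behind `astroca`, and what the synthetic benchmarks do and do
not establish about real data.

## Synthetic data model

The generator is the package's source of ground truth; its defaults are
the conditions under which the test suite and `scripts/acceptance.py`
characterize the pipeline.

**Movies.** A 128 × 128 field of view, 300 frames at 0.5 s per frame.
ROIs are painted as somas (filled ellipses, semi-axes 4–8 px),
processes (random-heading curved polylines ~20–35 px long, dilated to
2–3 px width) and perivascular endfeet (annular arcs hugging one side
of a smooth synthetic vessel path), mutually separated by a 2 px moat
so each planted ROI is one contiguous region distinct from its
neighbours. The functional channel is

    F(t, p) = B(t, p) · (1 + Σᵢ sᵢ(t) · 1[p ∈ ROIᵢ]) + ε(t, p)

where the baseline movie `B = base_image × (1 + drift)` carries a
rank-3 multiplicative drift (smooth temporal ramps/sinusoids × smooth
spatial maps, ±10% of baseline), so the low-rank-trend assumption of
the baseline stage is true by construction. Transients sᵢ are Poisson
events (1.5 min⁻¹ per ROI) with difference-of-exponentials kinetics
(rise 1 s, decay 4 s — generic indicator-like values; the source
experiments publish no kinetics distributions, so these are stated
conditions, not claims about astrocytes) and multiplicative ΔF/F₀
amplitude 0.5. Motion is a smoothed rigid random walk (amplitude 2 px)
plus a low-spatial-frequency sinusoidal non-rigid field (1 px); frame 0
is the motion reference. Noise is Gaussian with constant SD (default 5
intensity units against ROI baselines of ~90) so the noise ground truth
is exact; a Poisson mode exists for shot-noise realism but the Gaussian
default keeps detector calibration checks sharp.

**Event support / "active time" ground truth.** An event is counted as
ongoing while its waveform exceeds 10% of peak amplitude
(`support_fraction = 0.1`), i.e. rise plus ≈ 2.3 decay constants — the
full visible extent of an indicator transient. This definition matters
because the detection rule thresholds at 2 SD of the noise *of the
denoised trace*: its effective support level scales with the residual
noise, matching the 10% definition at amplitude ≈ 3 × raw noise SD (the
regime in which the ±5-percentage-point active-time recovery holds).
At much higher SNR the 2-SD rule flags proportionally longer stretches
of the decay tail and active time reads high against any fixed
ground-truth definition; this is a property of noise-relative
thresholds, not an implementation artifact.

**Physiology.** ICP is a smoothed 12 mmHg step (the experimental
10–15 mmHg range) held for 5 min; MAP rises by 20 mmHg starting 30 s
after ICP onset (rise constant 5 s), matching the reported ~21 mmHg /
~32 s responses, and decays after stimulus offset with a 120 s time
constant (a desk-scale stand-in — the in-vivo response outlasts the
stimulus by tens of minutes). The arterial waveform adds a pulse at
the instantaneous heart rate (360 bpm baseline, +25 bpm response);
raw RSNA is zero-mean noise amplitude-modulated by the MAP response
(2% of resting per mmHg).

## Motion correction

Rigid shifts come from FFT phase cross-correlation against the
temporal-median structural frame (robust to transients), with 10×
upsampled subpixel refinement. Residual motion is estimated per frame
by combined local-global (CLG) optical flow: the data term is the
Gaussian-smoothed (ρ = 3 px) structure tensor of the spatial gradients
and temporal difference, the regularizer is first-order (Horn–Schunck)
smoothness with weight α = 0.02 on intensity-standardized frames, and
the coupled per-pixel 2×2 systems are solved by Jacobi fixed-point
iteration (60 iterations, 2 warp cycles) on a 3-level coarse-to-fine
pyramid. The paper trail for this algorithm family fixes none of these
constants; all are exposed as configuration. Displacements use one
convention everywhere: (row, col) = (y, x), field maps moving → fixed,
`corrected(p) = moving(p + u(p))`. Resampling is bilinear with edge
replication (no zero borders to bias the block thresholds downstream),
and both channels receive the identical transform, driven by the
structural channel only.

Measured on planted motion: mean endpoint error ≈ 0.22 px at the
default amplitudes, second-pass residuals < 0.15 px.

## Baseline estimation

Stage one reshapes the movie to F (Nf × Npx) and computes a truncated
SVD (exact LAPACK when min(Nf, Npx) ≤ 512, randomized otherwise; the
two agree to ~1e-6 at test sizes). The first r = 20 temporal components
are smoothed by asymmetric IRLS and the trend rebuilt as ŨΣV*, so the
output rank never exceeds 20. Three refinements proved necessary and
are part of the package's design:

* **Matrix-level reweighting.** One SVD component can mix transients of
  several ROIs with opposite spatial signs, which per-component upswing
  rejection cannot fix. The estimate therefore iterates (3 passes):
  samples more than 2 robust noise SDs above the current trend — with
  the active mask dilated ±4 frames to catch sub-threshold decay
  tails — are replaced by temporal interpolation from quiet frames
  before the next decomposition. Interpolation (rather than
  substituting the trend itself) removes the events' elevation
  entirely, so the iteration converges to the quiet-period baseline.
* **Noise-floor cut.** Components whose singular value lies inside the
  random-matrix noise bulk (below 1.05 · σ̂(√Nf + √Npx), with σ̂ from
  median absolute temporal differences) carry no trend and are dropped;
  this removes most of the rank-20 noise capture while respecting the
  r = 20 cap.
* **IRLS details.** Whittaker smoothing with a second-difference
  penalty (λ = (n/20)⁴ by default, scale-free in trace length), 10
  reweighting iterations with weight p = 0.1 above the fit and 1 − p
  below, applied only to residuals exceeding the spread of the
  below-fit residuals (so smooth signals are not biased toward their
  lower envelope), and odd-reflection end padding (natural boundary
  conditions otherwise flatten end slopes; a rank-1 identity check
  fails at 4% without it, passes at < 2% with it).

Stage two corrects local deviations: the residual movie is winsorized
upward at +2σ̂ (positive excursions are transients, not baseline),
spatially averaged in overlapping 30-frame × 16 × 16 px windows (50%
overlap), each window trace is asymmetrically smoothed, and the
offsets are blended with strictly positive triangular weights
normalized to unity everywhere. ΔF/F₀ uses a floor of 1% of the global
mean to stay finite in dark corners.

Measured: F₀ RMSE ≈ 0.35–0.45 × noise SD on default movies (planted
rank-3 drift + transients + noise).

## Selective averaging and detection

Windows are 16 × 16 px with stride 8 (clamped at borders so coverage is
complete). Per window, pixel traces are projected onto the first 5
principal components (patch SVD) and clustered by k-means with k = 3
and a fixed seed; the cluster containing the center pixel is averaged,
and the average is accumulated into its member pixels with weight
w = 1/(ε + d), ε = 1e-6, d = Euclidean distance to the cluster centroid
in PC space. Aggregation divides by the accumulated weights, making
each pixel's final trace a convex combination of its window estimates;
pixels never selected by any cluster (rare, borders) keep their raw
trace. Noise SD per trace is 1.4826 · median|Δtrace|/√2 — insensitive
to slow trends (differencing) and sparse transients (median).
Detection thresholds the Gaussian-smoothed trace (FWHM 3 frames) at
2 × noise SD, then trims each detected run to its first and last
*unsmoothed* threshold crossing, so the smoothing kernel does not pad
event durations (≈ +6 percentage points of active time otherwise);
interior single-frame dips remain part of the event. The movie-level
transient mask additionally requires the unsmoothed trace to exceed
threshold at each flagged pixel-frame.

## ROI segmentation and classification

Per-frame foreground is pixel > sliding 11 × 11 local mean +
contrast_floor (default 5 intensity units; the sliding mean was chosen
over median/Gaussian variants and is configurable). The persistence map
(fraction of frames foreground) is thresholded strictly above 0.5 —
a region foreground in exactly half the frames is background — then
labeled with 8-connectivity and filtered at ≥ 6 px. Classification is a
heuristic (the original automated criteria are unpublished): endfoot if
≥ 50% of the ROI lies within 3 px of the vessel mask; else soma if
area ≥ 40 px and solidity ≥ 0.85; else process if eccentricity ≥ 0.93
or elongated-and-sparse; the marker-negative class is reserved for
externally supplied masks. Segmentation is invariant to affine
intensity rescaling when contrast_floor is scaled accordingly.

## Event statistics

Events are maximal runs of the activity vector, discarding runs shorter
than 2 frames. Active time = 100 × active frames / frames; frequency
counts event onsets inside an epoch per minute; epochs default to
baseline = pre-onset window of stimulus length, stimulus, and post =
equal window after offset. Responder rule (the source experiments never
define theirs, so this default is ours): a stimulus-epoch frequency
increase of ≥ 20% *and* a one-sided binomial test on event counts
(stimulus share of events vs share of duration, α = 0.05). A
frequency-and-duration rule was tried first and rejected: with
fixed-kinetics generator events, duration carries no rate information,
giving 10.5% false positives and 41% sensitivity at rate doubling; the
count-test rule measures 3–4% false positives and ~60% sensitivity at
doubling with 15-minute epochs. Peri-stimulus averages linearly resample
each trace to a common axis with t = 0 at its alignment time; SEM uses
the n − 1 standard deviation; traces not covering the window are
excluded with a warning.

## Physiology

CPP = MAP − ICP (CVP is listed in the experimental diagrams but the
operative definition subtracts ICP only; an optional `cvp` argument
subtracts max(ICP, CVP)). MAP is a 2 s sliding mean of the arterial
waveform; HR comes from systolic peaks (refractory period 0.25 × median
interbeat interval) interpolated to the full axis; a pulseless wave
yields NaN HR with a warning. RSNA is full-wave rectified and smoothed
by an exact discrete first-order lag, y[n] = a·y[n−1] + (1−a)·x[n] with
a = exp(−1/(τ·fs)), τ = 100 ms; normalization is affine between the
blockade floor (0%) and resting level (100%). Response onset is the
first sustained crossing of baseline mean + 2 SD; "sustained" defaults
to one second of samples — smoothed hemodynamic noise is strongly
autocorrelated, so a fixed small sample count (e.g. 5 samples at
100 Hz) triggers on noise bumps and under-reports the delay by tens of
seconds. Post-stimulus persistence is reported as the 1/e decay time of
the MAP elevation from its offset-time level, which recovers a planted
exponential release constant directly; deltas are epoch-mean
differences, with the peak MAP delta also reported (the epoch mean is
systematically below the plateau by the delay + rise fraction of the
epoch, ~12% at defaults).

## Pipeline and reproducibility

The orchestrator runs motion → baseline → detection → segmentation →
statistics, writing every intermediate plus a manifest of SHA-256
checksums. One pipeline seed fans out to per-stage seeds by SHA-256
hashing (all < 2³¹), so stages are individually reproducible; motion
fields are stored as `.npy` (zip-based archives embed timestamps and
would break bit-identical manifests). Two runs with the same config and
seed produce byte-identical statistics tables and manifests.

## Problem sizes and what the tests show

The benchmarks run at 128 × 128 × 300 (motion, baseline, segmentation,
SNR-2 detection) and 64 × 64 × 300 (statistics recovery), with
60-minute single traces for rate estimation and 150–200 draws for
Monte-Carlo null rates — sizes chosen so the full characterization runs
in minutes on one CPU while keeping every per-stage estimate
well-conditioned. Passing them shows the chain recovers what the
generator planted under the stated conditions; it does not certify
performance on real movies, whose noise is signal-dependent, whose
motion includes z-drift the model omits, whose baselines bleach
non-multiplicatively, and whose ROIs overlap in depth. The generator
deliberately omits those effects; they are the main known limitations,
along with the heuristic compartment classifier and the invented
responder rule above.
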