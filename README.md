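# astroca

Analysis pipeline for two-photon astrocyte Ca²⁺ imaging recorded during
cerebral-perfusion challenges, together with the accompanying
hemodynamic and sympathetic-nerve signal processing.

Astrocytes respond to falling cerebral perfusion pressure
(CPP = MAP − ICP, mean arterial pressure minus intracranial pressure)
with increases in the frequency and duration of intracellular Ca²⁺
transients in their somas, major processes and perivascular endfeet,
while the cardiovascular system mounts a delayed sympathetic pressor
response. Quantifying either side of that experiment takes a long chain
of signal processing; `astroca` implements that chain as a tested,
reusable library for imaging labs working with a Ca²⁺-indicator
(functional) channel plus an astrocyte-marker (structural) channel such
as OGB + SR101:

1. **Motion correction** — rigid shifts by FFT phase cross-correlation
   against a temporal-median template, then dense residual motion by
   combined local-global (CLG) optical flow (structure-tensor data term
   + Horn–Schunck smoothness, coarse-to-fine), estimated on the
   structural channel and applied to both channels.
2. **Time-varying baseline** — F₀(t) per pixel from a truncated SVD
   F = UΣV* of the (frames × pixels) movie matrix: the leading temporal
   components are cleaned of transient upswings by asymmetric
   iteratively-reweighted least squares and projected back with the
   first r = 20 components; small local deviations are corrected in
   overlapping windows. ΔF/F₀ = (F − F₀)/max(F₀, floor).
3. **Selective averaging & detection** — in a moving window, ΔF/F₀
   traces are projected onto the first few principal components and
   clustered; the cluster containing the window's center pixel is
   averaged and accumulated with inverse-distance weights; transients
   are detected where the temporally smoothed trace exceeds 2 standard
   deviations of its noise.
4. **ROI segmentation** — adaptive thresholding in 11 × 11 pixel blocks
   per structural frame, keeping contiguous regions that are foreground
   in strictly more than 50% of frames; compartment classification
   (soma / process / endfoot) by shape and vessel adjacency.
5. **Event statistics** — per-ROI active time (% of time Ca²⁺ is
   elevated), event frequency (min⁻¹), duration, responder
   classification, and peri-stimulus averages (mean ± SEM) aligned to
   stimulus onset/offset.
6. **Physiology** — CPP, MAP and heart rate from the arterial waveform,
   renal sympathetic nerve activity (rectified, smoothed with a 100 ms
   time constant, normalized to resting = 100% / blockade floor = 0%),
   and stimulus-to-response delay estimation.

Because raw recordings of this kind are rarely shareable, the package
includes a first-class synthetic-data generator
(`astroca.synthetic`) that emulates the statistical structure the
analysis assumes — astrocyte-shaped ROIs, exponential-kinetics
transients, low-rank multiplicative drift, rigid + non-rigid lateral
motion, shot-like noise, and ICP step stimuli with delayed pressor/RSNA
responses — with complete ground truth, so every stage is testable.

## Worked example

```python
import numpy as np
from astroca import synthetic as syn, motion, baseline, detection, roi, events

# 128x128, 300 frames at 2 Hz; noise chosen so the planted transient
# amplitude is ~3x the DF/F noise
params = syn.SyntheticMovieParams(noise_sd=15.0, seed=42)
movie, truth = syn.generate_movie(params)

corrected, field = motion.correct_movie(movie)
est = baseline.estimate_baseline(corrected.functional, r=20)
dff = baseline.compute_dff(corrected.functional, est)
result = detection.selective_average_movie(dff.dff,
                                           detection.DetectionParams(seed=0))
rois = roi.segment_rois(corrected.structural)
rois = roi.classify_compartments(rois, vessel_map=truth.vessel_mask)
traces = roi.extract_traces(result.denoised, rois)

print(f"max rigid shift estimated: {np.abs(field.rigid_shifts).max():.2f} px")
print(f"{rois.n_rois} ROIs segmented")
for i in range(3):
    noise = detection.estimate_noise_sd(traces[i])
    act = detection.detect_transients(traces[i], noise)
    iv = events.intervals_from_mask(act, params.frame_interval)
    print(f"ROI {i+1} ({rois.compartments[i]}): {len(iv)} events, "
          f"active time {events.active_time(iv, params.n_frames):.1f}%")
```

prints (about two minutes on one CPU):

```
max rigid shift estimated: 1.80 px
24 ROIs segmented
ROI 1 (process): 11 events, active time 40.7%
ROI 2 (process): 6 events, active time 33.0%
ROI 3 (process): 5 events, active time 25.7%
```

The generator planted 2 px of rigid motion (the estimate includes the
~1 px non-rigid component absorbed by the rigid stage), 24 ROIs across
the three compartments — all recovered — and per-ROI active times that
the full chain recovers with a median error of ≈ 6 percentage points
(thin processes near the field border are the hardest, as residual
sub-pixel motion on their steep intensity edges can mimic transients).
On clean ΔF/F₀ input the detection stage alone recovers active time
within ±5 percentage points per ROI (see the acceptance metrics below).

The same stages are available from a CLI:

```bash
astroca pipeline --seed 7 --out out/          # synthetic end-to-end run
astroca simulate --seed 7 --out data/         # generator only
astroca physio rec.csv --sample-rate 100 --protocol 180,480
```

An end-to-end run writes every intermediate artifact (corrected movies,
F₀, ΔF/F₀, denoised movie, transient mask, ROI labels, traces, event
statistics) plus `manifest.json` with SHA-256 checksums; re-running
with the same seed reproduces identical files.

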