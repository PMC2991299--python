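# Methods

This note documents the models, estimators and numerical conventions behind
`pcmr`, the choices made where the method leaves room, and what the synthetic
phantoms do and do not establish about behaviour on real data.

## Data model

A phase-contrast series is a pair of image stacks over one retrospectively
ECG-gated cardiac cycle: a modulus (magnitude) stack and a velocity stack
(cm/s, signed by through-plane direction), with a frame interval (ms), an
encoding velocity `venc` (cm/s) and a pixel spacing (mm). Phase `i` is taken
at time `i × frame_interval`, with phase 0 at the R-wave. Raw phase images
decode linearly: `v = raw / raw_fullscale × venc`. Velocities at the venc
bound are possible aliases; they are counted and logged but never unwrapped
(no unwrapping convention is part of the method). Pixel coordinates are
0-based `(row, col)` with pixel centres at integer positions; ROI membership
is pixel-centre-in-shape. For DICOM input the venc must be supplied
explicitly: vendor tags are inconsistent, and a silently wrong venc rescales
every velocity — the worst possible failure mode.

## Flow segmentation

On velocity images a jet is a connected region of same-signed velocity, which
makes segmentation shape-free:

1. **Reference phase.** The mean-velocity curve inside the rough user ROI is
   computed; the phase of the highest absolute mean is the reference phase and
   the sign of that mean is the sign of the flow of interest. Ties go to the
   earliest phase; an all-zero curve is an error ("no flow detected").
2. **Initialisation.** At the reference phase, the biggest connected
   component of sign-matching pixels inside the search region becomes the
   mask.
3. **Propagation.** The mask's centre of mass is carried to the neighbouring
   phase, where the biggest same-signed component containing that point is
   selected; the new centre of mass is carried onward, towards both ends of
   the cycle.

Numerical conventions the method's description leaves open, fixed here:

* **Connectivity** is 8-neighbour. Robust to single-pixel diagonal necks in a
  jet cross-section; fixed, never configurable per run.
* **Search region** = rough ROI dilated by a disk of radius 3 px, applied at
  every phase. This tolerates jet motion across the cycle while preventing
  leakage to the other valve.
* **Minimum component size** 4 px during tracking (noise specks below the
  smallest plausible orifice at 1.9 mm pixels are ignored).
* **Propagated point**: centre of mass rounded to the nearest pixel
  (half-up). If that pixel has the wrong sign, the largest component whose
  nearest pixel lies within 2 px is accepted; if none, the phase's mask is
  empty and the previous centroid is carried forward so tracking resumes when
  the flow reappears.
* **Ties** (equal component size) go to the lexicographically smallest
  (row, col) centroid — determinism over arbitrariness.

During phases where the tracked flow does not exist (a closed valve), the
tolerance rule can latch onto noise specks or adjacent moving tissue near the
carried centroid. Those masks are physiologically meaningless and harmless:
every parameter is extracted inside the diastolic window (mitral) or from the
systolic peak (aortic), where the true flow dominates.

## Flow curves and diastolic parameters

Per phase, with the tracked sign rectified positive and `w` the in-mask
velocities: the **maximal velocity** is the mean of `{w ≥ 0.95 max(w)}` (the
"95% rule" — averaging the top band resists single-pixel noise), the **mean
velocity** is `mean(w)`, and the **flow rate** is `mean(w) × mask area`
(ml/s). Phases with an empty mask contribute 0.

Landmarks are extracted as follows:

* **End of ejection** — descending-limb extrapolation of the aortic
  flow-rate curve's systolic peak (the aortic curve is used only for timing:
  through-plane obliquity makes its magnitudes unreliable).
* **Two-peak detection** (E/A on the maximal-velocity curve, Ef/Af on the
  flow-rate curve) — among local maxima inside the diastolic window
  `[end-of-ejection, cycle end]`, the pair separated by at least one sixth of
  the cycle with the greatest summed amplitude is chosen; the earlier peak is
  the E-type one regardless of magnitude. A local maximum is a sample
  strictly greater than both neighbours (a plateau counts once, at its first
  sample). With a single admissible peak, A-dependent quantities are null.
* **Limb extrapolation** — every wave onset/offset is the time-axis root of
  a least-squares line through the limb samples with values in
  [40%, 70%] of that wave's peak, augmented by the two exact
  piecewise-linear crossings of the 40% and 70% levels. The limb is walked
  from the peak while values strictly decrease; a limb that never descends
  below 70% of the peak is an error ("limb truncated"). The 40–70% band is
  applied per wave (Ef or Af), not to the curve's global maximum.
* **Derived indices** — filling start = ascending extrapolation of the Ef
  wave; filling end = descending extrapolation of the Af wave;
  `DT = (descending extrapolation of Ef wave) − t_Ef`;
  `IVRT = filling start − end of ejection` (floored at 0 with a warning);
  `FV` = exact piecewise-linear integral of the flow-rate curve over the
  filling interval with negative samples clipped to 0 (FV is a volume of
  forward filling; noise must not subtract). When the extrapolated times and
  the raw zero crossings disagree, the extrapolated times are used.

For triangular waves sampled so that band samples lie on the limb, the
extrapolations and FV are exact — the phantom exploits this (below).

## Myocardial isolation and E′

Tissue moves up and down within one cycle, so sign-connectivity cannot track
it. Instead, each pixel of a rough ROI around the LV contributes its
full-cycle velocity time-profile; k-means with **k = 7** clusters the raw
(unnormalised) profiles under squared-Euclidean distance, seeded k-means++
with 10 restarts (best inertia wins) for reproducibility. Pixels that stay
myocardial through the cycle share the S′/E′/A′ profile and land in one
cluster; the **biggest 8-connected spatial component over all clusters** is
the myocardial mask. The rough ROI must contain less background than
myocardium: a ROI loose enough that its background band outnumbers the ring
makes the background the biggest cluster — a genuine failure mode of the
biggest-cluster heuristic, exercised in the tests, and the reason the ROI is
drawn snugly around the LV.

Global and per-segment maximal-velocity curves reuse the 95% rule, applied to
whichever sign has the larger absolute in-mask extreme (sign retained).
Segments are 90° sectors about the cavity centre (mask centroid by default),
with a configurable reference angle and name mapping
(lateral/anterior/septal/inferior) — the segment convention of the imaging
plane is site-specific, so it is configuration, not code.

**E′** is detected on the rectified global maximal curve within the filling
window (taken from the flow timings when available; otherwise from the last
zero crossing of the global mean curve before its largest diastolic-direction
excursion). The same constrained two-peak logic applies; E′ is the earlier of
the two highest admissible peaks ("highest peak occurring first" is ambiguous
between *first* and *highest*; the pair-then-earlier reading is used and
documented). The diastolic direction is the sign of the mean tissue velocity
within the window — the annulus reverses direction between systole and
diastole, so this needs no user input.

### Known bias of the 95% rule on homogeneous tissue

On a region whose true velocity is spatially uniform (the phantom ring), the
95% rule's threshold keys off the *noisy* maximum, so the selected band is
the upper tail of the noise distribution: the expected excess is ≈ 2σ of the
pixel noise (≈ +1.0–1.3 cm/s at σ = 0.5 over ~465 pixels, i.e. ≈ +9–12% of an
11.3 cm/s E′; measured +9.5% ± 1.3% across seeds). On regions with real
spatial structure (a parabolic jet) the band is dominated by the spatial
profile and the rule is slightly *negatively* biased instead (E ≈ −2%:
band mean of the parabola top). Any top-tail estimator shares the uniform
-region bias (the mean of the top 5% by count has essentially the same
expectation), and the unbiased alternative — the mean curve — estimates a
different quantity; the maximal-curve convention is kept and the bias
documented. The same mechanism makes the A-wave estimate (peak 60 cm/s over
a ~200 px mask at σ = 2) noticeably seed-dependent.

## Cohort statistics

* **Overlap** between two masks is the Dice coefficient × 100
  (`200|A∩B|/(|A|+|B|)`; 100 for two empty masks); intersection-over-union is
  available as an option. Overlap between repeated segmentations is averaged
  over the diastolic phases for the transmitral flow and the systolic phases
  for the aortic flow — outside those windows the flow does not exist and
  masks are noise.
* **Variability** of a repeated measurement is `100|x₁−x₂| / mean(x₁,x₂)`
  (0 when both are 0; undefined when the mean is 0 with a nonzero
  difference).
* **Mann–Whitney**: exact two-sided p by full enumeration of group
  assignments (midranks, hence valid with ties) when `n ≤ 12`, otherwise the
  normal approximation with tie and continuity corrections
  (scipy). Two-sided throughout; 0.05 is the conventional significance
  display threshold.
* **Pearson** correlation with the OLS line, for comparisons against
  echocardiographic measurements ingested as plain numeric columns.
* **ROC**: thresholds sweep all midpoints between consecutive sorted unique
  values, in both orientations; the orientation with AUC ≥ 0.5 is reported.
  AUC is the trapezoidal area under the full threshold path (equal to the
  pairwise concordance probability with ties counting half — the tests verify
  this identity by brute force). The operating point maximises Youden's J
  (sensitivity + specificity − 1), ties broken by higher accuracy then lower
  threshold; sensitivity, specificity, NPV, PPV and accuracy are reported at
  that point. No confidence intervals are computed.

## The phantoms

The generators produce the study conditions for every test; their defaults
encode a typical acquisition — 15 ms frames and venc 180 cm/s for flow, 20 ms
and venc 15 cm/s for tissue, 1.9 × 1.9 mm pixels, a 900 ms cycle — and
healthy-control truth magnitudes: E = 80, A = 60 cm/s, DT = 185 ms,
IVRT = 78 ms, end of ejection 420 ms, E′ = 11.3 cm/s with S′ = 8 and
A′ = 5 cm/s.

* **Flow phantom.** A transmitral orifice (radius 15 mm) carrying a
  triangular biphasic E/A waveform with a parabolic spatial profile (zero at
  the rim), an aortic orifice (radius 9 mm) with an opposite-signed systolic
  triangle, and tissue annuli around both orifices moving with the
  longitudinal S′/E′/A′ waveform — on real basal velocity images the jets are
  bordered by myocardium of contrasting sign, and that contrast is exactly
  what the sign-based segmentation exploits. The annuli additionally carry a
  small diastolic drift (−1.5 cm/s, ramped in after end-ejection): real
  tissue never sits at exactly 0 cm/s through diastasis (slow annular drift,
  residual uncorrected phase offsets), and an exactly-zero band around the
  jet would make pixel sign a pure coin flip under noise — a degenerate
  condition, not a realistic one. Truth masks are the pixels with nonzero
  noise-free jet velocity; the truth flow-rate curve is the waveform times
  the pixelised profile integral, and FV truth is its closed-form time
  integral.
* **Tissue phantom.** A myocardial ring (radii 22–32 mm) moving uniformly
  with the S′/E′/A′ waveform, a cavity of per-pixel erratic "blood" profiles
  (random-phase sinusoids, amplitudes 6–12 cm/s), and a near-static
  background.
* Gaussian noise (default σ: 2 cm/s flow, 0.5 cm/s tissue — venc/SNR for a
  breath-hold acquisition with modulus SNR ≈ 40) is added everywhere, and
  velocities beyond ±venc wrap as the physics dictates. Waveforms are
  triangular by default so every 40–70% limb extrapolation is analytically
  exact and recovery error isolates implementation defects; a raised-cosine
  option exercises curved limbs. Waveform nodes sit on the frame grid where
  exactness matters (t_E = 540 = 36 × 15 ms) but filling bounds (498 ms,
  t_E + DT = 725 ms) deliberately do not — limb extrapolation is exact off
  the grid too, and temporal recovery is asserted to within one frame.
* `perturb_roi` jitters ROI vertices uniformly within ±k px (seeded),
  emulating a second operator's rough drawing for reproducibility studies.

### What the phantoms do not show

No partial-volume averaging, no view-sharing temporal blur, no spatially
varying phase-offset fields (only a constant offset option), no anatomy in
the modulus images, no heart-rate variability, and spatially uniform tissue
velocity (no transmural or regional gradients). Passing phantom tests
therefore demonstrates correctness of the algorithms under the stated model,
not clinical-grade accuracy on scanner data. Two consequences are worth
stating plainly: segmentation Dice against the full-orifice truth degrades
with noise because rim pixels (parabola → 0) flip sign with probability
Φ(−v/σ) — at σ = 5% venc the expected flipped fraction alone caps the mean
diastolic Dice near 93%, and the measured value (~79%) reflects additional
noise accretion at the jet boundary; and the E′ noise-selection bias
described above (~ +9.5% at σ = 0.5) sits at the tolerance usually asked of
it. Both are properties of the estimators under these conditions, reported
as measured.

## Problem sizes and runtimes

Default grids are 96 × 96 with 60 (flow) / 45 (tissue) phases — large enough
for realistic geometry at 1.9 mm pixels, small enough that the full pipeline
runs in ~0.15 s and the complete reproducibility study (10 operator
emulations of both pipelines) in a few seconds on one CPU. Oracle
cross-checks use 12 × 12 images and n ≤ 20 cohorts where exhaustive
enumeration is feasible.
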