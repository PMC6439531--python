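# Methods

## Overview

leafflow quantifies leaf movement in top-view time-lapse imagery of rosette
seedlings and uses it to predict harvest fresh weight. The central object is
the *normal field*: the dense optical-flow field between frames 12 h apart,
projected pixel-wise onto the radial axis through the seedling center. The
radial component separates outward apparent motion (leaf standing, driven by
elevation) from inward motion (leaf extension and drooping), and its
per-frame aggregates — magnitude |N̄ₖ|, angle θₖ, and projected area
Sₖ = mₖ — carry a circadian signature locked to the light/dark cycle.

## Coordinate and protocol conventions

* x rightward (array column), y downward (array row), origin at the
  top-left pixel center; angles via atan2(y, x) in (−π, π].
* Full protocol: 640 frames at 20-min intervals; registration and
  segmentation on a 640×480 raster, flow on 320×240; flow lag 12 h
  (36 frames), giving 604 analyzable frames k = 37…640.
* The analyzable series carries its own time axis t = 0…201 h anchored at
  the first analyzable frame, and the 15/9 light/dark schedule is anchored
  at t = 0 = lights-on. (640 frames at 20 min nominally span 213 h; the
  601-point overhang is absorbed by anchoring the series at k = 37.)
* Circle membership: Euclidean distance from center to pixel center
  ≤ radius. The plant ROI is the 28-px circle intersected with the
  Excess-Green mask; pixels outside the circle are never counted.

## Stage choices

**Registration.** Phase-only correlation (Fourier phase correlation with
20× upsampled local peak refinement) against the *first* frame of the
series; first-frame anchoring avoids drift accumulation across 640 frames.
Registration is global per frame.

**Segmentation.** ExG = 2g − r − b on sum-normalized chromatic coordinates
(r = R/(R+G+B), …; defined as 0 where R+G+B = 0), thresholded at 0.2.
Chromatic coordinates make the index invariant to uniform intensity
scaling, which is what makes a fixed threshold meaningful.

**Center detection.** Canny edges followed by circle-Hough voting over
radii within ±20% of the expected depression radius; the accumulator peak
must exceed 0.3 or detection fails explicitly (callers may fall back to a
configured center). The depression radius is 28 px at 320×240, corresponding
to 2.5 cm (px/cm is a config value).

**Dense flow.** The backend is pluggable behind a contract (zero field for
identical frames; global translations recovered to < 0.25 px median; ≥ 90%
outward signs under simulated radial expansion). The default is dense
iterative pyramidal Lucas–Kanade (`ilk`); TV-L1 (`tvl1`) is available but
systematically under-resolves the weak radial expansion of the textureless
leaf interior (outward fractions of 0.75–0.89 on the simulator scene versus
0.98–1.0 for ilk), which is why it is not the default. Flow is forward
(frame k−36 toward frame k) and computed on luminance.

**Radial projection.** The per-pixel dot product is computed as
(p·d)/|d| with d the integer offset from the center, then multiplied back
onto d/|d|; this form cancels exactly for tangential flow with integer
components. A pixel exactly at the center has no radial direction and gets
n = 0, sign 0. θₖ of a zero mean vector is stored as NaN (not 0) so
downstream correlations skip it. θ per pixel is realized as the signed
scalar p·r̂ (the inward/outward dichotomy), not a per-pixel angle.

## Feature reduction (115 dimensions)

Order and sizes: PPFD (1), track dummies (4; tracks 2–5 vs baseline 1),
PCA (20), angle-shift (6), magnitude-shift (6), PA-ave (9), angle-diff
(23), magnitude-diff (23), PA-diff (23).

* **Shift features**: Pearson correlation of a series with its copy shifted
  by 24, 48, 72, 96, 120, 144 h, NaN pairs dropped; NaN if the overlap has
  fewer than 3 points. Pearson is used because it is affine-invariant and
  consistent with R² tuning downstream.
* **PA windows**: means over 0–24, …, 168–192, 192–201 h (last window 9 h,
  right-closed).
* **Phase-mean differences**: under 15/9 over 0–201 h there are 9 light
  periods (the 9th truncated to 192–201 h, kept as a valid period — this is
  what yields the printed 23 = 8 LL + 7 DD + 8 LD count) and 8 dark
  periods. LD pairs use the light period *preceding* each dark period.
* **PCA blocks**: four blocks — angle-only, magnitude-only, PA-only, and
  all three concatenated — each reduced to 5 components. Plants are
  observations, series points variables; NaNs are mean-imputed with
  training-column means; blocks are fitted on the training split only to
  avoid leakage. The four-block realization is one defensible reading of a
  "four ways" design whose exact composition is ambiguous; it is documented
  here as this package's choice.

## Prediction

Seeded random 7:3 split (test size = ⌈0.3 n⌉; 338 → 236/102). Grid search
is exhaustive with seeded shuffled 5-fold CV scored by R²; ties resolve to
the first grid point. GBR reference grid: min_samples_split {10,30,50,70},
max_depth {4,6,8,10}, subsample {0.7,0.8,0.9,1.0} (a finite discretization
of the 0.7–1 range), learning_rate {0.01,0.05,0.1}; tree count stays at the
library default. SVR: RBF kernel with C, γ, ε ∈ {2^a, a = −20…20} (41³
points); the default "reduced" grids (GBR 2×2×2×2, SVR a ∈ {−10,−5,0,5,10})
keep desk-scale runs in seconds while preserving the geometric spacing —
the full grids are restored by `reduced_grids = false`. The SVR bundles its
min–max scaler in a pipeline so scaling is refit inside every CV fold.
Evaluation is the Pearson correlation between observed and predicted
weights; GBR importances summed within groups form a partition of 1.
"Stratified" five-fold for a continuous target is realized as plain seeded
random K-fold.

## The synthetic generator

What it emulates: ellipse-lobe rosettes (3 leaves at golden-angle
phyllotaxis, axis ratio 1:2, anchored at the center) whose projected area
grows as A₀·exp(rt); nutation as a ±amplitude/2 oscillation of the leaf-tip
radius at a 24-h period locked to the schedule; a dark ring depression of
radius 28 px; whole-panel sinusoidal drift (amplitude ≤ 3 px, period 96 h);
per-frame Gaussian intensity noise. Because the rosette at any instant is a
uniform scaling of a fixed template about the center, the ground-truth flow
is exactly radial plus the drift translation — which is what makes it an
oracle for the projection stage.

Cohort defaults are calibrated once to the regime the pipeline targets:
growth rate r ~ N(0.006, 0.0015²) h⁻¹ (seedling-scale relative area
growth), nutation amplitude ~ |N(3, 1²)| px, PPFD ~ N(220, 15²)
µmol m⁻² s⁻¹, tracks uniform on 1–5. The harvest-weight link is
w = 10·exp(350·r) + N(0, 8²) g, resampling non-positive draws; with the
rate distribution above this yields Gaussian-looking weights centered near
80 g spanning roughly 40–140 g, and a rate–weight correlation ≈ 0.9. The
analytic mode emits closed-form magnitude/angle/area series (growth trend +
nutation oscillation + noise) and skips rendering entirely; a `signal="pa"`
variant decouples the movement channels from the growth rate so only the
area channel is informative — used to check that grouped importance
concentrates where the signal is.

What the generator does **not** emulate: leaf occlusion and overlap,
per-leaf asymmetry of nutation, illumination changes between light and dark
imaging, lens distortion, neighbor-plant encroachment, and the
morphological complexity that makes real θₖ series multimodal. Passing
tests therefore demonstrate correctness of the computational pipeline and
recoverability of a planted circadian/growth signal — not field-level
accuracy on real crops.

## Problem sizes and determinism

Tests and the acceptance script run rendered scenes at 160×120 px with ≤ 13
frames and model-layer checks on 60-plant analytic cohorts with the reduced
grids — sizes chosen so the whole suite completes in well under a minute
while every stage still runs end to end. All randomness flows from a single
seed through stable per-stage hashed child seeds (< 2³¹); fixed seeds give
bit-identical images, features, and model selections.

## Known limitations

* The Hough center is returned at integer accumulator resolution.
* TV-L1 remains available but fails the radial-expansion contract on
  low-texture interiors (see above).
* Rendered-mode cohorts are slow at full protocol scale (640 frames ×
  n plants); analytic mode is the intended path for model-layer work.
* The periodogram-based rhythm checks are resolution-limited by the 201-h
  record (frequency bins at multiples of 1/201 h⁻¹ place the bin nearest
  24 h at 25.1 h).
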