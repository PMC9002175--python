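# Methods

This note documents the model behind `ichseg`, the choices made where the
procedure is genuinely underdetermined, and what the synthetic phantoms
do and do not establish about behavior on real CT.

## Windowing

CT display windowing and 0–1 normalization compose into one clamped
linear map, `v = clip((HU − (c − w/2)) / w, 0, 1)` with width w = 100 HU
and center c = 45 HU (the standard brain window for acute hemorrhage
reading).  Two saturation facts are load-bearing downstream: bone
(≥ 95 HU) maps to exactly 1.0 and air to exactly 0.0, which lets the
parenchyma extractor identify skull without a second HU threshold, and
clamping annihilates noise outside the window so air and bone are exactly
constant in the normalized volume.

## Watershed seeding

The relief flooded per slice is the *negated* Gaussian-smoothed intensity
(σ = 1.5 px), so hyperdense structures become catchment basins with an
interior minimum — the property that makes basin extrema usable as
region-growing seeds.  A gradient-magnitude relief would also isolate
lesions but fragments each tissue plateau into its own basin; the negated
intensity keeps the basin count equal to the number of bright structures,
which is what seed proposal needs.  Minima shallower than h = 0.05
(normalized) are removed by grayscale reconstruction before flooding;
with 4 HU noise the smoothed residual is ≈ 0.008, comfortably below h, so
noise does not oversegment.  Flooding uses no watershed lines: every
pixel belongs to exactly one basin.

Each basin is summarized by its pixel count, min/mean/max intensity on
the original slice, and its extremal point (brightest original pixel,
ties broken toward the smallest (row, col)).

**Seed admission.** Automatic selection must decide which basins are
bleeds.  A basin qualifies as hyperdense when it holds at least
`min_hyperdense_px = 10` pixels above the floor 0.55 (≈ 50 HU, typical
acute-blood attenuation) and below the saturation cutoff 0.999.  A count
is used rather than a peak test deliberately: the maximum over the tens
of thousands of parenchyma pixels in a basin crosses any fixed floor with
non-negligible probability under 4 HU noise, whereas ten independent
supra-floor pixels from noise alone is essentially impossible, and any
bleed of clinical size contributes hundreds.  The seed anchors at the
basin's brightest *sub-saturation* pixel, which also handles bleeds
against the inner table of the skull: such a lesion shares its basin with
bone, and the brightest non-bone pixel lies in the blood.  Candidates are
ranked by basin mean intensity, deduplicated to one per 3-D connected
supra-floor cluster, and capped at `max_seeds` (default 3).

Manual mode formalizes the human-in-the-loop selection: a click is
snapped to the candidate of the basin containing it (`manual_snapped`),
or kept verbatim when no basin claims it.  Snapping is idempotent.

## Region growing

The inclusion test compares each pixel against a *fixed* reference — the
originating seed's intensity, not a running region mean — so a flood
equals the connected component of the eligibility map containing the
seed.  The implementation computes exactly that component, which makes
results trivially independent of queue processing order; a literal BFS
oracle in the test suite confirms the equivalence.  Comparisons carry a
1e-12 absolute slack so exact ties (|difference| = τ) survive binary
rounding of decimal intensities.

*Pass 1* uses |Δ| ≤ τ with τ = 0.30 and 4-connectivity.  Growing is
2-D per slice; propagation to adjacent slices re-seeds at the
centroid-nearest in-mask pixel of the previous slice while carrying the
original seed's reference intensity.  Carrying the reference is what
gives the stopping rule its meaning: a re-seed position whose intensity
no longer resembles the original seed yields an empty slice and stops the
walk (a re-seed referenced to itself would always admit itself).

*Pass 2* refines the cut per slice.  The ROI is the bounding box of the
first-pass mask dilated by 5 px — enough background must enter the ROI
for a two-class split to exist.  The threshold t* maximizes the
between-class variance over the interior edges of a 256-bin histogram,
with class statistics computed exactly from the sample; ties break toward
the smaller t, which on a noiseless two-value ROI places t* just above
the background mode (maximizing sensitivity; every cut in the gap attains
the same variance).  The re-grow is one-sided, `intensity ≥ t*`, because
the Otsu split designates hemorrhage as the bright class.  A degenerate
single-intensity ROI falls back to the first-pass mask for that slice
with a logged warning — the second pass never returns less information
than the first.

*Skull-adjacent bleeds.*  The parenchyma domain is the 3-D flood from a
central brain voxel over 0.01 < v < 0.999, hole-filled per slice so
interior hyperdense lesions stay inside.  The domain is engaged when a
seed lies within 2 px of saturated bone, when the caller passes
`skull_adjacent`, or — as a safety net — when the final mask is found to
contain saturated voxels, in which case the pipeline re-runs itself
domain-restricted.

## Volumetry

Voxel counting: volume = count × slice thickness × row pitch × col pitch
/ 1000 (mm³ → mL).  The ABC/2 estimator is automated with a deterministic
protocol standing in for the clinician's on-screen calipers: the
largest-area slice is chosen (ties → lowest index), A is the exhaustive
pixel-center Feret diameter on that slice (anisotropic in-plane spacing
respected), B is the extent of the slice's pixel centers projected on the
direction perpendicular to A (not forced through A's midpoint, matching
common practice), and C is the number of mask-bearing slices times the
slice thickness.  For a perfect ellipsoid ABC/2 overestimates the
analytic volume π/6·ABC by exactly 3/π ≈ 1.047; on irregular shapes the
error grows, which the lobulated phantoms reproduce.

## Agreement statistics

Overlap: Sen = TP/(TP+FN), PPV = TP/(TP+FP), DSI = 2TP/(2TP+FP+FN),
JI = TP/(TP+FP+FN).  Undefined ratios (zero denominator) surface as an
explicit `None`, never a silent 0.  Volume agreement uses ICC(2,1) —
two-way random effects, absolute agreement, single measures, the
standard form for method comparison of continuous measurements —
computed from the two-way ANOVA mean squares with the McGraw–Wong
F-based 95% CI; ICC(3,1) and ICC(1,1) are available for sensitivity
probing.  Bland–Altman reports both the limits of agreement
(mean ± 1.96 × SD, sample SD with n−1) and the 95% CI of the mean
difference, labeled separately because they answer different questions.

## Synthetic phantoms

A phantom is a cylinder-like stack: an elliptical 2-voxel skull ring
(800 HU) around brain (30 HU) in air (−1000 HU), with lesions of acute
blood (65 HU) carved as ellipsoids, optionally radius-modulated in-plane
by 3–5 angular lobes of ≤ 30% amplitude ("lobulated"), optionally
multifocal, optionally clipped against the inner skull table
("skull-adjacent").  Default geometry follows a routine head-CT protocol:
12 slices of 7.2 mm, 256 × 256 in-plane at 0.726 × 0.644 mm.  I.i.d.
Gaussian HU noise (default σ = 4 HU) is added *after* the ground-truth
mask is recorded, so truth voxels are exactly blood pre-noise.  Tissue
HU values sit at standard CT attenuation levels; under the default
window they normalize to air 0, brain 0.35, blood 0.70, bone 1.0.

The suite generator draws lesion volumes log-uniformly in 1–30 mL (the
range of clinically common supratentorial bleeds), randomizes aspect
ratios and center jitter, and derives per-case seeds from a master seed.
Because 7.2 mm slices quantize the through-plane extent, a single
rescaling step recalibrates the semi-axes when the voxelized volume
drifts more than 5% from the drawn target.

**What the phantoms do not show.**  They contain no gray/white contrast,
ventricles, CSF spaces, partial-volume boundary voxels, streak or
beam-hardening artifacts, perihematomal edema, or intraventricular
extension.  Lesion boundaries are crisp one-voxel transitions, which is
why noiseless runs are voxel-exact and noisy cohort metrics are
near-perfect; on real CT the diffuse hematoma rim and edema would lower
overlap and make τ and the Otsu cut genuinely load-bearing.  Passing the
phantom suite establishes the correctness of the machinery — flood
semantics, thresholds, propagation, volumetry, statistics — not clinical
accuracy.

## Problem sizes and numerical conventions

The cohort analyses (tests and `scripts/acceptance.py`) use 30 standard
phantoms at the full clinical grid, segmented end-to-end in roughly
15 seconds total on one CPU; the lobulated comparison uses 12 cases.
Axis order is (slice, row, col), 0-based, everywhere; spacing is
(slice thickness, row pitch, col pitch) in mm.  NIfTI is the mask
interchange format (masks are not DICOM objects); DICOM series are read
slice-wise with slope/intercept rescaling, sorted by physical position,
and validated to uniform spacing within 1e-3 mm.  All tie-breaks
(basin extremum, largest slice, Otsu threshold, centroid re-seed) resolve
toward the smallest index/value, making every output bit-reproducible
for fixed inputs and configuration.
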