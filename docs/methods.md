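# Methods

## Measurement model

A low-contrast-module slice of the ACR CT phantom is modelled as a
water-equivalent disc (~200 mm, ~0–90 HU) in air, carrying a 25 mm cylinder
whose mean CT number exceeds the background by a few HU, centred 55 mm from
the phantom axis at an unknown angle. The measurement estimates three
quantities from two circular ROIs:

* **contrast** = mean CT number in the object ROI − mean in the background
  ROI (signed difference; the module-2 object is hyperdense, so positive in
  practice);
* **noise** = sample standard deviation (n−1 denominator) of the background
  ROI;
* **CNR** = contrast / noise.

The sample-SD convention matches scanner consoles and is conservative for
CNR. `cnr` is stored as `contrast / noise`, so the identity
`cnr × noise = contrast` holds to floating-point round-off.

## Localization

The only unknown geometric degree of freedom is the object's angle, plus
whatever misalignment the phantom has in the gantry. Both are absorbed by:

1. **Segmentation** — pixels above −300 HU (midway between air at −1000 and
   the body), largest connected component, holes filled. The largest-component
   rule discards couch fragments; hole filling makes the footprint solid.
2. **Centroid** — unweighted mean of foreground pixel centers, in mm. A
   binary centroid is used rather than an intensity-weighted one because the
   low-contrast insert would bias a weighted mean, while the binary centroid
   is indifferent to internal structure. The equivalent circular diameter is
   checked against [150, 250] mm; an out-of-range value raises a warning
   flag (wrong module / wrong object) but does not stop the measurement.
3. **Angular search** — a circular ROI rotated about the centroid at 55 mm
   radius in 2° clockwise steps (180 positions). The mean CT number per
   position forms the angular profile; the object is at the profile maximum,
   first occurrence winning ties (exact ties are measure-zero on real noise;
   the rule exists for synthetic edge cases). No sub-step refinement is
   performed: with a 25 mm ROI on a 25 mm object, a ≤1° offset (≈1 mm of
   arc) costs only a few percent of contrast.

Angles are measured from 12 o'clock of the displayed image, clockwise
positive; an ROI center at angle θ is `centroid + radius·(sin θ, −cos θ)` in
(x, y) display coordinates with y downward. The origin is the center of the
top-left pixel and every length is in mm, so FOV/matrix changes only alter
the pixel spacing.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| search radius | 55 mm | known radial position of the 25 mm object |
| object ROI diameter | 25 mm | matched filter for the 25 mm object ("25 mm ROI" is read as a diameter — a 25 mm *radius* could not stay inside the body at 55 mm radius) |
| angular step | 2° | resolves the object to ~1 mm of arc; 180 ROI evaluations per slice |
| background ROI diameter | 25 mm | chosen for symmetry with the object ROI; configurable and echoed in every report |
| segmentation threshold | −300 HU | midway between air and body; robust to ≥50 HU noise |
| tolerance | mean CNR ≥ 1.0 | accreditation criterion, boundary inclusive |

Batch reporting computes CNR per slice and then mean ± SD across slices
(never ratio-of-means). Method comparison uses
`|mean_a − mean_b| / mean_b × 100` with the reference (manual) series as
denominator — the definition is printed in every report — and a two-sided
Mann-Whitney U test at α = 0.05 with midranks for ties: exact p by full
enumeration of the C(n, n_x) label assignments for pooled n ≤ 12, a normal
approximation with tie and continuity corrections beyond. No
multiple-testing correction is applied.

## Synthetic phantom generator

`SyntheticPhantomConfig` defaults encode the canonical acquisition: 235 mm
FOV on a 512 matrix (0.459 mm pixels), 200 mm body at 90 HU in −1000 HU
air, one 25 mm disc of +6 HU contrast at 55 mm radius, Gaussian noise of
SD 3 HU on the body, 20-slice stacks. The object's default angle (134°) is
arbitrary; localization is angle-invariant. Configurable misalignment
shifts the whole phantom; the FOV must still contain body plus offset.

Rendering choices:

* **Area-fraction antialiasing** (4× supersampling) at disc edges, so ROI
  means are not biased by rasterization; away from edges noiseless images
  are exactly piecewise-constant.
* **White Gaussian noise** added to body pixels only. This is sufficient to
  exercise a mean/SD-based method, but real CT noise is spatially
  correlated and streaked; reconstruction-kernel and exposure effects are
  emulated purely by the noise SD (≈2.7–50 HU across clinical protocols).
  Consequently, passing tests demonstrate correctness of the geometry and
  statistics, not robustness to textured noise.
* The smaller 2–6 mm cylinder series can be drawn for visual realism but is
  never scored.

Determinism: a slice is a pure function of (config, slice seed); stack
slice k uses a seed derived from (config.seed, k) via `SeedSequence`, so
stacks are reproducible and slices independent.

## Numerical choices

* ROI membership is by pixel-center distance (Euclidean, mm); pixel counts
  agree with the analytic disc area to <2% for diameters ≥10 mm at 0.459 mm
  spacing.
* ROI statistics are evaluated on the circle's bounding box, making the
  180-position search O(ROI area), not O(image area).
* A zero background SD raises an explicit "noiseless image; CNR undefined"
  error rather than returning infinity; an all-air image raises "no phantom
  found"; every pipeline failure is tagged with its stage.
* DICOM fixtures store HU as unsigned 16-bit with slope 1 / intercept
  −1024, so write→read round-trips within ±0.5 HU.

## Problem sizes used in verification

The test suite and the acceptance script verify localization on 100
randomized slices (contrast 6 HU, noise SD 3 HU, misalignment up to 5 mm),
parameter recovery on a 20-slice default stack, and the noise-sweep trend
with 8 slices per noise level {4.2, 3.6, 2.9, 2.7} HU — stack depths chosen
to keep Monte-Carlo error well below the asserted margins (the SD of a
per-slice CNR at these settings is ≈0.04, so a 20-slice mean is known to
±0.01).

## Limitations

* No projection/reconstruction physics: no correlated noise, beam
  hardening, or kernel MTF; FOV and kernel effects enter only through
  spacing and noise SD.
* Single-slice 2-D processing; stacks are ordered lists, never resampled
  volumes.
* Only linear-rescale, single-frame, monochrome CT DICOM is read; no LUTs,
  multi-frame objects, or localizers.
* The smaller cylinder series is not detected or scored, and no
  model-observer metrics (d′, NPWE) are computed.
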