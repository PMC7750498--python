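# Methods

## Scope and model

`petseg` implements a validation pipeline for PET-based intraprostatic
tumor contours with histopathology as the reference standard, plus the
synthetic world needed to exercise it end to end:

1. **Histology reference construction.** Whole-mount step sections are
   modelled as sparse 2-D tumor masks at a fixed 4-mm physical step. Each
   section is expanded ±2 mm along Z (half the step) and the union of
   slabs is the 3-D reference volume. Slabs are half-open,
   `[z − 2, z + 2)`, so consecutively stepped sections tile Z with no gap
   and no double assignment; volume is conserved exactly
   (Σ slice area × 4 mm). No in-plane morphing between sections is
   performed — the expansion is purely axial.
2. **Fractional-SUVmax contouring.** `GTV(f)` is every gland voxel with
   `SUV ≥ f · SUVmax` where SUVmax is the intraprostatic maximum.
   Thresholding is inclusive (the SUVmax voxel belongs to every contour),
   applies no smoothing and no connected-component selection (multifocal
   uptake yields multifocal contours), and is restricted to the gland by
   construction. Contours nest: `f1 < f2 ⇒ GTV(f2) ⊆ GTV(f1)`.
3. **Individual scaling as volume matching.** Manual per-patient rescaling
   of the display window cannot be automated, but its stated goal —
   adjusting the contour volume to the available histological information —
   can: the absolute SUV threshold is searched on a grid (default step
   0.1 SUV) over `(0, SUVmax]` for the volume closest to the histology
   volume. Contour volume is non-increasing in the threshold, so the search
   is a monotone staircase; ties break toward the larger threshold (the
   more specific contour, guarding against tumor-volume overestimation).
4. **Evaluation.** Quadrant sensitivity/specificity (below), voxel Dice,
   coverage of the histology reference (`100·|GTV∩H|/|H|`), and volume
   proportions relative to the examined specimen and the whole gland.
   Histology-referenced analyses are restricted to the specimen region;
   contour/whole-gland proportion uses the untrimmed contour.
5. **Cohort statistics.** Median (IQR) summaries; Shapiro-Wilk normality
   screen; Friedman test across approaches (complete blocks over patients,
   midranks, standard tie correction, χ² reference with k−1 df) with
   pairwise uncorrected Dunn tests
   `z = (R̄ᵢ − R̄ⱼ)/√(k(k+1)/(6n))`, two-sided normal p, significance
   flagged at strict `p < 0.05`. No multiplicity correction is applied to
   the pairwise tests, by design.

### Quadrant scoring

On each axial slice holding at least one examined gland voxel, the
examined gland voxels are split by two axis-aligned lines through their
centroid; a voxel exactly on a line goes to the lower-index side, so the
assignment is deterministic. A quadrant is reference-positive if it holds
≥ 1 histology voxel and test-positive if it holds ≥ 1 contour voxel; TP,
FP, TN, FN accumulate over all quadrants of all scored slices (always 4
per slice — a quadrant left empty by the split counts as reference- and
test-negative). Slices with gland but no examined tissue are skipped
entirely rather than scored as 4 TN, so unexamined tissue cannot inflate
specificity. The quadrant anchor (the centroid) and the ≥ 1-voxel
positivity rule are the least-assumption choices for an otherwise
under-specified construction; both are isolated in `quadrant_partition` /
`quadrant_confusion` if a different convention is needed.

## The phantom world

`generate_phantom` builds one synthetic patient on an isotropic 2-mm grid
(world Z anchored at voxel centers, `z = k·2 mm`):

* **Gland**: an ellipsoid of aspect 1.2 : 1.0 : 0.9 (wider than tall),
  voxelized and rescaled by bisection until the voxel count matches the
  target volume (within a voxel shell, ≤ 5% for realistic sizes).
* **Lesions**: ellipsoids similar to the gland, placed in gland-normalized
  coordinates where containment (`‖c‖ ≤ 1 − s`) and pairwise disjointness
  (`‖cᵢ − cⱼ‖ ≥ sᵢ + sⱼ`) are exact; centers snap to voxel centers so the
  peak value is realized exactly. Placement retries whole configurations
  (60 restarts × 80 proposals) because an index lesion drawn near the
  gland center can make every satellite position infeasible.
* **Uptake**: background 3.0 SUV on the gland, 0 outside. Inside a lesion
  the default `ramp` profile falls linearly with the normalized ellipsoidal
  radius from the lesion peak to the background at the truth boundary, so
  every fractional threshold carves a distinct nested sub-volume whose
  geometry is known in closed form (`analytic_fraction_mask`) — the
  independent route used to validate the image thresholding. A `flat`
  profile (uniform peak) is also available; with blur and noise off, any
  threshold between background and peak then recovers the truth mask with
  DSC = 1 exactly.
* **Degradation**: isotropic Gaussian blur of 5 mm FWHM (post-
  reconstruction PET resolution) and additive zero-mean Gaussian noise of
  0.4 SUV, clipped at 0. With blur on, the image SUVmax falls below the
  lesion peak — the partial-volume effect that makes fractional thresholds
  lesion-size dependent.
* **Specimen and histology**: the specimen is the gland restricted to the
  central contiguous slab covering 75% of its Z extent (step sectioning
  spares the apex/base ends); histology planes sample the truth mask every
  4 mm, centered in that slab.

`sample_cohort_spec` draws per-patient parameters at the scales of the
validation cohort this package emulates: lesion peak SUV uniform in
[11.6, 59.8], index-lesion volume log-uniform in [0.6, 9.9] ml, gland
volume uniform in [20.4, 41.8] ml, 1–3 lesions (probabilities
0.6/0.3/0.1) with satellites log-uniform in [0.3, 1.5] ml at 40–90% of the
index peak. Satellites are dropped when the normalized packing bound shows
the gland cannot hold them. All randomness flows from one
`numpy.random.default_rng(seed)` stream; identical seeds give bitwise
identical datasets.

Fixed defaults chosen once (not stated by the emulated study): background
3.0 SUV (benign-gland uptake typical of PSMA tracers), blur 5 mm FWHM,
noise 0.4 SUV, specimen fraction 0.75, the lesion multiplicity mixture.

### What the phantom does and does not establish

The phantom reproduces the *measurement chain* (sparse histology sampling,
slab interpolation, trimming, thresholding, quadrant scoring) but not the
*error sources* of real data: no registration mismatch between histology
and PET, no gland shrinkage or elastic deformation, no anatomically
realistic shapes, no PET physics (sinograms, scatter, attenuation), and a
stylized uptake profile. Green tests therefore establish correctness of
the computations and the qualitative threshold trade-off, not clinical
performance numbers. Two visible consequences: per-patient threshold
volumes are almost deterministic fractions of the truth volume, so
rank-based tests separate approaches more sharply than heterogeneous
patient data would (the 40%-threshold volume tests significantly smaller
than the histology reference here, which real cohorts of this size need
not show); and for low-peak patients a 20% threshold can fall below the
gland background, contouring the whole gland — the synthetic analogue of a
real patient whose SUVmax sits close to the contouring window.

## Numerical choices

* Voxel membership everywhere is by voxel center; volumes are voxel counts
  × 8 mm³.
* Threshold search grid points are clean multiples of the resolution
  (rounded to 9 decimals) so integer-valued SUV plateaus are hit exactly;
  volume-error ties are compared with a 1e-9 ml tolerance before breaking
  toward the larger threshold. On a discrete staircase several adjacent
  thresholds share one contour, so "recovering" a generating threshold
  means returning its contour and a threshold within its plateau.
* Quantiles use numpy's linear interpolation; medians/IQRs are computed on
  unrounded values and formatted to one decimal only for display.
* Undefined metrics (empty denominators, both-empty Dice) are reported as
  `nan`/not-available, never as 0; the Friedman block matrix drops
  patients with any missing cell (complete-case).
* An all-tied Friedman block matrix returns statistic 0, p = 1 rather
  than dividing by a zero tie-correction factor.

## Known limitations

* The histology model only stacks slabs; strongly differing adjacent
  sections are not morphed into each other.
* Quadrant scoring is tied to axis-aligned image axes; a rotated gland
  would partition differently.
* `volume_matched_threshold` assumes the target is reachable; targets
  above the whole-gland volume return the search floor with a `flagged`
  result rather than an error.
* Manual observer contouring (display-window scaling by reader teams) is
  out of scope; the volume-matched threshold is the automatable surrogate
  for its individually scaled variant.
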