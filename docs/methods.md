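# Methods

This note documents the models, conventions and numerical choices behind
`histoconcord`, in the order the pipeline applies them.

## Masks, grids and orientation

All structures are binary occupancy masks on one shared axial voxel grid.
On load, every NIfTI volume is reoriented to a canonical frame: axis 0
increases toward the patient's left, axis 1 toward posterior, axis 2
toward superior.  Quadrant and sector names (left/right,
anterior/posterior, base/apex) are defined against these axes, so a fixed
internal orientation is a correctness requirement, not a convenience.  The
source affine and axis order are retained and restored on write, making
read→write round trips exact.

Choices and tolerances:

* any strictly positive voxel value binarizes to 1 (tolerates
  probability-like exports);
* grids must agree exactly in shape and within 10⁻³ mm in spacing and
  origin — the package never resamples.  Registration happened upstream
  (manually, in the workflow this package models), so a grid mismatch is
  evidence of a broken input, not something to paper over;
* affines whose off-axis components exceed 10⁻³ of the column norm are
  rejected as oblique, naming the offending axis.

GTVs are trimmed to the gland (and, when provided, to the histologically
examined region) by voxelwise intersection before any scoring.  The
examined region is an opaque optional mask because its geometry is
site-specific and not derivable from the other inputs.

## Contour interpolation

Step-sectioned histology yields closed planar tumor contours on sparse
axial planes (nominally every 4 mm).  Reconstruction to 3D is shape-based:
each contoured plane is rasterized (a voxel belongs to the contour iff its
center is inside or on the polygon), converted to a 2D signed-distance
field (positive inside), and intermediate slices take the zero-superlevel
set of the z-linear interpolation between the bracketing planes.  A value
of exactly 0 counts as inside, for determinism.  Contoured planes are
reproduced exactly (the interpolation is exact at knots).

Two boundary conventions:

* **End caps.** A step section represents a slab of tissue, not a plane;
  the volume therefore extends half a nominal step (2 mm by default)
  beyond the first and last contoured planes with the end contour's
  cross-section.  A lesion visible on a single section thus occupies about
  one section's thickness.
* **Component matching.** In-plane connected components on adjacent
  contoured planes are grouped by footprint overlap and interpolated
  pairwise; a component with no partner on the adjacent plane shrinks
  (by rising signed-distance threshold) to extinction exactly at the
  midpoint between the planes.  This prevents spurious bridging of
  multifocal disease: spatially separated volumes must remain separate
  lesions.

A `nearest` mode (each slice copies the nearer contoured plane) is exposed
for sensitivity analysis, since the upstream software's interpolation
algorithm is not publicly specified.

## Gland partitioning

Three schemes of decreasing spatial resolution:

* `QUADRANT_SLICE`: each gland-containing slice is divided into four
  quadrants around the per-slice gland center of mass.  Only nonempty
  (slice, quadrant) pairs count as analysable segments, so the per-patient
  segment count varies with gland height (typically 40–90 on clinical
  grids).
* `SEG18`: gland slices are split into base/mid/apex thirds of equal slice
  count (remainder to mid, then base; an equal-volume mode exists as an
  option); each third is divided left/right at the third's center of mass
  and into three anterior–posterior bands of equal physical extent between
  the third's AP extremes.  Exactly 18 descriptors, empty ones retained
  but flagged and excluded from scoring.
* `SEG6`: thirds × left/right — the sextant map.

The centroid (rather than bounding-box center) realizes "equal quadrants"
in tissue terms; the bounding-box alternative is available as an option.
The in-plane 6-way rule of `SEG18` is a declared convention: the published
segment maps it emulates do not fully specify the geometry, so the
simplest axis-aligned partition consistent with the sector naming is used.

Tie-breaking is fixed: voxel centers exactly on a split plane go left
(left–right axis) or anterior (AP axis), with a 10⁻⁹ mm comparison
epsilon.  All partitioners are deterministic and are verified against an
independent per-voxel classifier written with explicit loops.

## Segment scoring

A segment is positive for a structure when the overlap meets both of two
thresholds: a minimum voxel count (default 1) and a minimum fraction of
the segment's volume (default 0).  The default any-overlap rule is the
closest objective surrogate for the visual positivity reading used in
reader studies; stricter rules are exposed because the visual threshold of
a human reader is unknowable, and results should be reported together with
the rule parameters.

Confusion counts are taken over nonempty segments only.  Sensitivity and
specificity carry explicit undefined states: when disease involves every
analysable segment there are no negatives, specificity has a zero
denominator and is recorded as *missing* — never coerced to 0 or 1 — and
excluded from medians and paired tests case-wise.  This mirrors the
"not plausibly determinable" situation that coarse schemes produce in
high-tumor-burden patients.

## Lesion analysis

Connected components of the reference mask are lesions (26-connectivity by
default: interpolated volumes are smooth and thin oblique structures
should not split; 6 and 18 are available).  Lesion size is the maximum
pairwise distance between voxel centers (3D Feret diameter), computed
brute-force for components up to 10³ voxels and on convex-hull vertices
above that — both exact.  Index lesions are those with diameter ≥ 10 mm,
inclusive.

Detection: a reference lesion is detected when the test mask overlaps it
per the positivity rule.  False positives are test components overlapping
*no* reference component — including sub-index foci, so a test component
that sits on a real but small tumor is neither a detection (it does not
enter the index-lesion table) nor a false positive.  False positives are
reported at any size, with diameters, so a downstream size filter can be
applied.

## Voxel-level overlap

`DSC = 2|A∩B|/(|A|+|B|)` over voxel counts, plus intersection volume in
ml.  Two empty masks raise an error rather than returning a convention
value; cohort tables record the case as missing.

## Cohort statistics

Per-patient metric tables (patients × conditions) are compared with a
fixed, deterministic procedure at α = 0.05:

* **Normality gate**: Shapiro–Wilk; normal iff p > 0.05.  For paired
  two-condition tests the gate is applied to the paired differences (the
  natural quantity for both candidate tests); constant samples are flagged
  degenerate and routed non-normal.
* **Two conditions**: paired t (two-sided) when gated normal, otherwise
  the two-sided Wilcoxon matched-pairs signed-rank test.  Zero differences
  are dropped before ranking (classic convention) and their count
  reported.  For n ≤ 25 the p value is exact, from the full permutation
  distribution of the positive-rank sum computed by dynamic programming
  over (doubled) midranks — exact even with ties, which off-the-shelf
  exact routines refuse; above 25, the normal approximation with
  continuity correction.  Small paired cohorts (n ≈ 10) demand the exact
  small-sample behavior.
* **Three or more conditions**: when every condition passes the gate,
  repeated-measures one-way ANOVA with the Geisser–Greenhouse epsilon
  correction and Fisher's-LSD pairwise t tests on the ANOVA residual mean
  square; otherwise the Friedman test with uncorrected Dunn's pairwise
  z tests on mean ranks.  No multiplicity correction in either branch, by
  design of the emulated procedure.
* Missing values are handled by complete-case deletion restricted to the
  conditions in each comparison; every report carries the n actually used,
  the normality verdicts and the test provenance.  Summaries are median
  and IQR with linear-interpolation percentiles (declared in the output),
  plus range, mean and SD.

## Synthetic phantom cohort

No co-registered histology/imaging mask dataset is publicly available, so
the package ships a seeded generator whose defaults emulate the structure
of a small prostatectomy validation cohort:

* grid 96×96×40 voxels at 1×1×2 mm (clinical axial anisotropy); a coarse
  2×2×4 mm profile exists for fast tests;
* ellipsoidal gland, semi-axes drawn to give 20–60 ml volumes;
* 1–3 ellipsoidal lesions per patient, fully inside the gland and mutually
  disjoint; at least one index lesion (max diameter 14–21 mm, volumes
  ≈ 0.6–3.5 ml) per patient, plus optional sub-index foci (diameter
  ≈ 8.6–9.9 mm, ≈ 0.3–0.5 ml).  Sizes deliberately avoid the
  neighborhood of the 10 mm index threshold so that the analytic diameter
  and the voxelized Feret diameter always agree on index status (voxel
  centers lie inside the ellipsoid, so the measured Feret never exceeds
  the analytic diameter);
* per-modality deviations: the default **MRI-like** profile erodes each
  lesion by 1.5 mm (systematic volume underestimation and segment-level
  misses) with small (≤ 1.5 mm) rigid translation; the default
  **PET-like** profile dilates by 1 mm, translates ≤ 1.5 mm and adds a
  disjoint false lesion with probability 0.4.  A separate
  **partial-miss** profile (erosion 2 mm, through-plane translation up to
  ±6 mm, i.e. 1.5 section steps) emulates slice-direction
  misregistration — the dominant error mode when 4 mm step sections are
  matched to axial imaging — and is the condition under which the
  resolution tendency of the analysis schemes (coarser schemes → higher
  median sensitivity) is exercised;
* a configuration option makes one patient's reference cover the whole
  gland, to exercise the undefined-specificity path.

All primitives are ellipsoids so per-lesion volumes and diameters are
known by construction.  Ground-truth segment positivity and confusion
counts are computed at generation time by an independent per-voxel
classifier (plain loops, no code shared with the scoring pipeline);
lesion detectability and false-positive counts come directly from the
constructed masks.  Everything derives from a single master seed through
`numpy.random.SeedSequence.spawn`, so cohorts are bit-reproducible and no
global random state is touched.

What the phantom does **not** emulate: image intensities (SUV, MR
contrast), reader variability, irregular (non-ellipsoidal) lesion shapes,
non-rigid registration deformation, and zonal anatomy.  Passing tests on
the phantom therefore demonstrate the correctness of the measurement and
statistics chain — not the clinical performance of any modality.

## Problem sizes and determinism

The test suite and the acceptance script run cohorts of 10 patients
(default profiles, with exact ground-truth verification) and 30 patients
(partial-miss profile, medians only) on the 96×96×40 grid; these sizes
give stable cohort medians while keeping a full run in the minutes range
on one CPU.  Every pipeline output is a pure function of inputs, the run
configuration and the master seed; result files embed the package version,
a configuration hash and the seed.

## Known limitations

* The `SEG18` in-plane geometry is a declared convention (see above);
  other sites' 18-segment maps may differ, so cross-study comparisons
  should state the rule.
* Erosion/dilation radii are realized on the voxel lattice via Euclidean
  distance transforms; on anisotropic grids the effective radius is
  quantized by the slice spacing.
* The signed-distance taper for unmatched contour components shrinks a
  shape toward its inradius maxima, which is one of several defensible
  extinction geometries.
* Lesion-wise deviations are applied independently; the generator does not
  model spatially correlated registration error fields.
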