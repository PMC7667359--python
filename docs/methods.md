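# Methods

## Problem and scope

In acute ischemic stroke, the baseline DWI lesion volume is a key
selection criterion: infarcts larger than roughly 70 ml or 100 ml are
commonly exclusionary for reperfusion therapy and trial enrolment. The
reference measurement — manual delineation of the infarct border on
every DWI slice followed by voxel counting — is too slow for the acute
setting, so two diameter-based shortcuts are used at the workstation:

* **od-value**: on the slice showing the largest lesion extent, the
  maximum lesion diameter *a* (cm) and the maximal diameter *b* (cm)
  perpendicular to it are multiplied, od = a·b. Cutoffs od ≥ 32 and
  od ≥ 42 flag lesions >70 ml and >100 ml; a calibrated polynomial
  V(od) = 1.1·od + 0.03·od² converts the score to millilitres.
* **ABC/2**: the ellipsoid approximation V = A·B·C/2 with A = a, B = b
  and C = (number of lesion-bearing slices) × slice thickness, all in
  cm, giving millilitres directly.

`strokevol` implements both estimators, the measurement geometry that
feeds them, gold-standard voxel volumetry, the diagnostic-accuracy
statistics used to compare them, and a synthetic lesion-phantom cohort
on which the whole chain can be validated with known ground truth.

## Measurement geometry

Measurements emulate an electronic caliper on a rendered binary mask:

* Each lesion pixel contributes its four **corner points** in physical
  millimetres (spacing applied per axis before any geometry). This is
  the edge-to-edge convention of a human reader and gives a single
  pixel a nonzero diameter (its diagonal). Only boundary pixels are
  expanded — interior corners can never be extreme points — which
  leaves the convex hull unchanged.
* *a* is the **maximum Feret (caliper) diameter**: convex hull of the
  corner set, then the exact maximum over hull-vertex pairs. On masks
  small enough for exhaustive search this equals the all-pairs maximum
  exactly (tested property).
* *b* is the **projected width** of the corner set onto the axis
  perpendicular to *a*'s direction (max − min scalar projection). The
  alternative readings of "orthogonal diameter" (longest chord
  intersecting *a*; longest in-mask segment) are narrower; projected
  width matches caliper practice and guarantees b ≤ a by Feret
  maximality.
* The **measurement slice** is the one maximising the per-slice Feret
  diameter; ties break to the lowest slice index for determinism.
  Disconnected pixels on a slice are measured as one point set (a
  reader spans the full hyperintense region).
* Slice count C counts slices with at least one lesion voxel; gaps are
  not interpolated. Slice thickness is taken as the center-to-center
  slice spacing from the NIfTI header unless overridden.
* Voxel volumetry (the gold standard): lesion voxel count × voxel
  volume / 1000, in ml.

Axis order is (slice, row, col) for arrays and spacing everywhere;
physical coordinates are voxel-centre based and 0-based. On loading, the
slice axis defaults to the lowest-resolution axis, which is correct for
thick-slice DWI; it is overridable for isotropic data.

## Estimators and classification

od and ABC/2 are computed in full precision; rounding to one decimal
(half away from zero, the convention of clinical tables) happens only at
presentation. The od cutoff comparison is inclusive (od ≥ cutoff) and
configurable; ground truth labels use a strict comparison
(manual volume > threshold). The polynomial maps the cutoffs 32 and 42
to 65.92 ml and 99.12 ml — within 6% and 1% of the 70/100 ml thresholds
they operationalise, so cutoff classification and volume-threshold
classification of the converted score are mutually consistent (the
polynomial is strictly increasing).

## Diagnostic accuracy

Sensitivity, specificity, accuracy, PPV and NPV are computed from the
2×2 table with exact Clopper–Pearson 95% intervals by default (the
conservative convention in diagnostic-accuracy studies; Wilson is
available). A zero denominator marks the metric undefined rather than
zero. The C-statistic is the rank-based ROC AUC with midrank tie
handling, identical to the pairwise definition
P(score⁺ > score⁻) + ½·P(tie); it is tested against a brute-force
pairwise oracle. Percent overestimation of the median is
100·(median(estimate) − median(manual))/median(manual).

`reconstruct_confusion` recovers (tp, tn) from published marginals
(n, prevalence, sensitivity, specificity) by exhaustive integer search,
erroring unless the solution is unique at one-decimal half-up rounding.
This lets printed accuracy/PPV/NPV values be verified when the
underlying patient data are unavailable. Reconstructed intervals may be
compared with published ones but are not asserted equal, since the CI
procedure behind published tables is often unstated.

## Synthetic cohort

The phantom generator replaces the (non-public) patient masks:

* **Shape**: triaxial ellipsoids, aspect ratios a/c and b/c drawn
  uniformly from 1.2–2.5 (acute MCA infarcts are elongated), uniformly
  random 3D orientation. A configurable fraction (default 0.7) receives
  a **concave perturbation**: six Gaussian radial "bites" (angular
  width 0.3–0.6 rad, depth 0.2–0.4 of the radius, scaled by
  `roughness`) carved into the surface. Bites model the irregular,
  non-convex geometry of real infarcts: they reduce volume while
  leaving the maximal calipers largely intact, which is exactly the
  regime in which ABC/2 overestimates. A mean-zero signed-bump mode
  (volume preserved in expectation) is also available.
* **Volumes**: log-normal with μ = ln 26 and σ = 1.305 fitted to a
  median of 26 ml and IQR 10.7–62.2 ml by quartile matching in log
  space; the implied tail mass (22% > 70 ml, 15% > 100 ml) reproduces
  observed large-infarct prevalences without further adjustment.
  Draws are truncated at 500 ml (resampled; ~0.8% of mass) to keep
  grids bounded. The draw targets the *actual lesion* volume — what
  manual volumetry measures — so concave specs have their semi-axes
  rescaled by the perturbation volume factor (the angular mean of f³
  over the unit sphere, evaluated by 2048-point Fibonacci quadrature).
* **Grids**: 1 mm in-plane pixels (an assumption — the source
  acquisitions' in-plane resolution is unstated; exposed in config) and
  per-patient slice thickness drawn from {2.5, 3, 4, 5} mm. A voxel is
  lesion iff its centre lies inside the surface (matching binary manual
  delineation; no partial volume). Lesions touching the grid boundary
  raise an error rather than silently truncating volume.
* **Ground truth**: the catalog stores the continuous lesion volume,
  the rasterized mask volume, and (a, b) of the widest slice computed
  by exhaustive corner-pair search on the mask — an oracle sharing the
  corner convention but independent of the hull-based production path.
  Closed-form cross-section ellipse axes (`analytic_inplane_axes`) are
  exported separately for continuous-geometry cross-checks; for
  perturbed lesions they describe the unperturbed envelope only.

What the phantoms do **not** emulate: DWI intensities (masks only),
multifocal lesions, lesion anatomy constrained by vascular territory,
partial-volume and motion effects, and inter-reader variability in
caliper placement. Accuracy figures measured on phantoms are therefore
upper bounds — classification of smooth convex-ish shapes by their own
diameters is far easier than on real infarcts (phantom C-statistics are
≈0.99 vs ≈0.85–0.87 reported on patients) — while *qualitative*
behaviour (ABC/2's positive median bias exceeding the calibrated
od-conversion's) does transfer and is asserted in tests.

## Numerical choices

* Corner points deduplicated with `np.unique`, so point order and all
  argmax tie-breaks are deterministic.
* Feret ties (multiple corner pairs at the maximum distance) resolve to
  the first pair in sorted order; slice ties to the lowest index.
* Degenerate inputs: empty masks raise `EmptyMaskError` in geometry and
  are flagged-and-excluded rows in the pipeline (exclusions are counted
  in the run manifest: n_input = n_evaluated + n_excluded, always).
* The b ≤ a invariant is enforced at construction of
  `DiameterMeasurement` (violation would indicate an internal bug,
  since a projection width cannot exceed the maximum caliper).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-patient seeds are drawn below 2³¹
  from the cohort seed, so identical configs give byte-identical
  catalogs.

## Problem sizes used in validation

The test suite and acceptance script run cohorts of 100–238 phantoms
(plus a 200-phantom concave cohort for the bias-direction check) at the
default grid resolutions; sphere-convergence checks use 0.5–5 mm
spacings. These sizes give sampling error comfortably inside the
asserted tolerance bands while keeping a full run in the order of
seconds.

## Known limitations

* The per-seed sample median of a 100-patient log-normal cohort has a
  ~±18% (1 SD) spread; the 20–33 ml recovery band is ~1.6 SD, so
  distribution-recovery checks are seed-sensitive by nature at that n.
* `analytic_inplane_axes` picks the widest of the *grid* slice planes;
  for very thick slices relative to lesion size the continuous optimum
  can fall between planes.
* The concave perturbation is radial (star-shaped lesions); real
  infarcts can be non-star-shaped (e.g. C-shaped cortical ribbons),
  for which diameter-based overestimation is typically even larger.
* No DICOM ingestion, no segmentation: inputs are binary NIfTI masks.
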