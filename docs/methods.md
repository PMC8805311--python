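# Methods

`rtsegeval` evaluates auto-segmented pelvic structure sets for prostate
radiotherapy along two axes — contour geometry and dosimetric consequence —
and ties the two together with cohort statistics. This note documents the
models, conventions and numerical choices; nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and grid conventions

All volumes live on regular axis-aligned lattices indexed `[z, y, x]` with
`+z` superior, `+y` posterior and `+x` patient-left (the DICOM LPS frame).
`spacing` and `origin` are mm per axis in the same order; the origin is the
*center* of voxel `(0, 0, 0)` and a voxel spans the half-open cube centered
on its center. Voxel indices are 0-based; patient-space coordinates are
continuous mm. These conventions are applied uniformly — in particular to
the anisotropic PTV margin, whose "posterior" direction is `+y`.

## Contours and masks

Structure sets are per-slice closed planar polygons (the RT-struct view).
Rasterization marks a voxel inside iff its *center* falls inside an odd
number of polygons on the corresponding plane (even-odd rule), which makes
holes work naturally and is exactly testable against an independent
point-in-polygon oracle. When contour planes are sparser than the grid
(3 mm planes on a 1 mm grid), intermediate slices copy the nearest
contoured plane, provided it lies within half the structure's inter-plane
spacing — the nearest-neighbour z-fill that accompanies nearest-neighbour
mask resampling.

Extraction traces the 0.5 iso-level of the binary field per axial slice
(marching squares), emitting inner loops for holes. On smoothly shaped
organs of clinically relevant size the two operations are near-inverses:
the test suite requires DSC >= 0.99 for `rasterize(extract(mask))` round
trips, including the trip through an RT-struct file on disk. A single-voxel
structure extracts to a 0.5 mm² diamond — the half-pixel bias of the
iso-level is the known cost of the convention and is negligible for organs
≥ 10 mm across.

Resampling uses nearest-neighbour interpolation for masks (so they stay
binary) and trilinear for images and doses; cropping produces blocks of an
exact voxel size centered on a point (the prostate center of mass in the
pipeline), zero-padding any overhang with a warning.

## Geometric metrics

* DSC = 2|A∩B| / (|A| + |B|); two empty masks compare as 1 with a warning
  rather than failing a whole cohort.
* Boundary points are centers of mask voxels with at least one
  face-adjacent (6-connectivity) background voxel; array edges count as
  background. This voxel-center convention is spacing-aware and
  oracle-checkable; mesh-based surfaces are out of scope.
* `HD_avg` is the mean of the *pooled* directed boundary-distance lists
  (both directions concatenated). The other common symmetrization — max of
  the two directed means — is available via
  `hd_avg(..., symmetrization="max_of_means")`, since the literature uses
  both and rarely says which.
* `HD95` is the 95th percentile (linear interpolation between order
  statistics) of the pooled list; q = 100 recovers the classical Hausdorff
  distance.
* For the rectum, prediction voxels on axial slices where the reference is
  empty are removed before scoring (`restrict_to_reference_slices`): the
  rectum-colon boundary is not reliably contoured, so superior
  over-segmentation is deliberately not penalized.

Surface distances use a KD-tree; the suite verifies exact agreement with
an O(n²) all-pairs oracle on random masks, plus translation invariance and
the orderings `HD_avg <= HD100`, `HD95 <= HD100`.

## Dose metrics

* The cumulative DVH is exact voxel counting (no partial volumes) sampled
  every 0.01 Gy by default; D- and V-parameters interpolate linearly
  between samples, so halving the bin width moves D98/D2 by less than one
  bin. Evaluated parameters follow the clinical set for this site:
  D98/D2/V95% for prostate and its 3 mm isotropic expansion (surrogate
  CTV), V50/65/70 Gy for rectum, V60/65/70 Gy for bladder. DVH parameters
  are always computed on the *ground-truth* structures, for both dose
  grids, so differences measure dosimetric consequence, not contour
  overlap.
* CTV-to-PTV margin expansion is anisotropic: 6 mm in all directions,
  5 mm posterior, per common clinical practice for this site. A voxel
  joins the expansion iff it satisfies the per-octant ellipsoid inequality
  built from the six directional margins — the standard way to blend
  unequal margins across octants. A zero margin pins that half-axis.
* Paddick conformity index CI = TV_PIV² / (TV · PIV), with PIV the volume
  enclosed by a prescription isodose. The isodose level is configurable
  and defaults to 95% of prescription (clinical reports rarely state the
  level; 95% matches the V95% coverage criterion used for the target).
* ICRU 83 PTV criteria: D98% >= 95% and D2% <= 107% of prescription,
  reported with the margin to each threshold.

## Gamma analysis

The 3D gamma index is *global*: the dose tolerance is a percentage of the
prescription (default 3% of 74 Gy), not of local dose, and the low-dose
cut-off (default 10% of prescription) is applied to the reference grid.
For each considered reference voxel,

    gamma(x) = min_r sqrt(|r|²/dta² + (D_eval(x+r) − D_ref(x))²/ΔD²),

with the evaluated dose interpolated trilinearly on a lattice refined 3×
per axis (search step = spacing/3 <= 1/3 voxel pitch). Offsets are visited
in shells of increasing physical length; a voxel's search terminates when
the shell radius alone exceeds its current best gamma × dta (no further
offset can improve it), which makes the minimum exact on the search
lattice without a fixed radius cap. By default a voxel also stops as soon
as it is known to pass (gamma <= 1 found) — its map entry is then an upper
bound <= 1 — because pass/fail and the pass rate are what the analysis
reports; `exact_map=True` refines every voxel. Offsets leaving the
evaluated grid are skipped. Pass/fail per voxel is validated against an
exhaustive 0.1 mm-lattice oracle, excluding voxels within ±0.05 of
gamma = 1 where the two search lattices may legitimately disagree. The
reference is always the plan optimized on ground-truth contours; the
metric is asymmetric by construction.

## Synthetic phantom and surrogate dose

No public clinical data exist for this pipeline, so the cohort is
synthetic. The phantom puts three organs on a (default) 160³ × 1 mm grid,
later cropped to 128³ around the prostate center of mass: a ~31 cm³
ellipsoidal prostate (semi-axes 17/20/22 mm), an ellipsoidal bladder
superior-anterior of it, and a curved rectal tube (radius 11 mm) posterior,
bowing away from the prostate plane. Organ masks are validated disjoint and
in-grid. Image intensities are HU-like constants per organ plus Gaussian
noise, clamped to the soft-tissue window [−150, 150] HU.

Perturbed "auto-segmentation-like" contours are drawn from the
augmentation family used to train segmentation networks on such data:
rotations up to 20°/10°/10° about the SI/AP/ML axes, translations up to
10 mm per axis, per-axis zoom in [0.9, 1.1], and a smooth deformation
defined by Gaussian shifts on a 15³ control-point grid, each component
applied with probability 0.93. Composition order is fixed as
zoom → rotation → translation → deformation (the augmentation literature
does not fix one); resampling is nearest-neighbour about the grid center so
outputs stay binary, and zero magnitudes reproduce the input bit-exactly.
The deformation is implemented as a backward displacement field, cubically
interpolated from the control grid. The control-point sigma defaults to
3 mm — one tenth of the raw training-augmentation setting of 30, which is
calibrated for intensity-image augmentation; at full strength it produces
anatomically implausible contours, which a *perturbation* model must avoid.
The sigma's unit (mm of control-point displacement) is our reading of an
underdocumented setting and is configurable.

The surrogate dose model replaces a commercial treatment planning system:
prescription dose (74 Gy in 37 fractions) inside the PTV, and outside it a
decay of one decade per fall-off length (default 10 mm, matching the ~1 cm
low-dose fall-off objective of a VMAT prostate plan) in Euclidean distance
from the PTV surface, floored at 2% of prescription (the low-dose bath).
Smooth plateau noise (0.5 Gy SD, 5 mm correlation length) models
within-target heterogeneity and is added inside the PTV only, preserving
the monotone radial decrease outside. This reproduces the features the
metrics measure — plateau, steep PTV-edge gradient, conformal isodoses,
low-dose bath — but not multi-beam streak structure, tissue heterogeneity
or optimizer trade-offs; passing tests demonstrate the pipeline's
correctness, not planning-system realism.

Cohorts derive per-case seed streams from one root seed
(`numpy.random.SeedSequence.spawn`), so any case is reproducible in
isolation. The two dose grids of a case share the plateau-noise stream:
with zero-magnitude perturbation they are bit-identical, mirroring a
planning system re-run with fixed settings on the same contours.

## Statistics and reporting

Paired DVH parameters are compared with the two-sided Wilcoxon signed-rank
test at alpha = 0.05 (scipy's implementation behind the module surface):
zero differences discarded (Wilcoxon's original rule), exact null
distribution for n <= 25 non-zero pairs, normal approximation above; fewer
than 5 pairs yields a warning and no p-value, all-zero differences the
defined "no evidence" result. The test suite checks the exact p against
full 2^n enumeration. Geometric-dosimetric association uses the Pearson
correlation with a two-sided t-test (df = n − 2); constant inputs are
reported as undefined rather than dropped. No multiple-testing correction
is applied, matching common practice for such cohort reports. Cohort
summaries report mean and *sample* SD (ddof = 1); reporting precision is
2 decimals for DSC/CI, 1 for HD, whole percent for gamma, with raw values
always retained.

The bundled clinical reference table (11 patients; DSC, HD_avg, HD95 per
organ, conformity indices of both plans, gamma pass rate) is transcribed
reference data from a published clinical evaluation of deep-learning
pelvic auto-segmentation — it is loaded and summarized, never recomputed,
since the underlying images and plans are not shareable. One documented
inconsistency: the bladder DSC column of that table averages to 0.96 while
its printed summary row says 0.97 (a companion comparison table prints
0.96 ± 0.01); bladder DSC and bladder HD_avg summary values are therefore
not used as hard reproduction gates. Similarly, recomputing the
prostate-DSC vs gamma Pearson r from the rounded per-patient values gives
≈ 0.68 where the original analysis of unrounded data reported 0.67
(p = 0.023); both are reported, neither is forced.

The plan-consistency check mirrors the calibration experiment used to
validate that planning is stable under contour format conversion: ground
truth contours → RT-struct file → masks → re-derived PTV → regenerated
dose, requiring every DVH parameter of the re-planned dose within ±2%
(relative) of the original.

## Problem sizes and determinism

Unit and property tests run on grids ≤ 20³ where brute-force oracles are
exact and cheap; oracle-equivalence sweeps use 100 random grids. End-to-end
tests use a compact phantom (96³ grid, 64–80³ crops) with 11-case cohorts,
the cohort size of the clinical test set; `scripts/acceptance.py` runs the
full-size phantom (160³, 128³ crop). All generators are pure functions of
spec and seed, and the pipeline is bit-reproducible for a fixed root seed.

## Known limitations

* The surrogate dose is star-shaped around the PTV; genuinely non-convex
  targets could violate the along-ray monotonicity the model guarantees
  for clinical-like anatomy.
* Gamma pass/fail near gamma = 1 depends on the search lattice; the 1/3
  voxel default matches common QA practice but borderline voxels can flip
  relative to a finer search.
* No inter-observer contour model, CT artifact physics, femoral-head
  reporting, or biological indices (EUD/NTCP/TCP). Gamma normalization is
  global only (percent of prescription); local-dose normalization is not
  implemented.
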