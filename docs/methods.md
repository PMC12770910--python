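# Methods

`craniomorph` measures extracranial head tissues — skull, subcutaneous fat
and temporalis-type muscle — from voxelwise tissue masks, the kind produced
by modern deep-learning head segmenters from T1-weighted MRI or by HU
thresholding of CT. The toolkit itself contains no learned components: it is
the geometry and statistics layer that turns masks into comparable numbers.

## Coordinate conventions

All operations run in one canonical voxel frame: axis 0 increases
posterior→anterior, axis 1 left→right, axis 2 inferior→superior (nibabel
axis codes `('A','R','S')`). NIfTI files are reoriented on read and the
transform is recorded so writes restore the on-disk layout. Indexing is
0-based; slice bands are half-open intervals; "slice z" is the axial plane
at index z. The anterior-crop equations below are meaningless without a
declared anterior axis, which is why the frame is enforced at the I/O
boundary rather than trusted per call.

Inputs are expected at ~1 mm isotropic spacing (the usual post-registration
resolution). Volumetrics accept any spacing — voxel counting scales exactly
— but the thickness pipeline refuses in-plane spacing outside [0.9, 1.1] mm,
because its millimetre constants (band extent, ray step) would silently
mis-scale on coarser grids.

## Anterior ROI standardization

Publicly shared head MRI is defaced, and every defacing tool removes a
different amount of face and forehead, so raw extracranial volumes are not
comparable across datasets. The standardization uses the brain mask S, which
defacing never touches. Per axial slice z, the most anterior brain voxel is

    T(z) = max{ x : ∃y, S(x,y,z) = 1 },    T(z) = 0 for empty slices,

propagated inferior→superior as a running maximum,

    T*(z) = max(T(z), T*(z−1)),   T*(−1) = 0,

so the cutting plane never moves posteriorly while ascending the head; all
voxels with x > T*(z) are zeroed in masks and images alike (the boundary
voxel itself is kept — only the strict inequality is removed). Consequences
used as test oracles:

- no brain voxel is ever removed (each sits at x ≤ T(z) ≤ T*(z));
- cropping is idempotent and anti-extensive;
- any defacing that removed only voxels strictly anterior to T*(z) of the
  intact volume yields a voxel-identical standardized ROI.

Slices with no brain (neck) inherit the running maximum from below, i.e.
T*(z) = 0 at the bottom of the volume, where the crop keeps only the x = 0
plane. That is the recurrence taken literally; callers who want to exclude
the neck slab entirely can pass `only_brain_slices=True`, which zeroes
non-brain-intersecting slices without altering the core recurrence.

## Volumetrics

Per-class volumes are voxel counts times voxel volume, reported in cm³
alongside the raw counts so unit errors are auditable. No partial-volume
modelling: the inputs are hard masks, and pretending to sub-voxel accuracy
would be spurious. Percent change against a reference report is
`100·(test−ref)/ref` per class; 0/0 is defined as 0, x/0 is flagged
undefined rather than silently dropped.

## Skull thickness

Thickness is estimated on axial cross-sections of the binary skull mask,
which are ring-shaped in the measurement band. Per slice:

1. largest connected component → fill holes → largest enclosed hole is the
   cranial cavity; a slice without a cavity (solid blob) is degenerate and
   skipped;
2. outer and inner contours are extracted as sub-voxel 0.5-level curves
   (`skimage.measure.find_contours`);
3. 100 sample points are placed uniformly by arc length on the outer
   contour, starting at its most anterior vertex (ties broken by smallest
   lateral index) so sampling is reproducible;
4. at each sample the local tangent is a central difference over contour
   neighbours ±2 samples away; the measurement ray runs along the *inward
   normal*. A tangent line has no finite chord through the shell, so the
   normal chord is the geometrically meaningful realization of a
   "tangent-based" measurement, and is what this package computes;
5. the ray marches in 0.25-voxel steps (max 50 mm). It must enter the mask
   within ~2 voxels of the contour; thickness is the distance from the
   contour point to the midpoint of the mask→cavity crossing. Rays that
   leave the slice, never exit, or exit into a non-cavity air pocket
   (frontal sinus, orbital air) are *missing*, not zero — this is how sinus
   anatomy is kept from biasing the estimate.

The measurement band starts 10 mm superior to a reference slice z0
(anatomically the top of the orbital roof, supplied by the caller; a crude
closed-ring heuristic exists behind `--auto-z0` for phantoms and QC only)
and covers 16 mm of physical extent — `round(16/spacing_z)` slices, which is
16 slices at 1 mm. Valid samples from all band slices are pooled, the pool
is trimmed to its central 95% (2.5–97.5 percentiles, linear interpolation
between order statistics), and the median of the kept values is reported
with full audit counts. Trimming per slice before pooling is exposed as
`per_slice_trim=True`; on near-constant phantom data the two differ by well
under a voxel. Fewer than 160 valid samples (≈10% of the nominal 1600) is an
error, not a number.

The CT reference mask is `HU > threshold` (strict, default 471 HU) followed
by largest-connected-component cleanup. A threshold above every bone voxel
returns an empty mask with a warning — the caller decides whether to exclude
the scan — rather than crashing a batch.

## Agreement statistics

- **Dice**: `2|A∩B|/(|A|+|B|)`; two empty masks score 1 (agreement on
  absence) by documented convention.
- **HD95**: surface voxels are mask voxels with a face-adjacent background
  neighbour (the volume border counts as background). Surface points are
  scaled by spacing, directed nearest-neighbour distances computed both ways
  with a KD-tree (exact), pooled, and the 95th percentile taken. Pooling
  both directions into one distribution is one of several HD95 conventions;
  it is symmetric by construction and bounded by the exact Hausdorff
  distance.
- **Bland–Altman**: bias = mean(y−x), limits = bias ± 1.96·SD(y−x) with
  sample SD.
- **Gwet AC1** for two raters: with observed agreement `pa` and mean
  marginal proportions `π_q`, `pe = Σ_q π_q(1−π_q)/(Q−1)` and
  `AC1 = (pa−pe)/(1−pe)`. The CI uses Gwet's subject-level linearized
  variance with a normal approximation, truncated above at 1. Subjects
  missing either rating are dropped (pairwise-complete), with the retained
  count reported. AC1 equals 1 iff pa = 1, is invariant to category
  relabeling, and is near 0 for independent uniform ratings — all of which
  the suite checks.

## Digital head phantoms

The phantom generator exists so every pipeline stage can be validated
against closed-form truth without imaging data. Phantoms are geometric, not
anatomical: concentric ellipsoids for brain (default semi-axes 55/60/50 mm),
a 2 mm CSF gap, a skull shell of exactly known wall thickness (default
5 mm), a 4 mm subcutaneous fat layer, two lateral ellipsoidal muscle patches
abutting the skull (temporalis-like), and a nose-like fat protrusion
anterior to the skull so defacing and the anterior crop have something to
remove. Defaults were chosen once to sit in the adult anatomical range at
1 mm isotropic on a 160³ grid; brain and skull truth volumes are analytic,
fat/muscle truth is voxel-derived because the compartments intersect.
CT appearance is piecewise-constant HU (air −1000, brain 40, muscle 50, fat
−100, cortical bone 1000; an optional 450 HU cancellous inner half-wall
gives the two-density skull used for threshold sweeps); T1 appearance has
fat bright and bone dark. Optional Gaussian noise is seeded; identical specs
produce bit-identical volumes.

The perturbation harness mirrors the robustness checks a real pipeline
needs: ±5° pitch about the left-right axis (nearest-neighbour for labels,
linear for intensities, same grid); gamma 0.7/1.5, brightness ±0.2 (no
clipping, so the pair is an exact inverse) and min-max rescaling to
[0, 1.2]; and three defacing styles (coronal plane, boundary-following
wedge, and maximal "aggressive" removal) that all stay strictly anterior to
the intact propagated boundary, the regime where ROI standardization must be
exactly invariant.

What phantoms do **not** emulate: MRI physics (bias fields, partial volume,
sequence contrast), real segmentation errors, open or pneumatized anatomy
(sutures, mastoid air cells), pediatric geometry. Passing the suite
demonstrates geometric and statistical correctness of the measurement code,
not segmentation accuracy on real scans.

### Why the thickness-validation band is centred on the equator

An axial slice of a spherical shell is an annulus whose in-plane width
exceeds the true 3-D wall thickness away from the equator (by the factor
1/cos of the surface inclination). Real skulls are measured where the vault
walls are near-vertical; the phantoms reproduce that regime by placing the
16 mm band symmetrically about the shell equator (z0 = equator − 18 slices,
so the band spans equator ± 8 mm). For the default 40 mm shells the residual
obliquity inflates the width by < 0.2 mm, well inside the 1-voxel
recoverability bound the suite enforces for walls of 3–10 mm.

## Numerical choices

- Ray step 0.25 voxel, max ray 50 mm; thickness read at the crossing
  midpoint, giving ≤ half-step quantization (~0.125 mm at 1 mm voxels).
- Percentiles: NumPy linear interpolation throughout.
- Normal orientation at each contour sample is chosen by probing mask
  occupancy at ±0.75–1.75 voxels along the candidate normal.
- Tilt uses `scipy.ndimage.rotate` on the fixed grid; label interpolation is
  nearest-neighbour, so a +5°/−5° round trip loses a little mask (Dice
  ≥ 0.98 on the skull class is the tested bound).
- Problem sizes in the test and acceptance harnesses (160³ full phantoms,
  120³ shells, ≤ 32³ random masks for brute-force oracles, 12 blob pairs for
  the exhaustive HD95 oracle) keep the whole matrix of phantoms ×
  perturbations × pipelines comfortably under a minute while leaving the
  discretization bounds meaningful.

## Known limitations

- Thickness is outer-table-to-inner-table along in-plane normals; it does
  not decompose cortical vs cancellous bone and has no sub-voxel
  partial-volume model.
- The reference slice z0 is an input; the bundled heuristic is a
  convenience, not an anatomical detector.
- The anterior crop assumes the brain mask is trustworthy; an over-eroded
  brain mask moves the boundary posteriorly and removes real tissue.
- Gwet AC1 is implemented for one rater pair; multi-rater generalizations
  are out of scope.
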