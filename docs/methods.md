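# Methods

## Scope and model

`petcoreg` simulates, end to end, how rigid coregistration of FDG-PET with CT
perturbs PET quantification. The chain it models is the clinical one: a PET
volume reconstructed on a coarse grid (4.1 × 4.1 × 5.0 mm) is aligned to a CT
study — either a 1-mm diagnostic CT ("CT1", 1.4 × 1.4 × 1.0 mm voxels) or a
5-mm low-dose CT ("CT5", 1.4 × 1.4 × 5.0 mm) — by a rigid (6-DOF) transform,
and the transformed PET is written out *in the CT geometry* by trilinear
resampling. Lesions are then delineated and quantified (SUVmax, metabolic
tumor volume MTV, total lesion glycolysis TLG = MTV × SUVmean) on the
resampled data. Because patient images are replaced by digital phantoms with
analytic ground truth, every stage of the chain can be verified exactly.

The central mechanism is trilinear interpolation: the value at an off-grid
point is a convex combination of the eight surrounding voxel values. Three
consequences drive everything the package measures:

1. a translation by an exact multiple of the voxel size onto an identically
   spaced grid moves data without interpolating it at all — deviations vanish;
2. a shift near half a voxel maximizes interpolation, which acts as a local
   smoothing — the apparent maximum can only decrease (convexity bound), so
   SUVmax is biased downward and relative thresholds move with it;
3. the coarser the target grid relative to the structure, the larger the
   effect — CT5's 5-mm slices match the PET slice spacing, so axial sampling
   phase matters, while CT1's 1-mm slices sample the interpolant densely and
   deviations nearly disappear.

## Coordinate conventions

World coordinates are millimetres. A grid's `origin` addresses the *center*
of voxel (0,0,0); sampling happens at target voxel centers. Rigid transforms
are parameterized as intrinsic Z-Y-X Euler angles (degrees) about an explicit
center plus a translation; `resample_volume(src, T, target)` evaluates
`src(T⁻¹(x))` at every target voxel center, i.e. `T` maps source (moving)
space into target (fixed) space, so a registration result can be applied
directly. Out-of-field values are filled with 0 SUV (air background).

Numerical choice: continuous indices within 1e-9 voxel of an integer are
snapped to it before interpolation. IEEE division (`i·4.1/4.1`) does not
return exact integers, and without snapping the identity resample would not
be bit-exact nor integer shifts interpolation-free; with it, both exactness
properties hold to machine precision.

## Phantoms

A lesion is an analytic sphere or ellipsoid of constant uptake over a lung
background (default 0.4 SUV), optionally with a cold concentric necrotic core
(radius fraction 0.5, core at background — the "central necrosis" morphology).
Generation is: center-inclusion voxelization, convolution with an isotropic
Gaussian of 5 mm FWHM (the reconstruction filter; σ = FWHM/2.3548, applied to
the background-subtracted activity so lesion-excess activity is conserved),
then i.i.d. Gaussian noise (default SD 0.2 SUV, a moderate clinical
reconstruction-noise level; no canonical value exists for the emulated
protocol, so noise is a free parameter and key properties are checked at
zero and moderate noise), clipped at 0 SUV. Each phantom carries its exact analytic volume and its
voxelized support, enabling delineation-accuracy checks a patient study
cannot perform.

The cohort generator draws 28 lesions with log-uniform volumes in 1.1–27.2 ml
and uniform uptake in 1.6–30.9 SUV (the solid-lung-lesion cohort ranges the
simulation emulates), 25 %
of them necrotic, centers jittered by up to half a PET voxel so grid phase
varies across lesions; per-lesion seeds are master seed + index.

The pseudo-CT counterpart maps the same anatomy with unrelated intensities:
lung at −750, lesion soft tissue at +40 (HU-like), necrotic cores *not*
reproduced (solid on CT), 1 mm blur and independent 60-HU noise. This keeps
the PET↔CT intensity relation non-monotone (|r| < 0.9 by construction), so
cross-modality registration genuinely requires mutual information.

What the phantoms do **not** emulate: projection/reconstruction physics
(OSEM, attenuation, scatter), respiratory motion, irregular lesion shapes,
and spatially correlated noise. Passing tests therefore demonstrate the
interpolation/segmentation mechanism, not absolute clinical effect sizes;
patient-cohort effect sizes reported in the literature (median SUVmax shifts
near −9 % after coregistration to 5-mm CT) are qualitative references only,
since they depend on image texture this generator does not reproduce.

## Registration

Similarity is Shannon mutual information (bits) of the joint intensity
histogram (64 × 64 equal-width bins spanning each image's range) between
fixed-image samples and the moving image read through the candidate
transform; out-of-field samples are discarded. Two modes differ only in
sampling density of fixed-grid voxel centers — "fast" 5 %, "slow" 50 %
(an order-10 work ratio). Samples are drawn without replacement, seeded, and
preferentially from an informative pool (voxels deviating from the image
median by >10 % of the range, dilated 2 voxels): uniform sampling wastes
almost all samples on homogeneous background where MI carries no alignment
signal.

The optimizer is derivative-free Powell search: translation-only first, then
the full 6 DOF from that start (initial step 0.5 mm/deg), followed by seeded
random-restart Powell runs keeping the best MI — rotation–translation
coupling leaves shallow local optima that a single descent can stall in.
Inside the optimizer the histogram uses first-order (linear) bin assignment
so MI varies continuously with the parameters; the public `joint_histogram`
keeps hard counts (total = number of in-bounds samples). Tolerances:
1e-3 mm/deg parameter convergence, 200 iterations per stage.

Identifiability caveat: a single blurred sphere is rotationally symmetric and
its MI surface is flat in rotation; validation scenes therefore use several
lesions at large radii (long lever arms). On 5-mm-slice targets the axial MI
signal is additionally degraded by grid-phase artifacts; the validation scene
uses an isotropic 2.5 mm structural grid, under which both modes recover a
6-DOF misalignment to a few tenths of a millimetre and of a degree.

## Segmentation

Four threshold methods operate inside a lesion VOI (a box around the lesion
with margin), each returning the 26-connected component containing the VOI
maximum (ties broken at the lowest linear index):

* **T40/T50/T60** — all voxels with *at least* 40/50/60 % of the measured VOI
  maximum (boundary voxels included; the maximum is re-measured on each image
  being segmented, never carried across images).
* **AT** — background-adapted volume-reproducing threshold: fixed-point
  iteration of (i) estimate the local background as the mean over a shell 2–3
  dilation steps outside the current mask (26-connectivity, restricted to
  the VOI, other lesions excludable), (ii) re-threshold at
  `B + f·(max − B)`. The start mask thresholds at `B₀ + 0.40·(max − B₀)`
  with `B₀` the 25th percentile of the VOI — a robust background proxy that
  reduces to a plain T40 start on cold background and makes every step, and
  hence the converged mask, exactly invariant under a global additive
  intensity offset (the property separating background-adapted from fixed
  thresholding). Oscillations that never settle return the last mask flagged
  non-converged.

The volume-reproducing fraction defaults to f = 0.5: once a blurred sphere's
maximum is fully recovered, its edge profile crosses `B + 0.5·(max − B)`
exactly at the true boundary, so 0.5 is the analytic large-lesion value.
`calibrate_volume_reproducing_fraction` refines f by exhaustive grid search
(step 0.01 over 0.2–0.8) minimizing mean squared relative volume error on
sphere phantoms spanning ≥ a decade of volume; on the package's calibration
set it lands at f ≈ 0.41, consistent with values reported for
background-subtracted volume-reproducing thresholding in the literature, and
recovers noise-free blurred-sphere volumes within 15 % (partial-volume loss
makes small spheres the hardest). The exact update rule of the commercial
implementation this emulates is unpublished; this scheme is a documented,
testable stand-in honoring "volume-reproducing threshold after subtraction
of local background".

## Quantification

SUVmax is the VOI maximum, so all delineation methods share one SUVmax per
lesion and per-method comparisons isolate volume effects; MTV is voxel
count × voxel volume (ml, no
partial-voxel correction); SUVmean averages over the mask; TLG = MTV × SUVmean
holds to machine precision in every emitted record. Deviations are
`100·(coregistered − original)/original` per quantity, signed and unsigned.

## Study design

For each lesion the "OR" baseline resamples the original PET onto the target
CT grid with the identity transform (hardware coregistration); the
coregistered arm applies a rigid transform — the known ground-truth
misalignment in "oracle" mode, or an MI-estimated one in fast/slow modes —
and resamples onto the same grid. Both arms are segmented independently with
all four methods and compared per lesion. Misalignments are sampled uniformly
in ±1.5 PET voxels per axis and ±2° per rotation axis — magnitudes
representative of residual clinical misalignment, sub-voxel by design so
interpolation is active — with options for translation-only and for
snapping to exact voxel
multiples (the zero-interpolation control). The cohort experiment runs in
oracle mode: it isolates the resampling effect and keeps a 28-lesion,
two-grid, four-method study to a few seconds; the registration estimator is
validated in its own dedicated experiment.

Deviation tables are summarized per (grid, mode, method) with mean, median,
IQR and range of signed and unsigned differences (quantiles by linear
interpolation between order statistics), a two-sided Wilcoxon signed-rank
test against zero, and Bland-Altman mean/SD with 95 % limits of agreement
(±1.96 SD; ±2 SD is emitted alongside for plot annotation, mirroring the
field's mixed usage). Wilcoxon drops zero differences and average-ranks ties;
p is exact (shift-algorithm null distribution) for n ≤ 12 and a
tie-corrected, continuity-corrected normal approximation above. Lesions are
treated as independent even when a patient contributes several — the common
practice in such analyses — and no LoA confidence intervals or mixed-effects
modeling are attempted.

## Mechanistic experiments

* **Shift sweep** — a noise-free necrotic phantom is shifted by fractions of
  the source voxel size along one axis and re-quantified: deviations vanish
  at fractions 0 and 1 and peak near 0.5, symmetric about the half-voxel.
* **Heterogeneity contrast** — a necrotic lesion (r = 11 mm, core at half
  radius) vs a volume-matched solid twin at a half-slice axial shift on CT5.
  The necrotic maximum sits on a thin rim that interpolation flattens
  (SUVmax ≈ −6 to −10 %), dragging the relative threshold down and ballooning
  the mask (MTV ≈ +9 %), while the solid lesion's plateau maximum is stable
  and its volume barely moves. The demonstration uses T40, where the
  threshold sits on the shallow outer edge and translates the maximum drop
  into the largest boundary motion; AT's steeper-edge threshold partially
  compensates the effect. On coarse 5-mm slices, smooth idealized phantoms
  additionally show a discretization artifact real, irregular lesions
  average away: near-flat "pole caps" crossing the threshold coherently as
  slice phase changes. The contrast experiment reports median-stable
  settings (verified across ten noise seeds), but per-seed MTV values on
  CT5 retain a few percentage points of this quantization.

## Problem sizes and defaults

Default experiment sizes are chosen so the full test suite and the
acceptance script each run in minutes on one core: lesion-local grids
(lesion radius + 25 mm margin per side), a 28-lesion cohort per replicate,
five replicates for the grid-coarseness comparison, 20 seeded repetitions
for the fast/slow registration contrast, and an 11-point shift sweep. All
randomness flows from explicit seeds; identical configurations produce
byte-identical CSV outputs.

## Known limitations

* Only threshold-based delineation is implemented; gradient- or model-based
  methods may respond differently to interpolation.
* The registration validation covers small misalignments (±1.5 voxels, ±2°)
  from an identity start; large-capture-range registration (multi-resolution
  pyramids) is out of scope.
* Phantom noise is white; reconstructed PET noise is spatially correlated,
  which damps single-voxel maxima less than blur-matched white noise does —
  another reason cohort effect sizes here are smaller than the published
  patient values.
* NIfTI I/O stores geometry in the format's float32 affine; round trips are
  exact only to single precision.
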