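# Methods

## The mediator framework

Affine (12-parameter) registration of a whole-head T1-weighted volume to a
template fails surprisingly often in practice: clinical sagittal
acquisitions carry large fields of view with bright neck and shoulder
tissue, and brain position, orientation and anatomy vary widely, so an
intensity-driven optimiser started from scratch can settle far from the
correct alignment.  The mediator framework sidesteps the hard
subject-to-template problem by maintaining a library of intermediate images
(*mediators*) whose transforms into the template space were established
once and quality-controlled.  A new subject is registered to each mediator
— a much easier problem whenever some mediator resembles the subject — and
the final subject-to-template map is the composition

    T_s→m*→t = T_s→m* ∘ T_m*→t

where `m*` is the selected mediator.  Everything then reduces to (a) a
reliable pairwise affine engine, (b) a selection rule for `m*`, and (c) a
way to keep the library small.

All transforms in this package are **pull-backs** on RAS+ world (mm)
coordinates: a transform labelled `a→b` maps a world point of space *b* to
the corresponding point of space *a*, which is exactly what resampling
needs and makes the composition above a single matrix product
`T_s→m.matrix @ T_m→t.matrix`.  The 12 parameters are ordered (rotations
in degrees, intrinsic Z-Y-X; translations in mm; scales; upper-triangular
shears), applied scale → shear → rotation → translation; the
decomposition back from a matrix is a QR factorisation with positive
diagonal, unique for positive scales and rotations within ±90°.

## Registration engine

The cost is the **ratio image uniformity** (RIU): the coefficient of
variation, sd/mean with the sample (n−1) standard deviation, of the
voxelwise ratio fixed/moving over an overlap domain.  The domain keeps
voxels where each image exceeds 5% of its own robust maximum (99th
percentile), which excludes air without any segmentation.  RIU is exactly
zero for proportional images, so no intensity normalisation is needed.
The global (non-partitioned) form is used.

Optimisation is coarse-to-fine over a Gaussian pyramid (factors 4, 2, 1;
smoothing σ = factor/2 voxels before decimation), initialised by a
centre-of-mass translation.  The default optimiser is **L-BFGS-B on an
analytic gradient** of the RIU obtained by the image-gradient chain rule;
for speed the optimiser evaluates the cost on a deterministic strided
subsample (≤40 000) of fixed-image foreground voxels, while the reported
final cost is always the full-grid RIU at the returned transform.  A
derivative-free Powell mode with per-parameter step scaling
(1° ≙ 1 mm ≙ 0.01 scale ≙ 0.01 shear) is available through
`optimizer_name="powell"`; it reaches the same optima but needs roughly an
order of magnitude more cost evaluations, which is why it is not the
default.

Two structural choices guard against the characteristic failure mode of
12-dof fits on smooth head images, where a wrong rotation can be almost
perfectly compensated by shear at coarse resolution:

* the **coarsest level is rigid-only** (rotation + translation); scales and
  shears open from the next level, where enough structure survives the
  smoothing to separate them from rotation;
* a deterministic **3×3×3 rotation grid** (default ±10°) is probed at the
  coarsest level; the best three cells are refined there, the two best
  survivors are refined again at the mid level, and a single winner
  continues.  There are no stochastic restarts anywhere — identical inputs
  give bit-identical transforms.

On noiseless default-scale phantoms this recovers ground-truth affines
with mean brain-voxel displacement well under 1 mm at roughly 2–4 s per
registration on one CPU core.

## Similarity criteria and evaluation

* **SSD** — Σ(Xᵢ−Yᵢ)² over the mediator's whole grid, with the subject
  resampled onto it (out-of-FOV voxels resampled as 0) and the mediator
  first **histogram-matched** to the resampled subject (256-level
  empirical-quantile mapping).  Smallest SSD wins.
* **MI** — mutual information in bits from a 64×64 equal-width joint
  histogram over each image's [min, max]; no intensity matching, zero-count
  cells contribute nothing.  Largest MI wins.  Raw (unnormalised) MI is
  used; only the argmax matters for selection, which any monotone
  normalisation leaves unchanged.
* **Oracle Dice** — when ground-truth masks exist, the subject mask is
  carried to template space through each candidate's composed transform
  and scored as 2|X∩Y|/(|X|+|Y|) against the template mask.  This is the
  "true best" upper bound, unavailable in practice.

Registration quality is always reported as the Dice of brain masks in
template space, with Dice > 0.85 counted as a successful alignment (a
config default, not a constant).  Masks travel with nearest-neighbour
interpolation so they stay binary; ties in any criterion break toward the
first mediator in library order.

## Library shrinkage

Every ordered mediator pair is cross-registered and scored by
histogram-matched SSD; the two directed values are averaged into a
symmetric dissimilarity matrix with zero diagonal (a failed pair is imputed
with its row maximum and flagged).  Complete-linkage agglomerative
clustering — the default of the R heatmap tooling this mirrors — is cut to
k groups, and each group keeps its **medoid** (member minimising summed
within-cluster dissimilarity; ties toward the earliest id).  Cuts of one
dendrogram at decreasing k are nested, so the best-achievable Dice over a
shrunken library is non-increasing in shrinking k by construction.

## Synthetic phantoms

The generator emulates the features that make this problem hard, not MR
physics.  A canonical anatomy is built from nested compartments (WM core,
GM shell, CSF rim, skull shell; T1-like mean intensities) on a 96³ grid at
2 mm (default desk scale — a full multi-mediator cohort run finishes in
minutes; larger grids are a config option).  Three aspects deserve
explanation:

* **Internal structure.**  Pure nested ellipsoids are affinely degenerate:
  a rotated ellipsoid equals a sheared one, so no intensity cost can
  recover rotations on them.  Lateral-ventricle, thalamus-like and
  off-axis lobe structures anchor the pose the way real anatomy does.
  Their strong per-seed jitter (±25%) also carries most of the
  between-anatomy variation, mirroring real cohorts where ventricle volume
  varies far more than the brain envelope; the envelope itself varies
  gently (±2% axis jitter plus 2% low-order harmonic surface modulation)
  so that exact ground-truth transforms of different anatomies still
  overlay their masks with Dice ≈ 0.95–0.98.
* **Anatomy-attached neck.**  The bright neck block is defined below the
  brain in the source sample's coordinates and carried through the pose,
  as a real neck moves with the head; it enters an enlarged inferior FOV
  differently for every pose.  (A grid-attached slab would misalign with
  the head by the full pose difference and corrupt even perfect brain
  alignments.)
* **FOV asymmetry.**  Test subjects get a generous padded FOV (24 mm per
  face, air in the margin), mediators keep a tight grid — matching the
  clinical situation where incoming sagittal scans cover more than a
  curated library image.  This matters for whole-image SSD: it guarantees
  the subject's data covers the mediator's grid after alignment, so the
  zero-fill convention penalises misalignment rather than FOV geometry.

Noise is additive Gaussian (σ = 4 intensity units against tissue means of
45–210) and the multiplicative bias field is a smooth ±10% low-frequency
random field — deliberately simple; no claim of Rician statistics or
k-space fidelity is made.  Every sample stores its exact pull-back into
canonical space, and cohort subjects record which mediator's anatomy
generated them, so selection accuracy is checkable against construction.
All randomness flows from explicit integer seeds; identical calls are
bit-identical.

What passing tests on these phantoms show: that the engine recovers known
affine truth, that the selection criteria identify anatomy-matched
mediators against realistic nuisance (noise, bias, neck, FOV), and that
composition and shrinkage behave as the algebra dictates.  What they do
not show: performance on real MRI contrast, non-affine anatomy
differences, or pathology — the phantom anatomy family is far narrower
than any human cohort.

## Numerical notes and limitations

* Trilinear interpolation everywhere for images (exact at lattice points),
  nearest-neighbour for masks; out-of-grid samples are 0.
* Histogram matching uses linear interpolation between 256 quantile knots;
  outputs are monotone in the input by construction.
* The RIU overlap floor (5% of the 99th percentile) assumes air is dark;
  inverted-contrast data would need a different floor rule.
* `register_affine` reports `converged=False` and returns the best
  incumbent when no pyramid level improved on the initialisation.
* On these phantoms the *direct* subject-to-template route often matches
  or beats the mediator routes — this engine handles the neck/FOV
  variation robustly, so the cohorts here do not reproduce the
  catastrophic direct-registration failures that motivate the framework on
  real heterogeneous data.  The comparison machinery reports whatever the
  data give; no ordering involving the direct mode is asserted anywhere.
* Pairwise library registration is embarrassingly parallel; the
  implementation runs it serially for determinism and simplicity, and the
  contract is that any parallel execution must reproduce the serial
  results exactly.
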