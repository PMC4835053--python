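# Methods

## Problem and model

After focal laser ablation of a prostate tumour, the pre- and
post-treatment T2-weighted MRI volumes differ for three reasons: the
patient lies differently in the scanner, the bladder and rectum have
moved or filled differently and push on the gland, and the ablation
itself has changed the gland's shape.  `ablaquant` decomposes the
observed change into those three parts so the treatment-induced part can
be quantified on its own:

1. **Linear alignment** — a 9-degree-of-freedom transform (per-axis
   translation, rotation, scale; no shear) maximizing Mattes mutual
   information between the volumes, found by regular-step gradient
   descent over a 3-level multi-resolution pyramid.
2. **Organ-deformation removal** — a finite-element model of the pelvic
   soft tissue, meshed with 8-node hexahedra, estimates the deformation
   the bladder and rectum impose.  Forces on the bladder/rectum surface
   nodes are chosen to deform those organs toward their pre-treatment
   counterparts; solving `K U = F` (BiCGStab) yields the tissue
   deformation, which is inverted and applied to the post image.
3. **Residual treatment deformation** — a second FEM drives the
   corrected post-treatment prostate surface onto the pre-treatment one;
   the resulting dense field is the treatment-attributed shape change
   and also produces the spatially aligned image pair for intensity
   comparison.

Outcome measures: Dice overlap per organ, organ volumes (ml) and percent
change, the deformation-magnitude heatmap `||T3(c) − c||`, and a relative
intensity-difference map (percent of the masked mean of the reference
image by default; a per-voxel reference is selectable).

## Elasticity

Tissue is homogeneous, isotropic, linear-elastic: Young's modulus
E = 30 kPa (soft tissue; configurable, and swept in the validation
experiment) and Poisson's ratio nu = 0.45 (near-incompressible, the
standard choice in prostate FEM work; the ratio matters little here
because loads are displacement-derived).  Elements are axis-aligned
cubic hexahedra with trilinear shape functions and 2x2x2 Gauss
quadrature; for these elements the integrand is quadratic per direction,
so this quadrature is exact.  The mesh covers the labelled organs' bounding
box plus a background margin (10 mm by default), clipped to the image;
background voxels get the same soft-tissue material, standing in for
unlabelled pelvic tissue.  The outer mesh boundary is clamped
(homogeneous Dirichlet) as a far-field condition in every mode.

An octree-adaptive mode subdivides surface-intersecting elements in
powers of two down to a minimum size, recording hanging-node constraints
as trilinear master–slave relations that are eliminated before solving.
The reported experiments all use the uniform mesh, which matches the
~1 mm operating point the method was designed around; adaptivity is
exercised by the test suite.

The solver is BiCGStab with a relative-residual tolerance of 1e-6 and
either a Jacobi or an incomplete-LU preconditioner (ILU, drop tolerance
5e-4, fill factor 10 — the default for one-off pipeline meshes); a
sparse direct path exists for small systems and oracle comparisons, and
a `factorized` mode computes one exact sparse LU and reuses it across
right-hand sides.  The repeated synthetic experiments use the
factorized mode on a single whole-image mesh: because the material is
homogeneous, `K(E) = (E/E0) K(E0)` and the element organ labels do not
enter the stiffness, so one factorization at the 30 kPa reference
serves ground-truth generation, every seeded repeat, every modulus in a
sweep and both pipeline stages (solutions at other moduli are rescaled
right-hand sides).

## Surface driving

The deformation source in stages 2 and 3 is a correspondence between an
organ's surface in the two configurations.  Surface node displacements
are estimated as a coherent translation (ICP with translation only —
pelvic organs are rotationally near-symmetric, so an ICP rotation is
weakly determined and a spurious one injects false tangential motion)
plus a symmetric closest-point residual against the target surface
cloud (marching-cubes vertices of the target mask, sub-voxel).
Residuals beyond a gating radius (20 mm default) are excluded as
outliers.

Two driving modes exist:

* **prescribed** — correspondence displacements become Dirichlet values
  at the surface nodes.  Robust, and for homogeneous tissue exactly
  independent of Young's modulus.
* **force** (default) — displacements are converted to nodal forces
  through a spring constant and applied over repeated sweeps, with the
  correspondence re-evaluated each sweep.  The spring constant is a
  fixed physical quantity: `gamma` times the node's diagonal stiffness
  at the 30 kPa reference material, with `gamma = 0.03` chosen so that
  one sweep at the reference modulus realizes roughly 80% of the
  requested displacement (measured directly on the phantom mesh).
  Because the springs are E-independent, stiffer tissue undershoots per
  sweep and softer tissue overshoots — this is what makes recovery
  accuracy modulus-sensitive, peaking near the modulus the springs were
  sized for.  Fine-scale surface modes see a smaller effective gain than
  coarse ones, so the spring constant is doubled every 5 converging
  sweeps (up to 4x) and halved if the residual grows; a hard stop
  triggers when the residual exceeds 3x its initial value (grossly
  soft tissue diverges on the first sweep and stays unrecovered, which
  is the observed failure mode at 0.3–3 kPa).  The sweep budget is 18,
  chosen so the slow-converging stiff end of the biomechanical range
  (120 kPa) reaches its plateau.

Stage 2 estimates the *forward* organ deformation on the post-aligned
configuration (where that deformation is genuinely an elastic field) and
then inverts the dense field by fixed-point iteration (20 iterations or
0.01 mm).  Estimating the inverse directly as a single elastic solve
mis-places the interior by a term of order strain x displacement, which
at the strains needed to depress the prostate Dice to 0.65 costs several
Dice points.  Stage 3's deformation is small, so its field is used
directly without inversion.

## Dense fields, warping, composition

Nodal displacements are spread to voxels by trilinear shape-function
interpolation in the containing element (default).  Two alternates are
selectable for audit: `inverse_distance_weight` over the 8 corners, and
`as_printed_distance_weight`, which weights corners *proportionally* to
their distance — an unusual rule under which a coincident corner gets
zero weight; it is retained because pipelines of this family have been
described with that weighting, and the difference is worth measuring
rather than silently normalizing away.  All schemes normalize weights,
so uniform fields are reproduced exactly.

Warping is backward lookup, `J(c) = I(c + d(c))`, with linear or nearest
sampling (labels always nearest).  Composition resamples the second
field at the first field's displaced positions; a fixed-point numeric
inverse is provided as a utility and used by stage 2.

## Linear registration

Mattes mutual information (32 bins), regular-step gradient descent with
parameter scaling from physical shift, ScaleVersor3D parameterization
(3 translations, 3 rotation parameters, 3 scales) about the moving-image
centroid, 3-level pyramid (shrink 4/2/1, smoothing 2/1/0 mm), regular
deterministic sampling of 25% of voxels.  The recovered transform maps
fixed-image points into the moving image (the resampling convention),
which is what every downstream warp consumes.  The histogram MI used in
metrics and tests is linear-binned over each image's range.

## Synthetic phantom

No imaging data ships with the package; a parametric pelvic phantom
generates the study conditions.  The default scene mimics the clinical
acquisitions: ~140 mm field of view at 1 mm isotropic spacing with a
51 ml prostate (the cohort's median pre-treatment volume), a bladder
superior-anterior to it, and a posterior rectal tube.  The rectum is
bowed laterally with a gently varying radius: a straight constant-radius
cylinder would make motion along its own axis unobservable to any
surface-based method.  T2-like contrast (bright urine, intermediate
gland, dark muscle) plus seeded Gaussian noise (SD 8 by default).

Two lateral bone-like pillars (intensity-only, not segmented organs)
flank the scene: far from the organs they barely deform, and they
anchor the linear patient-positioning registration the way the pelvis
does on a real scan — without rigid background anatomy the MI optimum
absorbs part of the organ-driven deformation into the linear fit.

A `compact` variant (96 mm field of view, ~13 mm prostate semi-axes) is
used for all repeated experiments.  The organs are scaled down more than
the field of view so the organ-driven displacement field decays over a
clinically realistic distance before reaching the clamped boundary; in a
tighter box, the strain needed to depress the prostate Dice to 0.65
makes the ground-truth deformation nearly non-invertible, and no
recovery method could be judged against it.

**Ground-truth organ deformation.**  Following the construction used
when real pre/post pairs are available, forces on the bladder and rectum
surfaces are *chosen to deform those organs toward target surfaces*:
seeded random targets built from one shared translation (drawn mainly in
the anterior-posterior/superior-inferior plane, where organ filling
actually displaces the gland; 10–16 mm), per-organ inflation (−4% to
+10%) and a smooth long-wavelength modulation.  The force sweeps run on
the phantom FEM itself, so the ground truth is exactly an elastic
surface-force solution and is linear in an overall force scale.  A
bisection on that scale (re-warping only, one solve total) calibrates
the starting prostate Dice to 0.65 ± 0.01.  Sampling both organs from
one shared flow matters: independently drawn pushes occasionally
converge on the gland and squeeze rather than transport it, producing
deformations whose inverse lies outside what any correspondence-driven
recovery can represent — a generator artefact, not a property of
inter-visit organ motion.

**Focal lesion.**  A cosine-tapered force pattern pulling mesh nodes
around a site inside the prostate through the FEM, calibrated by
bisection (again via linearity) until the warped prostate loses the
requested volume fraction; plus a tapered relative intensity change in a
ball around the site.  The ground-truth treatment field is returned for
end-to-end recovery tests.

What the phantom does *not* emulate: MRI physics (bias fields, coil
profiles, partial-volume averaging beyond voxelization), anatomical
texture inside organs, segmentation error, and inter-visit biological
change other than the modelled organ drift and lesion.  Passing the
synthetic experiments therefore demonstrates that the pipeline recovers
deformations of the kind it models, under its own elasticity
assumptions, at the study's geometry and noise scale — not that it is
robust to segmentation variability or to deformations outside the
elastic, surface-driven family.

## Validation experiments

**Deformation-recovery experiment** (`experiment_e1`, also the
acceptance targets): generate the compact phantom; per seeded force
pattern, calibrate to starting prostate Dice 0.65 ± 0.01, apply the
deformation, recover with the stage-2 FEM in force mode, and record the
Dice between the original and recovered prostate.  One full-image mesh
(cubic elements, 3.5 mm — coarser than the 1 mm clinical operating point
to keep 20+ repeats at desk scale; the recovered fields are smooth at
organ scale, and halving the element size changes recovered Dice by well
under a point) serves ground truth, every repeat and every modulus,
since homogeneous stiffness is label-independent and is simply
relabelled per configuration.  Typical results: mean recovered Dice
~0.93 ± 0.02 over 20 patterns at 30 kPa; ≥ 0.92 across 20–120 kPa; and
a log-modulus sweep over 0.3–3000 kPa peaking at 30 kPa with collapse at
the soft end (first-sweep overshoot divergence) and stagnation at the
stiff end (undershoot) — the numbers are computed fresh by
`scripts/acceptance.py` and the acceptance tests, not stored.

**Full-chain experiment** (`experiment_e2`): pre phantom → organ
deformation (calibrated to a milder Dice 0.80) → focal lesion (5% volume
loss near the posterior capsule, −30% intensity) → linear misalignment,
all composed into a single lookup field so the synthetic post scan is
one resampling of the pre scene, as a real acquisition would be.  The
complete pipeline then recovers each component; the report compares the
measured prostate volume change against the end-to-end truth (the
configured lesion shrink plus the organ-motion volume effect — the
elastic deformation is not exactly volume-preserving at nu = 0.45) and
quantifies lesion localization both as the heatmap argmax and as the
site's signal fraction (peak magnitude within 10 mm of the site over
the global maximum).  At a 5%-volume lesion the site's signal is ~0.9 of
the global maximum, but the argmax itself can land on a stage-2 residual
bump of comparable height — single-voxel argmax localization at this
lesion size sits at the pipeline's residual noise floor, whereas the
direct lesion experiment (no organ chain) localizes within 10 mm
robustly.

## Numerical choices and degenerate inputs

* Dice of two empty masks is defined as 1.0 (with a warning); volume
  change requires a positive pre volume.
* Constant images give MI 0 with a warning.
* Voxels outside the mesh receive zero displacement (logged).
* Ties in point location at shared element faces break toward the lower
  element id; element organ assignment is by majority voxel label on a
  3^3 stencil.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); repeated runs are bitwise identical.

## Known limitations

* Identity direction matrices only; oblique acquisitions must be
  resampled upstream.
* Linear small-strain elasticity with a single homogeneous modulus;
  heterogeneous per-tissue moduli are a configuration extension, not
  exercised by the experiments (consistent with the reported finding
  that heterogeneity did not change results).
* The treatment field is surface-driven, so purely internal shape
  change that leaves the capsule untouched is attributed only through
  its surface expression.
* Patient-level clinical findings (per-patient volume trajectories,
  real ablation-zone maps) require the clinical data and are out of
  scope; the phantom covers the method's mechanics, not the cohort.
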