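# ablaquant

Biomechanically constrained registration and quantification of focal
laser ablation (FLA) effects on prostate MRI.

## The problem

FLA destroys prostate tumours by localized thermal necrosis, and
T2-weighted MRI acquired before and months after treatment is how its
effect is judged.  But the two scans cannot be compared voxel-to-voxel:
the patient lies differently, the bladder and rectum have moved and
filled differently (deforming the gland), and the ablation itself has
changed the gland's shape.  `ablaquant` separates these three effects so
the treatment-induced change can be measured on its own.  It is aimed at
researchers in prostate-cancer imaging who have pre/post T2-weighted
volumes with organ segmentations (prostate, bladder, rectum) and want
quantitative, spatially resolved treatment-response measures.

## The model

Writing `T1` for the patient-positioning transform, `T2` for the
organ-driven deformation and `T3` for the treatment-induced change,

    C_post = T1(T2(T3(C_pre)))    =>    T3(C_pre) = T̂2(T̂1(C_post))

where `T̂` denotes an inverse.  The pipeline estimates:

* **T̂1** — a 9-DOF linear transform (translation, rotation, per-axis
  scale) maximizing mutual information, via regular-step gradient
  descent on a multiresolution pyramid;
* **T̂2** — a hexahedral finite-element model of the pelvic soft tissue
  (homogeneous linear elasticity, Young's modulus 30 kPa, Poisson 0.45).
  Forces at the bladder/rectum surface nodes deform those organs toward
  their pre-treatment positions; the sparse system `K·U = F` (3N dofs)
  is solved with preconditioned BiCGStab, nodal displacements are
  interpolated to a dense per-voxel field, and the inverted field
  removes the organ-driven deformation from the post scan.  The prostate
  carries no direct load — it moves only through elastic transmission;
* **T3** — a second FEM drives the corrected post prostate surface onto
  the pre-treatment one, yielding the residual (treatment) deformation
  and the spatially aligned image pair.

Reported measures: per-organ Dice overlap, prostate volume (ml) and
percent change, the deformation heatmap `‖T3(c) − c‖₂` (mm), and the
relative intensity-difference map (%) between the aligned images.

Everything is validated on a synthetic pelvic phantom with ground-truth
deformations generated by the same elasticity engine, so no patient data
is required.  See `docs/methods.md` for the full model description.

## Worked example

Generate a phantom, deform it, and run the full pipeline:

```bash
ablaquant phantom --seed 42 --out-dir work/pre
ablaquant e2 --seed 1 --out-dir work/e2
```

The `e2` command builds a synthetic "post-treatment" scan (organ motion
+ a 5%-volume focal lesion + a linear misalignment), runs the
three-stage pipeline and prints the comparison against the generator's
ground truth (output of the run above):

```
{
  "seed": 1,
  "organ_deformation_dice": 0.799,
  "true_lesion_site_mm": [53.2, 41.4, 42.0],
  "t3_peak_mm": [48.0, 52.0, 31.0],
  "t3_peak_error_mm": 16.1,
  "site_signal_fraction": 0.925,
  "configured_shrink_percent": 5.0,
  "true_volume_change_percent": -5.50,
  "measured_volume_change_percent": -4.03,
  "prostate_dice_after_t2": 0.862
}
```

`organ_deformation_dice` is the prostate Dice the injected organ motion
was calibrated to.  `site_signal_fraction` says how hot the true
ablation site is relative to the hottest point of the recovered
treatment-deformation heatmap — 0.93 here, i.e. the site carries nearly
the maximal deformation, although the single-voxel argmax
(`t3_peak_mm`) lands on a residual-registration bump of comparable
height elsewhere on the gland.  `measured_volume_change_percent` tracks
the true end-to-end change (`true_volume_change_percent`, the
configured 5% lesion shrink plus the organ-motion volume effect) within
about a point.  `prostate_dice_after_t2` measures how well stage 2
restored the gland before the treatment deformation was estimated.  On
real data the same pipeline runs as

```bash
ablaquant run --pre-image pre.nii.gz --pre-labels pre_seg.nii.gz \
              --post-image post.nii.gz --post-labels post_seg.nii.gz \
              --config cfg.yaml --out-dir results/
```

writing `transform.json`, the dense `t2_field`/`t3_field`, the aligned
volumes, heatmaps and a JSON/CSV report.

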