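"""Three-stage decomposition of post-treatment change.

Stage 1 (T1-hat): linear MI alignment of the post- onto the pre-treatment
scan.  Stage 2 (T2-hat): a bladder/rectum-driven FEM removes the deformation
the surrounding organs impose on the prostate.  Stage 3 (T3): a prostate
FEM captures the residual — primarily treatment-induced — shape change, and
yields the spatially aligned image pair for intensity comparison.

Resampling convention: every stage produces a backward-lookup field defined
on the grid the moving image is resampled onto.  The stage-2 FEM is meshed
on the post-aligned configuration and its bladder/rectum surfaces are
driven toward the pre-treatment ones; this estimates the forward organ
deformation in the configuration where it is genuinely elastic, and the
resulting dense field is then inverted (fixed-point) and applied to the
post image — estimating the inverse directly as a single elastic solve
would mis-place the gland by a term of order strain x displacement.  The
stage-3 FEM is meshed on the corrected post configuration, its prostate
driven toward the pre-treatment prostate, directly giving the (small)
lookup field that warps the pre image onto the aligned post pair.  The
prostate surface receives no direct load in stage 2; it moves only through
elastic transmission.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .elasticity import (MatchOptions, MaterialParams, SolverOptions,
                         StiffnessSolver, assemble_stiffness, match_surfaces,
                         outer_boundary_nodes)
from .errors import PipelineError
from .hexmesh import build_mesh, label_surface_points
from .imaging_io import (BLADDER, PROSTATE, RECTUM, DenseDisplacementField,
                         LabelMap, VolumeImage, resample_to_isotropic)
from .linear_register import (LinearTransform, RegistrationOptions,
                              apply_linear, register_linear)
from .warpfield import interpolate_displacements, numeric_inverse, warp_image

log = logging.getLogger(__name__)


@dataclass
class PipelineOptions:
    material: MaterialParams = field(default_factory=MaterialParams)
    match: MatchOptions = field(default_factory=MatchOptions)
    registration: RegistrationOptions = field(
        default_factory=RegistrationOptions)
    element_mm: float = 2.0
    margin_mm: float = 10.0
    working_spacing_mm: float = 1.0
    resample_working_grid: bool = False  # resample inputs to isotropic grid
    seed: int = 0
    # optional shared (mesh, stiffness, solver) covering the working grid;
    # homogeneous stiffness is label-independent, so one factorization can
    # serve both FEM stages (and repeated runs) after relabelling
    solver_cache: tuple | None = None


@dataclass
class RegistrationResult:
    t1: LinearTransform
    t2_field: DenseDisplacementField
    t3_field: DenseDisplacementField
    pre_image: VolumeImage
    pre_labels: LabelMap
    aligned_post_image: VolumeImage      # T2-hat(T1-hat(I_post))
    aligned_post_labels: LabelMap
    warped_pre_image: VolumeImage        # T3(I_pre)
    provenance: dict = field(default_factory=dict)


def _surface_fem(domain_labels, target_clouds, material, opts,
                 element_mm, margin_mm, solver_cache=None):
    """Mesh the domain configuration and drive organ surfaces to targets."""
    if solver_cache is not None:
        # shared-geometry cache: homogeneous stiffness is label-independent,
        # so only the element organ labels need re-deriving
        mesh, stiffness, solver = solver_cache
        mesh = mesh.with_labels(domain_labels)
    else:
        mesh = build_mesh(domain_labels, min_size=element_mm,
                          max_size=element_mm, margin=margin_mm)
        e_ref = opts.spring_reference_kpa if opts.mode == "force" \
            else material.youngs_modulus
        stiffness = assemble_stiffness(
            mesh, MaterialParams(e_ref, material.poisson_ratio))
        solver = None
        if opts.mode == "force":
            boundary = outer_boundary_nodes(mesh)
            fixed = {3 * n + d: 0.0 for n in boundary for d in range(3)}
            solver = StiffnessSolver(stiffness, fixed, opts.solver)
    u, tele = match_surfaces(mesh, material, target_clouds, opts,
                             solver=solver, stiffness=stiffness)
    fld = interpolate_displacements(mesh, u, domain_labels)
    return fld, tele, (mesh, stiffness, solver)


def remove_organ_deformation(pre_labels: LabelMap,
                             post_aligned_labels: LabelMap,
                             post_aligned_image: VolumeImage,
                             material: MaterialParams = None,
                             opts: PipelineOptions = None,
                             solver_cache=None):
    """Stage 2: estimate and remove bladder/rectum-driven deformation.

    Returns ``(t2_field, corrected_image, corrected_labels, telemetry)``.
    """
    opts = opts or PipelineOptions()
    material = material or opts.material
    for lab, name in ((BLADDER, "bladder"), (RECTUM, "rectum")):
        for which, lm in (("pre", pre_labels), ("post", post_aligned_labels)):
            if not lm.mask(lab).any():
                raise PipelineError(
                    "remove_organ_deformation",
                    f"{which} label map lacks the {name} label")
    # forward organ deformation, estimated on the post-aligned anatomy
    targets = {lab: label_surface_points(pre_labels, lab)
               for lab in (BLADDER, RECTUM)}
    forward, tele, cache = _surface_fem(post_aligned_labels, targets,
                                        material, opts.match, opts.element_mm,
                                        opts.margin_mm, solver_cache)
    # invert it and apply: the lookup field that removes the organ motion
    fld = numeric_inverse(forward, iterations=15, tol_mm=0.03)
    corrected_labels = warp_image(post_aligned_labels, fld)
    corrected_image = warp_image(post_aligned_image, fld) \
        if post_aligned_image is not None else None
    return fld, corrected_image, corrected_labels, {"stage": "t2", **tele,
                                                    "cache": cache}


def estimate_treatment_deformation(pre_image: VolumeImage,
                                   pre_labels: LabelMap,
                                   corrected_post_image: VolumeImage,
                                   corrected_post_labels: LabelMap,
                                   material: MaterialParams = None,
                                   opts: PipelineOptions = None,
                                   solver_cache=None):
    """Stage 3: residual prostate deformation attributed to the treatment.

    Returns ``(t3_field, warped_pre_image, telemetry)``; warping the pre
    image with the field yields the partner of the corrected post image.
    """
    opts = opts or PipelineOptions()
    material = material or opts.material
    for which, lm in (("pre", pre_labels), ("post", corrected_post_labels)):
        if not lm.mask(PROSTATE).any():
            raise PipelineError("estimate_treatment_deformation",
                                f"{which} label map lacks the prostate label")
    targets = {PROSTATE: label_surface_points(pre_labels, PROSTATE)}
    fld, tele, _ = _surface_fem(corrected_post_labels, targets,
                                material, opts.match, opts.element_mm,
                                opts.margin_mm, solver_cache)
    warped_pre = warp_image(pre_image, fld) if pre_image is not None else None
    return fld, warped_pre, {"stage": "t3", **tele}


def run_pipeline(pre_image, pre_labels, post_image, post_labels,
                 opts: PipelineOptions = None, out_dir=None
                 ) -> RegistrationResult:
    """Execute T1-hat, T2-hat and T3 in order and assemble the result."""
    opts = opts or PipelineOptions()
    prov = {"config": _describe_options(opts), "stages": {}}
    t_start = time.time()

    if opts.resample_working_grid:
        s = opts.working_spacing_mm
        pre_image = resample_to_isotropic(pre_image, s)
        pre_labels = resample_to_isotropic(pre_labels, s)
        post_image = resample_to_isotropic(post_image, s)
        post_labels = resample_to_isotropic(post_labels, s)

    try:
        t1 = register_linear(post_image, pre_image, opts.registration)
        aligned_img = apply_linear(post_image, t1, reference=pre_image)
        aligned_lab = apply_linear(post_labels, t1, reference=pre_labels)
        prov["stages"]["t1"] = t1.telemetry if hasattr(t1, "telemetry") else {}
    except Exception as exc:
        raise PipelineError("linear_alignment", str(exc)) from exc

    try:
        t2_field, corr_img, corr_lab, tele2 = remove_organ_deformation(
            pre_labels, aligned_lab, aligned_img, opts.material, opts,
            solver_cache=opts.solver_cache)
        tele2.pop("cache", None)
        prov["stages"]["t2"] = tele2
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("remove_organ_deformation", str(exc)) from exc

    try:
        t3_field, warped_pre, tele3 = estimate_treatment_deformation(
            pre_image, pre_labels, corr_img, corr_lab, opts.material, opts,
            solver_cache=opts.solver_cache)
        prov["stages"]["t3"] = tele3
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("estimate_treatment_deformation", str(exc)) from exc

    prov["runtime_s"] = time.time() - t_start
    prov["seed"] = opts.seed
    result = RegistrationResult(
        t1=t1, t2_field=t2_field, t3_field=t3_field,
        pre_image=pre_image, pre_labels=pre_labels,
        aligned_post_image=corr_img, aligned_post_labels=corr_lab,
        warped_pre_image=warped_pre, provenance=prov)

    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _describe_options(opts: PipelineOptions):
    return {
        "material": {"youngs_modulus_kpa": opts.material.youngs_modulus,
                     "poisson_ratio": opts.material.poisson_ratio},
        "loads": {"mode": opts.match.mode,
                  "gating_mm": opts.match.gating_mm,
                  "spring_gamma": opts.match.spring_gamma,
                  "max_sweeps": opts.match.max_sweeps},
        "solver": {"tol": opts.match.solver.tol,
                   "preconditioner": opts.match.solver.preconditioner},
        "mesh": {"element_mm": opts.element_mm, "margin_mm": opts.margin_mm},
        "working_spacing_mm": opts.working_spacing_mm,
        "seed": opts.seed,
    }


def _write_outputs(result: RegistrationResult, out_dir):
    from pathlib import Path

    from .imaging_io import (write_displacement_field, write_labelmap,
                             write_volume)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.t1.to_json(out / "transform.json")
    write_displacement_field(result.t2_field, out / "t2_field.nii.gz")
    write_displacement_field(result.t3_field, out / "t3_field.nii.gz")
    write_volume(result.aligned_post_image, out / "aligned_post.nii.gz")
    write_labelmap(result.aligned_post_labels, out / "aligned_post_labels.nii.gz")
    write_volume(result.warped_pre_image, out / "warped_pre.nii.gz")
    with open(out / "report.json", "w") as f:
        json.dump(result.provenance, f, indent=2, default=str)
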