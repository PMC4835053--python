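"""Outcome measures: Dice overlap, organ volumes, heatmaps, intensity change.

These are the quantities reported per patient after the registration chain:
prostate volume before/after treatment, the deformation-magnitude heatmap of
the treatment field, and the relative intensity-difference map between the
spatially aligned pre- and post-treatment images.

Volume change is reported per case as 100 (post - pre) / pre.  Note that
for a cohort, the percent change of the median volumes and the median of
per-case percent changes differ; both conventions appear in the treatment-
response literature, so multi-case summaries should state which is used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .imaging_io import (DEFAULT_LABELS, DenseDisplacementField, LabelMap,
                         VolumeImage)
from .warpfield import magnitude_map

log = logging.getLogger(__name__)


def dice(a, b):
    """Dice similarity coefficient 2|A n B| / (|A| + |B|) of two masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError(f"dice: mask shapes differ {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        log.warning("dice of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def organ_volume(labels: LabelMap, organ) -> float:
    """Organ volume in ml (voxel count x voxel volume / 1000)."""
    n = int(labels.mask(organ).sum())
    if n == 0:
        log.warning("organ label %s absent; volume 0", organ)
    return n * float(np.prod(labels.spacing)) / 1000.0


def volume_change(pre_ml, post_ml) -> float:
    """Percent volume change 100 (post - pre) / pre."""
    if pre_ml <= 0:
        raise ValueError("volume change undefined for pre volume <= 0")
    return 100.0 * (post_ml - pre_ml) / pre_ml


def intensity_difference_map(a: VolumeImage, b: VolumeImage, mask,
                             reference="masked_mean"):
    """Relative percent intensity difference |a - b| within a mask.

    The normalizing reference defaults to the masked mean of ``a`` (robust
    to per-voxel zeros); ``reference='per_voxel'`` divides by |a| voxelwise.
    Returns ``(map_image, stats)`` where stats holds max/mean percent and
    the world location of the maximum.
    """
    a.require_same_grid(b, "intensity_difference_map")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("intensity difference: empty mask")
    eps = 1e-9
    if reference == "masked_mean":
        ref = max(float(np.abs(a.data[mask]).mean()), eps)
        denom = ref
    elif reference == "per_voxel":
        denom = np.maximum(np.abs(a.data), eps)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    out = np.zeros(a.dims, dtype=float)
    diff = 100.0 * np.abs(np.asarray(a.data, float)
                          - np.asarray(b.data, float)) / denom
    out[mask] = diff[mask] if np.ndim(diff) else diff
    arg = np.unravel_index(np.argmax(out), out.shape)
    stats = {
        "max_percent": float(out.max()),
        "mean_percent": float(out[mask].mean()),
        "argmax_mm": a.voxel_to_world(np.asarray(arg)).tolist(),
    }
    return a.copy_geometry(out), stats


@dataclass
class QuantReport:
    """Assembled outcome measures for one registration run."""

    dice_by_organ: dict
    volumes_ml: dict                 # (timepoint, organ_name) -> ml
    volume_change_percent: dict      # organ_name -> percent
    max_deformation_mm: float
    intensity_diff_stats: dict
    files: dict = field(default_factory=dict)

    def to_json(self, path=None):
        d = {
            "dice_by_organ": self.dice_by_organ,
            "volumes_ml": {f"{tp}/{org}": v
                           for (tp, org), v in self.volumes_ml.items()},
            "volume_change_percent": self.volume_change_percent,
            "max_deformation_mm": self.max_deformation_mm,
            "intensity_diff_stats": self.intensity_diff_stats,
            "files": self.files,
        }
        if path is not None:
            with open(path, "w") as f:
                json.dump(d, f, indent=2)
        return d

    def to_csv(self, path):
        import pandas as pd
        rows = [{"timepoint": tp, "organ": org, "volume_ml": v}
                for (tp, org), v in self.volumes_ml.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


def build_report(result, out_dir=None) -> QuantReport:
    """Assemble all outcome measures from a RegistrationResult."""
    from .ablation_pipeline import RegistrationResult  # noqa: F401 (typing)
    pre_labels = result.pre_labels
    names = {lab: name for lab, name in DEFAULT_LABELS.items() if lab != 0}

    dice_by_organ = {}
    volumes = {}
    vol_change = {}
    for lab, name in names.items():
        pre_mask = pre_labels.mask(lab)
        post_mask = result.aligned_post_labels.mask(lab)
        if not pre_mask.any() and not post_mask.any():
            continue
        dice_by_organ[name] = dice(pre_mask, post_mask)
        pre_ml = organ_volume(pre_labels, lab)
        post_ml = organ_volume(result.aligned_post_labels, lab)
        volumes[("pre", name)] = pre_ml
        volumes[("post", name)] = post_ml
        if pre_ml > 0:
            vol_change[name] = volume_change(pre_ml, post_ml)

    heat = magnitude_map(result.t3_field)
    prostate = pre_labels.mask(1)
    _, stats = intensity_difference_map(result.warped_pre_image,
                                        result.aligned_post_image, prostate)
    report = QuantReport(
        dice_by_organ=dice_by_organ,
        volumes_ml=volumes,
        volume_change_percent=vol_change,
        max_deformation_mm=float(heat.data.max()),
        intensity_diff_stats=stats,
    )
    if out_dir is not None:
        from pathlib import Path

        from .imaging_io import write_volume
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        heat_path = out_dir / "t3_deformation_heatmap.nii.gz"
        write_volume(heat, heat_path)
        diff_img, _ = intensity_difference_map(
            result.warped_pre_image, result.aligned_post_image, prostate)
        diff_path = out_dir / "intensity_difference_percent.nii.gz"
        write_volume(diff_img, diff_path)
        report.files = {"t3_heatmap": str(heat_path),
                        "intensity_difference": str(diff_path)}
        report.to_json(out_dir / "quant_report.json")
        report.to_csv(out_dir / "volumes.csv")
    return report
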