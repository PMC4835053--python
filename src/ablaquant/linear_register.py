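"""Mutual-information linear (9-DOF) alignment of post- to pre-treatment MRI.

The transform has per-axis translation, rotation and scale (no shear),
applied about a fixed centre.  Registration maximizes Mattes mutual
information with a regular-step gradient-descent optimizer over a
multi-resolution pyramid (SimpleITK backend, matching the ITK lineage of
this kind of pipeline); the histogram MI used for reporting and for metric
checks is implemented directly.

Convention: the recovered transform maps *fixed*-image points into the
*moving* image's space (backward lookup), so resampling the moving image
through it brings it onto the fixed grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.spatial.transform import Rotation

from .errors import RegistrationError
from .imaging_io import LabelMap, VolumeImage, _from_sitk, _to_sitk

log = logging.getLogger(__name__)


@dataclass
class LinearTransform:
    """Translation + ZYX Euler rotation + per-axis scale about a centre."""

    translation: tuple = (0.0, 0.0, 0.0)  # mm
    rotation: tuple = (0.0, 0.0, 0.0)     # radians, ZYX order
    scale: tuple = (1.0, 1.0, 1.0)
    center: tuple = (0.0, 0.0, 0.0)       # mm

    def __post_init__(self):
        if any(s <= 0 for s in self.scale):
            raise ValueError("scale factors must be positive")

    def matrix(self):
        """4x4 homogeneous matrix: p' = R S (p - c) + c + t."""
        r = Rotation.from_euler("ZYX", self.rotation).as_matrix()
        a = r @ np.diag(self.scale)
        m = np.eye(4)
        m[:3, :3] = a
        c = np.asarray(self.center)
        m[:3, 3] = np.asarray(self.translation) + c - a @ c
        return m

    @classmethod
    def from_matrix(cls, m, center=(0.0, 0.0, 0.0)):
        """Recover parameters from a (near) shear-free homogeneous matrix.

        Uses the polar decomposition A = R P and keeps the diagonal of P;
        exact whenever the matrix is rotation x per-axis scale without
        shear (the family is not closed under composition/inversion when
        rotation meets anisotropic scale — residual shear is discarded).
        """
        from scipy.linalg import polar
        m = np.asarray(m, dtype=float)
        a = m[:3, :3]
        r, p = polar(a)
        if np.linalg.det(r) < 0:
            raise ValueError("matrix includes a reflection; not representable")
        scale = np.diag(p)
        rot = Rotation.from_matrix(r).as_euler("ZYX")
        c = np.asarray(center)
        t = m[:3, 3] - c + a @ c
        return cls(tuple(t), tuple(rot), tuple(scale), tuple(center))

    def apply_points(self, pts):
        pts = np.asarray(pts, dtype=float)
        m = self.matrix()
        return pts @ m[:3, :3].T + m[:3, 3]

    def inverse(self):
        m = np.linalg.inv(self.matrix())
        return LinearTransform.from_matrix(m, self.center)

    def to_sitk(self):
        t = sitk.AffineTransform(3)
        m = self.matrix()
        t.SetMatrix(m[:3, :3].ravel())
        t.SetTranslation(m[:3, 3])
        return t

    def to_json(self, path=None):
        d = {"translation_mm": list(self.translation),
             "rotation_rad_zyx": list(self.rotation),
             "scale": list(self.scale),
             "center_mm": list(self.center),
             "matrix": self.matrix().tolist()}
        if path is not None:
            with open(path, "w") as f:
                json.dump(d, f, indent=2)
        return d

    @classmethod
    def from_json(cls, path):
        with open(path) as f:
            d = json.load(f)
        return cls(tuple(d["translation_mm"]), tuple(d["rotation_rad_zyx"]),
                   tuple(d["scale"]), tuple(d["center_mm"]))


def entropy(img: VolumeImage, bins=32):
    """Marginal Shannon entropy (nats) with linear binning over the range."""
    data = np.asarray(img.data, dtype=float).ravel()
    if data.max() == data.min():
        return 0.0
    p, _ = np.histogram(data, bins=bins)
    p = p / p.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(a: VolumeImage, b: VolumeImage, bins=32):
    """Histogram mutual information (nats) between two same-grid images."""
    a.require_same_grid(b, "mutual_information")
    x = np.asarray(a.data, dtype=float).ravel()
    y = np.asarray(b.data, dtype=float).ravel()
    if x.max() == x.min() or y.max() == y.min():
        log.warning("mutual_information: constant image, returning 0")
        return 0.0
    pxy, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = pxy / pxy.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    marg = (px[:, None] * py[None, :])[nz]
    return float((pxy[nz] * (np.log(pxy[nz]) - np.log(marg))).sum())


@dataclass
class RegistrationOptions:
    bins: int = 32
    pyramid: bool = True              # 3-level shrink/smooth pyramid
    learning_rate: float = 1.0
    min_step: float = 1e-4
    iterations: int = 200
    sampling_fraction: float = 0.25   # regular (deterministic) sampling


def register_linear(moving: VolumeImage, fixed: VolumeImage,
                    opts: RegistrationOptions = None,
                    fixed_mask=None) -> LinearTransform:
    """9-DOF MI registration of ``moving`` onto ``fixed``.

    Returns the transform mapping fixed-image points to moving-image points;
    metric telemetry is attached as ``transform.telemetry``.  When a
    ``fixed_mask`` (boolean array on the fixed grid) is given, the metric is
    evaluated only there — focusing the alignment on the gland region keeps
    genuinely deformed surrounding organs from biasing the linear fit.
    """
    opts = opts or RegistrationOptions()
    f = _to_sitk(np.asarray(fixed.data, dtype=np.float32), fixed.spacing,
                 fixed.origin)
    m = _to_sitk(np.asarray(moving.data, dtype=np.float32), moving.spacing,
                 moving.origin)

    tx = sitk.ScaleVersor3DTransform()
    # rotation/scale centre: moving-image centroid
    center = [moving.origin[d]
              + moving.spacing[d] * (moving.dims[d] - 1) / 2.0
              for d in range(3)]
    tx.SetCenter(center)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=opts.bins)
    if fixed_mask is not None:
        mask_img = _to_sitk(np.asarray(fixed_mask, dtype=np.uint8),
                            fixed.spacing, fixed.origin)
        reg.SetMetricFixedMask(sitk.Cast(mask_img, sitk.sitkUInt8))
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(opts.sampling_fraction, 12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=opts.learning_rate, minStep=opts.min_step,
        numberOfIterations=opts.iterations, relaxationFactor=0.6)
    reg.SetOptimizerScalesFromPhysicalShift()
    if opts.pyramid:
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(tx, inPlace=True)
    metric_trace = []
    reg.AddCommand(sitk.sitkIterationEvent,
                   lambda: metric_trace.append(reg.GetMetricValue()))
    try:
        reg.Execute(f, m)
    except RuntimeError as exc:
        if "samples map inside" in str(exc).lower() or "all samples" in str(exc).lower():
            raise RegistrationError(
                "no overlap at initialization; seed the registration with a "
                "translation bringing the volumes into rough overlap") from exc
        raise

    versor = np.asarray(tx.GetVersor())
    rot = Rotation.from_quat(versor).as_matrix()  # sitk versor is (x,y,z,w)
    a = rot @ np.diag(tx.GetScale())
    mhom = np.eye(4)
    mhom[:3, :3] = a
    c = np.asarray(tx.GetCenter())
    mhom[:3, 3] = np.asarray(tx.GetTranslation()) + c - a @ c
    result = LinearTransform.from_matrix(mhom, center=tuple(c))
    result.telemetry = {"metric_trace": [float(v) for v in metric_trace],
                        "final_metric": float(reg.GetMetricValue()),
                        "stop_condition": reg.GetOptimizerStopConditionDescription()}
    return result


def apply_linear(img, t: LinearTransform, interp="linear", reference=None):
    """Resample an image or label map through a linear transform.

    ``reference`` (grid-defining image) defaults to the input's own grid.
    Label maps use nearest-neighbour interpolation.
    """
    is_labels = isinstance(img, LabelMap)
    ref = reference if reference is not None else img
    arr = img.labels if is_labels else img.data
    src = _to_sitk(np.asarray(arr, dtype=np.float32), img.spacing, img.origin)
    mode = sitk.sitkNearestNeighbor if (is_labels or interp == "nearest") \
        else sitk.sitkLinear
    out = sitk.Resample(src, [int(d) for d in ref.dims], t.to_sitk(), mode,
                        ref.origin, ref.spacing,
                        (1.0, 0, 0, 0, 1.0, 0, 0, 0, 1.0), 0.0,
                        sitk.sitkFloat32)
    data, spacing, origin = _from_sitk(out)
    if is_labels:
        return LabelMap(np.round(data).astype(np.int32), spacing, origin,
                        dict(img.label_dictionary))
    return VolumeImage(data, spacing, origin)
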