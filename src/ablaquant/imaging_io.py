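"""Volumes, label maps and dense displacement fields, with NIfTI/MetaImage I/O.

All grids use an identity direction matrix: voxel ``(i, j, k)`` sits at world
position ``origin + index * spacing`` (mm).  Oblique acquisitions must be
resampled upstream; this keeps FEM node placement unambiguous.  Arrays are
indexed ``[x, y, z]`` (world-axis order), displacement fields carry a trailing
component axis and are stored in world millimetres so they remain valid when
the paired images differ in native spacing.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, GeometryError

log = logging.getLogger(__name__)

#: Canonical organ labels used throughout the pipeline.
DEFAULT_LABELS = {0: "background", 1: "prostate", 2: "bladder", 3: "rectum",
                  4: "ablation_zone"}

PROSTATE, BLADDER, RECTUM, ABLATION_ZONE = 1, 2, 3, 4

_GRID_TOL = 1e-4  # mm tolerance when comparing grid metadata


@dataclass
class VolumeImage:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensity per voxel.
    spacing : tuple of 3 floats
        Voxel size in mm, all > 0.
    origin : tuple of 3 floats
        World position (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.data.ndim != 3:
            raise FormatError(
                f"expected a 3D scalar array, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if any(d < 1 for d in self.data.shape):
            raise GeometryError(f"all dims must be >= 1, got {self.data.shape}")

    @property
    def dims(self):
        return self.data.shape

    def voxel_to_world(self, idx):
        """World coordinates (mm) of voxel indices (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_voxel(self, pts):
        """Continuous voxel indices of world points (..., 3)."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def grid_points(self):
        """World coordinates of every voxel centre, shape (nx, ny, nz, 3)."""
        ax = [self.origin[d] + self.spacing[d] * np.arange(self.dims[d])
              for d in range(3)]
        return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)

    def same_grid(self, other, tol=_GRID_TOL):
        return (self.dims == other.dims
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))

    def require_same_grid(self, other, what="operand"):
        if self.dims != other.dims:
            raise GeometryError(f"{what}: dims differ {self.dims} vs {other.dims}")
        if not np.allclose(self.spacing, other.spacing, atol=_GRID_TOL):
            raise GeometryError(
                f"{what}: spacing differs {self.spacing} vs {other.spacing}")
        if not np.allclose(self.origin, other.origin, atol=_GRID_TOL):
            raise GeometryError(
                f"{what}: origin differs {self.origin} vs {other.origin}")

    def copy_geometry(self, data):
        """New VolumeImage with this grid's metadata and the given data."""
        return VolumeImage(np.asarray(data), self.spacing, self.origin)


@dataclass
class LabelMap:
    """Integer organ labels on the same grid convention as :class:`VolumeImage`."""

    labels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    label_dictionary: dict = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            frac = np.abs(self.labels - np.round(self.labels))
            if np.nanmax(frac) > 1e-6:
                raise FormatError("label map contains fractional voxel values")
            self.labels = np.round(self.labels).astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.labels.ndim != 3:
            raise FormatError(
                f"expected a 3D label array, got ndim={self.labels.ndim}")
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = sorted(present - set(self.label_dictionary))
        if unknown:
            raise FormatError(f"labels {unknown} absent from label dictionary")
        if not present:
            log.warning("label map is empty (all background)")

    # grid helpers shared with VolumeImage
    dims = VolumeImage.dims
    voxel_to_world = VolumeImage.voxel_to_world
    world_to_voxel = VolumeImage.world_to_voxel
    grid_points = VolumeImage.grid_points
    same_grid = VolumeImage.same_grid
    require_same_grid = VolumeImage.require_same_grid

    @property
    def data(self):  # allow uniform treatment with VolumeImage
        return self.labels

    def mask(self, label):
        return self.labels == label

    def copy_geometry(self, labels):
        return LabelMap(labels, self.spacing, self.origin,
                        dict(self.label_dictionary))

    def as_image(self):
        return VolumeImage(self.labels.astype(np.float32), self.spacing,
                           self.origin)


@dataclass
class DenseDisplacementField:
    """Per-voxel world-mm displacement realizing T(c) = c + d(c).

    Fields are applied in the backward-lookup convention: warping an image I
    with field d produces J(c) = I(c + d(c)).
    """

    vectors: np.ndarray  # (nx, ny, nz, 3), mm
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise FormatError(
                f"displacement field must have shape (nx,ny,nz,3), "
                f"got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise FormatError("displacement field contains non-finite values")

    @property
    def dims(self):
        return self.vectors.shape[:3]

    voxel_to_world = VolumeImage.voxel_to_world
    world_to_voxel = VolumeImage.world_to_voxel
    same_grid = VolumeImage.same_grid
    require_same_grid = VolumeImage.require_same_grid

    def scaled(self, factor):
        return DenseDisplacementField(self.vectors * float(factor),
                                      self.spacing, self.origin)

    def magnitudes(self):
        return np.linalg.norm(self.vectors, axis=-1)


# ---------------------------------------------------------------------------
# SimpleITK conversion (sitk arrays are indexed [z, y, x])
# ---------------------------------------------------------------------------

def _check_path(path):
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    return path


def _to_sitk(data, spacing, origin, vector=False):
    if vector:
        arr = np.ascontiguousarray(np.transpose(data, (2, 1, 0, 3)))
    else:
        arr = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    img = sitk.GetImageFromArray(arr, isVector=vector)
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img, vector=False):
    arr = sitk.GetArrayFromImage(img)
    if vector:
        arr = np.transpose(arr, (2, 1, 0, 3))
    else:
        arr = np.transpose(arr, (2, 1, 0))
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def read_volume(path) -> VolumeImage:
    """Read a 3D scalar NIfTI/MetaImage volume."""
    img = sitk.ReadImage(_check_path(path))
    if img.GetDimension() != 3:
        raise FormatError(
            f"{path}: expected a 3D image, got dimension {img.GetDimension()}")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError(
            f"{path}: expected a scalar image, got "
            f"{img.GetNumberOfComponentsPerPixel()} components")
    arr, spacing, origin = _from_sitk(img)
    return VolumeImage(arr, spacing, origin)


def write_volume(img: VolumeImage, path) -> None:
    """Write a volume as NIfTI or MetaImage; refuses non-finite intensities."""
    if not np.all(np.isfinite(img.data)):
        raise FormatError("volume contains NaN/Inf intensities; refusing to write")
    sitk.WriteImage(_to_sitk(img.data, img.spacing, img.origin), str(path))


def read_labelmap(path, dictionary=None) -> LabelMap:
    """Read an integer label map and validate its labels against a dictionary."""
    vol = read_volume(path)
    dictionary = dict(DEFAULT_LABELS) if dictionary is None else dict(dictionary)
    return LabelMap(vol.data, vol.spacing, vol.origin, dictionary)


def write_labelmap(labels: LabelMap, path) -> None:
    sitk.WriteImage(
        _to_sitk(labels.labels.astype(np.int16), labels.spacing, labels.origin),
        str(path))


def read_displacement_field(path) -> DenseDisplacementField:
    """Read a 3-component vector image as a displacement field (mm)."""
    img = sitk.ReadImage(_check_path(path))
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: displacement field must be a 3D vector image")
    ncomp = img.GetNumberOfComponentsPerPixel()
    if ncomp != 3:
        raise FormatError(
            f"{path}: displacement field needs 3 components, found {ncomp}")
    arr, spacing, origin = _from_sitk(img, vector=True)
    return DenseDisplacementField(arr, spacing, origin)


def write_displacement_field(fld: DenseDisplacementField, path) -> None:
    sitk.WriteImage(
        _to_sitk(fld.vectors.astype(np.float64), fld.spacing, fld.origin,
                 vector=True),
        str(path))


def resample_to_isotropic(img, spacing_mm=1.0, interp="linear"):
    """Resample a VolumeImage/LabelMap to an isotropic grid.

    The common working grid for the pipeline; labels use nearest-neighbour.
    """
    is_labels = isinstance(img, LabelMap)
    arr = img.labels if is_labels else img.data
    src = _to_sitk(arr.astype(np.float32), img.spacing, img.origin)
    new_spacing = (float(spacing_mm),) * 3
    new_size = [max(1, int(np.ceil(d * s / spacing_mm)))
                for d, s in zip(arr.shape, img.spacing)]
    mode = sitk.sitkNearestNeighbor if (is_labels or interp == "nearest") \
        else sitk.sitkLinear
    out = sitk.Resample(src, new_size, sitk.Transform(), mode,
                        img.origin, new_spacing, (1.0, 0, 0, 0, 1.0, 0, 0, 0, 1.0),
                        0.0, sitk.sitkFloat32)
    data, spacing, origin = _from_sitk(out)
    if is_labels:
        return LabelMap(np.round(data).astype(np.int32), spacing, origin,
                        dict(img.label_dictionary))
    return VolumeImage(data, spacing, origin)
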