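"""Volumetric image container and NIfTI-1 I/O.

A :class:`VolumeImage` is a 3D scalar grid plus the minimal world-space
metadata needed by the projector and simulator: voxel size in mm and the
world position (mm) of the *center* of voxel ``(0, 0, 0)``.  Volumes carry a
semantic role (activity, attenuation in cm^-1 at 511 keV, Hounsfield units,
reconstructed PET intensity, integer tissue label, or binary mask) so that
operations can reject inputs that make no physical sense.

World coordinates are in mm; voxel indices are 0-based; by default the
origin is chosen so the volume is centered on the world origin (the scanner
isocenter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    GeometryError,
    InvalidSpecError,
    SemanticsError,
    UnsupportedOrientationError,
)

#: Recognised semantic roles of a volume.
SEMANTICS = ("activity", "attenuation", "hounsfield", "pet_intensity", "label", "mask")

#: Tissue classes understood by the phantom and map-building machinery.
TISSUES = ("air", "csf", "white_matter", "gray_matter", "bone", "soft_tissue")


def centered_origin(shape, voxel_size_mm) -> tuple[float, float, float]:
    """Origin (center of voxel 0,0,0) that centers the grid on the world origin."""
    return tuple(-(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size_mm))


@dataclass
class VolumeImage:
    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] | None = None
    semantics: str = "pet_intensity"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise InvalidSpecError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidSpecError(f"voxel sizes must be three positive reals, got {self.voxel_size_mm}")
        if self.origin_mm is None:
            self.origin_mm = centered_origin(self.data.shape, self.voxel_size_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if self.semantics not in SEMANTICS:
            raise SemanticsError(f"unknown semantics {self.semantics!r}; expected one of {SEMANTICS}")
        if self.semantics == "attenuation" and np.any(self.data < 0):
            raise InvalidSpecError("attenuation volume has negative values")
        if self.semantics == "mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise InvalidSpecError(f"mask volume must contain only {{0,1}}, found values {vals[:10]}")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + self.voxel_size_mm[axis] * np.arange(self.shape[axis])

    def same_grid(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def require_same_grid(self, other: "VolumeImage", what: str = "volumes"):
        if not self.same_grid(other):
            raise GeometryError(
                f"{what} must share one grid: {self.shape}@{self.voxel_size_mm} vs "
                f"{other.shape}@{other.voxel_size_mm}"
            )

    def like(self, data: np.ndarray, semantics: str | None = None) -> "VolumeImage":
        """New volume on this grid with different data (and optionally role)."""
        return VolumeImage(
            data=data,
            voxel_size_mm=self.voxel_size_mm,
            origin_mm=self.origin_mm,
            semantics=semantics or self.semantics,
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass
class TissueSegmentation:
    """Integer label volume plus the label -> tissue legend."""

    labels: VolumeImage
    legend: Mapping[int, str]

    def __post_init__(self):
        if self.labels.semantics != "label":
            raise SemanticsError("segmentation labels must have semantics='label'")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        bad = set(self.legend.values()) - set(TISSUES)
        if bad:
            raise InvalidSpecError(f"unknown tissue names in legend: {sorted(bad)}")
        if "air" not in self.legend.values():
            raise InvalidSpecError("segmentation legend must include an air label")
        present = set(np.unique(self.labels.data).astype(int).tolist())
        missing = present - set(self.legend)
        if missing:
            raise InvalidSpecError(f"voxel labels {sorted(missing)} missing from legend")

    def mask_for(self, tissue: str) -> np.ndarray:
        """Boolean mask of all voxels carrying the given tissue class."""
        ids = [k for k, v in self.legend.items() if v == tissue]
        return np.isin(self.labels.data, ids)

    def head_mask(self) -> VolumeImage:
        """Binary head-support mask: everything that is not air."""
        return self.labels.like((~self.mask_for("air")).astype(np.uint8), semantics="mask")


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------

def _decompose_affine(aff: np.ndarray):
    """Split an axis-aligned (up to flips/permutation) affine into voxel/origin.

    Returns (perm, flips, voxel, origin) mapping file axes to canonical +x+y+z
    order, or raises for oblique matrices.
    """
    R = aff[:3, :3]
    perm = [-1, -1, -1]
    flips = [1, 1, 1]
    voxel = [0.0, 0.0, 0.0]
    for col in range(3):
        nz = np.flatnonzero(np.abs(R[:, col]) > 1e-6 * max(1.0, np.abs(R).max()))
        if len(nz) != 1:
            raise UnsupportedOrientationError(
                "oblique NIfTI affine is not supported; resample the volume to an "
                "axis-aligned grid first"
            )
        row = int(nz[0])
        perm[col] = row
        flips[col] = 1 if R[row, col] > 0 else -1
        voxel[col] = abs(float(R[row, col]))
    if sorted(perm) != [0, 1, 2]:
        raise UnsupportedOrientationError("affine does not define a one-to-one axis mapping")
    return perm, flips, voxel, aff[:3, 3].astype(float)


def read_volume(path, semantics: str = "pet_intensity", nan_policy: str = "zero") -> VolumeImage:
    """Read a NIfTI-1 volume (.nii or .nii.gz) into a :class:`VolumeImage`.

    The affine must be axis-aligned up to axis flips; data are reoriented so
    all three axes increase with world coordinates.  NaN voxels are zero
    filled with a warning (``nan_policy='zero'``) or left in place
    (``nan_policy='keep'``).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise InvalidSpecError(f"expected a 3D volume, got shape {data.shape}")
    perm, flips, voxel, trans = _decompose_affine(img.affine)
    # reorder data axes so data axis i corresponds to world axis i
    inv = np.argsort(perm)  # world axis -> file axis
    data = np.transpose(data, axes=tuple(inv))
    voxel = [voxel[i] for i in inv]
    flips = [flips[i] for i in inv]
    origin = np.empty(3)
    for ax in range(3):
        n = data.shape[ax]
        if flips[ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = trans[ax] - voxel[ax] * (n - 1)
        else:
            origin[ax] = trans[ax]
    data = np.ascontiguousarray(data)
    if np.issubdtype(data.dtype, np.floating) and np.isnan(data).any():
        warnings.warn(f"{path}: NaN voxels encountered; policy={nan_policy}")
        if nan_policy == "zero":
            data = np.nan_to_num(data, nan=0.0)
    return VolumeImage(data=data, voxel_size_mm=tuple(voxel), origin_mm=tuple(origin), semantics=semantics)


def write_volume(vol: VolumeImage, path) -> None:
    """Write a :class:`VolumeImage` as NIfTI-1, preserving dtype and grid."""
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def read_dicom_series(paths: Iterable, semantics: str = "hounsfield") -> VolumeImage:
    """Minimal read-only DICOM series loader (axial, axis-aligned series)."""
    import pydicom

    slices = [pydicom.dcmread(str(p)) for p in paths]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    data = np.stack([s.pixel_array * float(getattr(s, "RescaleSlope", 1.0))
                     + float(getattr(s, "RescaleIntercept", 0.0)) for s in slices], axis=-1)
    data = np.ascontiguousarray(np.transpose(data, (1, 0, 2)))
    s0 = slices[0]
    dz = (float(slices[1].ImagePositionPatient[2]) - float(s0.ImagePositionPatient[2])
          if len(slices) > 1 else float(getattr(s0, "SliceThickness", 1.0)))
    voxel = (float(s0.PixelSpacing[1]), float(s0.PixelSpacing[0]), abs(dz))
    origin = tuple(float(v) for v in s0.ImagePositionPatient)
    return VolumeImage(data=data, voxel_size_mm=voxel, origin_mm=origin, semantics=semantics)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to(vol: VolumeImage, shape, voxel_size_mm, origin_mm=None, order: int = 1) -> VolumeImage:
    """Trilinear (order=1) or nearest (order=0) resample onto a target grid.

    Intended for grid harmonisation between phantom, scanner and statistics
    grids; it is not a registration tool — both grids share world space.
    """
    shape = tuple(int(n) for n in shape)
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
    if origin_mm is None:
        origin_mm = centered_origin(shape, voxel_size_mm)
    coords = np.meshgrid(*[origin_mm[a] + voxel_size_mm[a] * np.arange(shape[a]) for a in range(3)],
                         indexing="ij")
    idx = [(coords[a] - vol.origin_mm[a]) / vol.voxel_size_mm[a] for a in range(3)]
    out = ndimage.map_coordinates(np.asarray(vol.data, dtype=float), np.stack(idx), order=order,
                                  mode="constant", cval=0.0)
    return VolumeImage(out, voxel_size_mm, origin_mm, semantics=vol.semantics)


def resample_like(vol: VolumeImage, ref: VolumeImage, order: int = 1) -> VolumeImage:
    if vol.same_grid(ref):
        return vol
    return resample_to(vol, ref.shape, ref.voxel_size_mm, ref.origin_mm, order=order)
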