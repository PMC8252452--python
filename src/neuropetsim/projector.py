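"""Line-integral machinery shared by the simulator and the reconstruction.

The sinogram is a plane x angle x radial histogram of LORs.  Radial bin
``s`` is the signed distance of the LOR from the isocenter, azimuth
``phi in [0, pi)`` is sampled uniformly (bin centers at ``(a+0.5)*dphi``),
and planes coincide with the z slices of the scanner's reconstruction grid
(3D ring-pair data are single-slice rebinned onto this grid, see
:func:`neuropetsim.recon.ssrb`).  Radial bins are uniform in ``s`` — no arc
correction is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import GeometryError, InvalidSpecError
from .scanners import ScannerModel
from .volume import VolumeImage, resample_to

SINOGRAM_KINDS = ("prompts", "trues", "scatter", "expected", "acf")
_COUNT_KINDS = ("prompts", "trues", "scatter")


@dataclass
class Sinogram:
    data: np.ndarray  # [n_planes, n_angles, n_radial]
    kind: str
    scanner_name: str = ""
    radial_bin_size_mm: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidSpecError(f"sinogram must be 3D, got shape {self.data.shape}")
        if self.kind not in SINOGRAM_KINDS:
            raise InvalidSpecError(f"unknown sinogram kind {self.kind!r}")
        if self.kind in _COUNT_KINDS:
            if np.any(self.data < 0):
                raise InvalidSpecError(f"{self.kind} sinogram must be >= 0")
            if not np.allclose(self.data, np.round(self.data)):
                raise InvalidSpecError(f"{self.kind} sinogram must be integer-valued")
        if self.kind == "acf" and np.any(self.data < 1.0 - 1e-9):
            raise InvalidSpecError("ACF sinogram values must be >= 1")

    @property
    def shape(self):
        return self.data.shape

    @property
    def total_counts(self) -> float:
        return float(self.data.sum())

    def require_dims(self, scanner: ScannerModel):
        want = (scanner.n_planes, scanner.n_angles, scanner.n_radial)
        if self.data.shape != want:
            raise GeometryError(
                f"sinogram dims {self.data.shape} do not match scanner "
                f"{scanner.name} dims {want}"
            )


@dataclass
class RayPath:
    """Ordered voxel/length decomposition of a ray segment through a grid."""

    voxels: list  # of (i, j, k)
    lengths_mm: list  # of float, > 0

    def total_length(self) -> float:
        return float(sum(self.lengths_mm))

    def integrate(self, vol: VolumeImage) -> float:
        data = np.asarray(vol.data)
        return float(sum(data[v] * l for v, l in zip(self.voxels, self.lengths_mm)))


def siddon_path(p1_mm, p2_mm, grid: VolumeImage) -> RayPath:
    """Exact voxel traversal of the segment p1 -> p2 clipped to the grid.

    A segment that misses the grid yields an empty path.  Incremental
    (Amanatides-Woo) implementation of Siddon's decomposition; the sum of
    lengths equals the chord length of the segment inside the grid bounding
    box to floating-point accuracy.
    """
    p1 = np.asarray(p1_mm, dtype=float)
    p2 = np.asarray(p2_mm, dtype=float)
    if np.allclose(p1, p2):
        raise InvalidSpecError("ray endpoints must differ")
    d = p2 - p1
    seg_len = float(np.linalg.norm(d))
    u = d / seg_len
    shape = grid.shape
    voxel = grid.voxel_size_mm
    lo = [grid.origin_mm[a] - voxel[a] / 2.0 for a in range(3)]
    hi = [lo[a] + shape[a] * voxel[a] for a in range(3)]

    tmin, tmax = 0.0, seg_len
    for a in range(3):
        if abs(u[a]) < 1e-12:
            if p1[a] <= lo[a] or p1[a] >= hi[a]:
                return RayPath([], [])
        else:
            t1 = (lo[a] - p1[a]) / u[a]
            t2 = (hi[a] - p1[a]) / u[a]
            if t1 > t2:
                t1, t2 = t2, t1
            tmin = max(tmin, t1)
            tmax = min(tmax, t2)
    if tmax <= tmin:
        return RayPath([], [])

    t = tmin
    pos = p1 + t * u
    idx = [int(np.floor((pos[a] - lo[a]) / voxel[a])) for a in range(3)]
    for a in range(3):
        idx[a] = min(max(idx[a], 0), shape[a] - 1)
    step, tdelta, tnextb = [0] * 3, [np.inf] * 3, [np.inf] * 3
    for a in range(3):
        if u[a] > 0:
            step[a] = 1
            tdelta[a] = voxel[a] / u[a]
            tnextb[a] = ((idx[a] + 1) * voxel[a] + lo[a] - p1[a]) / u[a]
        elif u[a] < 0:
            step[a] = -1
            tdelta[a] = -voxel[a] / u[a]
            tnextb[a] = (idx[a] * voxel[a] + lo[a] - p1[a]) / u[a]

    voxels, lengths = [], []
    while t < tmax - 1e-12:
        a = int(np.argmin(tnextb))
        tnext = min(tnextb[a], tmax)
        seg = tnext - t
        if seg > 1e-12:
            voxels.append(tuple(idx))
            lengths.append(seg)
        t = tnext
        if tnext == tnextb[a]:
            idx[a] += step[a]
            tnextb[a] += tdelta[a]
            if idx[a] < 0 or idx[a] >= shape[a]:
                break
    return RayPath(voxels, lengths)


# ---------------------------------------------------------------------------
# Scanner-space projection
# ---------------------------------------------------------------------------

def sinogram_geometry(scanner: ScannerModel):
    """Angle cos/sin arrays and radial bin-center positions (mm)."""
    dphi = np.pi / scanner.n_angles
    phis = (np.arange(scanner.n_angles) + 0.5) * dphi
    svals = (np.arange(scanner.n_radial) - (scanner.n_radial - 1) / 2.0) * scanner.radial_bin_size_mm
    return np.cos(phis), np.sin(phis), svals


def on_scanner_grid(vol: VolumeImage, scanner: ScannerModel) -> VolumeImage:
    """Resample a volume onto the scanner's reconstruction grid if needed.

    The projector requires the volume's z slices to coincide with the
    sinogram planes; any grid mismatch is resolved by trilinear resampling
    onto the full reconstruction grid (which is FOV-centered).
    """
    from .volume import centered_origin

    want_shape = scanner.recon_shape
    want_voxel = scanner.recon_voxel_mm
    if (vol.shape == want_shape and np.allclose(vol.voxel_size_mm, want_voxel, atol=1e-6)
            and np.allclose(vol.origin_mm, centered_origin(want_shape, want_voxel), atol=1e-6)):
        return vol
    if float(np.hypot(vol.shape[0] * vol.voxel_size_mm[0], vol.shape[1] * vol.voxel_size_mm[1])) / 2.0 \
            > scanner.ring_radius_mm:
        raise GeometryError(
            f"volume transaxial extent exceeds the {scanner.name} detector ring"
        )
    return resample_to(vol, want_shape, want_voxel, order=1)


def _vol_to_planes(vol: VolumeImage) -> np.ndarray:
    return np.ascontiguousarray(np.moveaxis(np.asarray(vol.data, dtype=np.float64), 2, 0))


def forward_project(vol: VolumeImage, scanner: ScannerModel, angle_indices=None) -> Sinogram:
    """Line integrals (value * mm) of ``vol`` along every LOR of the scanner.

    Linear in the input.  ``angle_indices`` restricts the projection to an
    angular subset (used by OSEM); the returned sinogram then has that many
    angle rows.
    """
    vol = on_scanner_grid(vol, scanner)
    cos_a, sin_a, svals = sinogram_geometry(scanner)
    if angle_indices is not None:
        cos_a = cos_a[angle_indices]
        sin_a = sin_a[angle_indices]
    volz = _vol_to_planes(vol)
    sino = np.zeros((scanner.n_planes, len(cos_a), scanner.n_radial), dtype=np.float64)
    xmin = vol.origin_mm[0] - vol.voxel_size_mm[0] / 2.0
    ymin = vol.origin_mm[1] - vol.voxel_size_mm[1] / 2.0
    _kernels.fp_kernel(volz, sino, cos_a, sin_a, svals,
                       vol.voxel_size_mm[0], vol.voxel_size_mm[1], xmin, ymin)
    return Sinogram(sino, kind="expected", scanner_name=scanner.name,
                    radial_bin_size_mm=scanner.radial_bin_size_mm)


def back_project(sino: Sinogram, scanner: ScannerModel, angle_indices=None) -> VolumeImage:
    """Adjoint of :func:`forward_project` onto the scanner recon grid."""
    cos_a, sin_a, svals = sinogram_geometry(scanner)
    if angle_indices is not None:
        cos_a = cos_a[angle_indices]
        sin_a = sin_a[angle_indices]
    want = (scanner.n_planes, len(cos_a), scanner.n_radial)
    if sino.data.shape != want:
        raise GeometryError(f"sinogram dims {sino.data.shape} do not match {want}")
    nx, ny, nz = scanner.recon_shape
    vx, vy, vz = scanner.recon_voxel_mm
    from .volume import centered_origin

    origin = centered_origin(scanner.recon_shape, scanner.recon_voxel_mm)
    volz = np.zeros((nz, nx, ny), dtype=np.float64)
    xmin = origin[0] - vx / 2.0
    ymin = origin[1] - vy / 2.0
    _kernels.bp_kernel(np.asarray(sino.data, dtype=np.float64), volz, cos_a, sin_a, svals,
                       vx, vy, xmin, ymin)
    data = np.ascontiguousarray(np.moveaxis(volz, 0, 2))
    return VolumeImage(data, scanner.recon_voxel_mm, origin, semantics="pet_intensity")


def attenuation_sinogram(mu: VolumeImage, scanner: ScannerModel) -> Sinogram:
    """Attenuation correction factors exp(+integral mu dl), dl in cm.

    ``mu`` is linear attenuation at 511 keV in cm^-1; every bin is >= 1.
    """
    if mu.semantics != "attenuation":
        raise InvalidSpecError("attenuation volume required (semantics='attenuation')")
    if np.any(np.asarray(mu.data) < 0):
        raise InvalidSpecError("attenuation map has negative values")
    line = forward_project(mu, scanner)  # (cm^-1) * mm
    acf = np.exp(line.data / 10.0)
    return Sinogram(acf, kind="acf", scanner_name=scanner.name,
                    radial_bin_size_mm=scanner.radial_bin_size_mm)
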