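"""OSEM/MLEM reconstruction with attenuation correction.

The update is the standard multiplicative expectation-maximization step
over angle-interleaved subsets

    x <- x / BP_S(A . 1) * BP_S( y / (A . FP_S(x) + s + eps) )

where ``A`` multiplies by the attenuation survival factor ``1/ACF`` and
``s`` is an optional additive scatter estimate in the data.  One subset
equal to all angles reduces to MLEM.  3D ring-pair data are single-slice
rebinned (:func:`ssrb`) before reconstruction; within this package the
simulator already histograms coincidences onto direct planes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InvalidSpecError
from .projector import Sinogram, back_project, forward_project
from .scanners import ScannerModel
from .volume import VolumeImage, centered_origin

log = logging.getLogger(__name__)


@dataclass
class ReconConfig:
    n_iterations: int | None = None     # default: scanner.osem_iterations
    n_subsets: int | None = None        # default: scanner.osem_subsets
    attenuation: Sinogram | None = None  # ACF sinogram
    scatter_estimate: Sinogram | None = None
    post_filter_fwhm_mm: float | None = None  # default: scanner.post_filter_fwhm_mm
    epsilon: float = 1e-12
    initial: VolumeImage | None = None        # starting image (default: uniform ones)

    def resolved(self, scanner: ScannerModel):
        it = self.n_iterations if self.n_iterations is not None else scanner.osem_iterations
        sub = self.n_subsets if self.n_subsets is not None else scanner.osem_subsets
        fwhm = (self.post_filter_fwhm_mm if self.post_filter_fwhm_mm is not None
                else scanner.post_filter_fwhm_mm)
        if it < 1:
            raise InvalidSpecError("n_iterations must be >= 1")
        if sub < 1 or scanner.n_angles % sub != 0:
            raise InvalidSpecError(
                f"n_subsets ({sub}) must divide n_angles ({scanner.n_angles})"
            )
        return it, sub, fwhm


def osem(prompts: Sinogram, scanner: ScannerModel, config: ReconConfig | None = None) -> VolumeImage:
    """Reconstruct a sinogram onto the scanner's published grid.

    Returns a nonnegative PET-intensity volume; an optional Gaussian post
    filter models unresolved detector blurring.
    """
    config = config or ReconConfig()
    prompts.require_dims(scanner)
    if prompts.kind not in ("prompts", "trues", "expected"):
        raise InvalidSpecError(f"cannot reconstruct a {prompts.kind!r} sinogram")
    n_iter, n_sub, post_fwhm = config.resolved(scanner)

    y = np.asarray(prompts.data, dtype=np.float64)
    if np.any(y < 0):
        raise InvalidSpecError("prompts must be >= 0")

    origin = centered_origin(scanner.recon_shape, scanner.recon_voxel_mm)
    if y.sum() == 0:
        warnings.warn("all-zero prompts sinogram: returning a zero volume")
        return VolumeImage(np.zeros(scanner.recon_shape), scanner.recon_voxel_mm, origin,
                           semantics="pet_intensity")

    if config.attenuation is not None:
        config.attenuation.require_dims(scanner)
        att = 1.0 / np.asarray(config.attenuation.data, dtype=np.float64)
    else:
        att = np.ones_like(y)
    if config.scatter_estimate is not None:
        config.scatter_estimate.require_dims(scanner)
        scat = np.asarray(config.scatter_estimate.data, dtype=np.float64)
    else:
        scat = None

    subsets = [np.arange(s, scanner.n_angles, n_sub) for s in range(n_sub)]
    sino_geom = dict(kind="expected", scanner_name=scanner.name,
                     radial_bin_size_mm=scanner.radial_bin_size_mm)

    # per-subset sensitivity images BP_S(A . 1)
    sens = []
    for idx in subsets:
        s_img = back_project(Sinogram(np.ascontiguousarray(att[:, idx, :]), **sino_geom),
                             scanner, angle_indices=idx)
        sens.append(np.asarray(s_img.data))

    if config.initial is not None:
        if config.initial.shape != scanner.recon_shape:
            raise GeometryError("initial image must live on the scanner recon grid")
        x = np.asarray(config.initial.data, dtype=np.float64).copy()
    else:
        x = np.ones(scanner.recon_shape, dtype=np.float64)
    vol = VolumeImage(x, scanner.recon_voxel_mm, origin, semantics="pet_intensity")
    eps = config.epsilon
    for it in range(n_iter):
        for s_i, idx in enumerate(subsets):
            fp = forward_project(vol, scanner, angle_indices=idx).data
            denom = att[:, idx, :] * fp + eps
            if scat is not None:
                denom = denom + scat[:, idx, :]
            ratio = y[:, idx, :] / denom
            corr = back_project(
                Sinogram(np.ascontiguousarray(att[:, idx, :] * ratio), **sino_geom),
                scanner, angle_indices=idx,
            ).data
            sj = sens[s_i]
            upd = np.zeros_like(x)
            np.divide(corr, sj, out=upd, where=sj > 0)
            x = x * upd
            vol = VolumeImage(x, scanner.recon_voxel_mm, origin, semantics="pet_intensity")
        log.debug("OSEM iteration %d/%d done (total %g)", it + 1, n_iter, x.sum())

    if post_fwhm and post_fwhm > 0:
        sigma = [post_fwhm / 2.3548200450309493 / v for v in scanner.recon_voxel_mm]
        x = ndimage.gaussian_filter(x, sigma=sigma)
    return VolumeImage(np.clip(x, 0.0, None), scanner.recon_voxel_mm, origin,
                       semantics="pet_intensity")


def sensitivity_image(scanner: ScannerModel, acf: Sinogram | None = None) -> VolumeImage:
    """Full back projection BP(A . 1); useful for count-accounting checks."""
    dims = (scanner.n_planes, scanner.n_angles, scanner.n_radial)
    att = (1.0 / np.asarray(acf.data, dtype=np.float64)) if acf is not None else np.ones(dims)
    return back_project(Sinogram(att, kind="expected", scanner_name=scanner.name,
                                 radial_bin_size_mm=scanner.radial_bin_size_mm), scanner)


def ssrb(ringpair_data: np.ndarray, kind: str = "trues", scanner_name: str = "",
         radial_bin_size_mm: float = 1.0) -> Sinogram:
    """Single-slice rebinning of ring-pair data [n_rings, n_rings, n_angles, n_radial].

    Ring pair (i, j) accumulates into plane i + j, giving 2*n_rings - 1
    planes; total counts are conserved exactly.
    """
    arr = np.asarray(ringpair_data)
    if arr.ndim != 4 or arr.shape[0] != arr.shape[1]:
        raise GeometryError("expected ring-pair data shaped [n_rings, n_rings, n_angles, n_radial]")
    n_rings = arr.shape[0]
    out = np.zeros((2 * n_rings - 1,) + arr.shape[2:], dtype=arr.dtype)
    for i in range(n_rings):
        for j in range(n_rings):
            out[i + j] += arr[i, j]
    return Sinogram(out, kind=kind, scanner_name=scanner_name,
                    radial_bin_size_mm=radial_bin_size_mm)
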