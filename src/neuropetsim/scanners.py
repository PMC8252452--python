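"""Parameterised tomograph models.

Three commercial scanners ship as YAML files (GE Discovery ST, GE Advance
NXi, Siemens Biograph mCT); any other tomograph can be described by a user
YAML with the same schema.  Reconstruction grids and voxel sizes for the
built-in models follow the matrices these scanners produce clinically
(128x128x47 @ 1.95x1.95x3.27 mm, 128x128x35 @ 2.05x2.05x4.3 mm,
400x400x148 @ 1.02x1.02x1.50 mm).  Ring geometry, energy resolution and
energy windows are implementer-chosen defaults from vendor literature (BGO
blocks with ~15% energy resolution and a 375-650 keV window for the two GE
scanners, LSO with ~12% and 435-650 keV for the mCT); they are stored
transparently in the YAML files and can be overridden freely.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import InvalidSpecError

BUILTIN_SCANNERS = ("discovery_st", "advance_nxi", "biograph_mct")


@dataclass
class ScannerModel:
    name: str
    ring_radius_mm: float
    n_rings: int
    n_crystals_per_ring: int
    crystal_axial_pitch_mm: float
    energy_resolution_fwhm_fraction: float   # FWHM / 511 keV
    energy_window_kev: tuple[float, float]
    n_radial: int
    n_angles: int
    n_planes: int
    radial_bin_size_mm: float
    recon_shape: tuple[int, int, int]
    recon_voxel_mm: tuple[float, float, float]
    osem_subsets: int = 21
    osem_iterations: int = 2
    post_filter_fwhm_mm: float = 5.0

    def __post_init__(self):
        self.energy_window_kev = tuple(float(v) for v in self.energy_window_kev)
        self.recon_shape = tuple(int(v) for v in self.recon_shape)
        self.recon_voxel_mm = tuple(float(v) for v in self.recon_voxel_mm)
        self.validate()

    def validate(self):
        lo, hi = self.energy_window_kev
        if not lo < hi:
            raise InvalidSpecError(f"{self.name}: energy window low must be < high, got {lo}..{hi}")
        if self.n_radial < 4 or self.n_angles < 4:
            raise InvalidSpecError(f"{self.name}: n_radial and n_angles must be >= 4")
        if self.ring_radius_mm <= self.fov_radius_mm:
            raise InvalidSpecError(
                f"{self.name}: ring radius {self.ring_radius_mm} mm must exceed the "
                f"transaxial FOV radius {self.fov_radius_mm:.1f} mm"
            )
        if self.n_planes != self.recon_shape[2]:
            raise InvalidSpecError(
                f"{self.name}: n_planes ({self.n_planes}) must equal the axial recon "
                f"dimension ({self.recon_shape[2]}) — planes and recon slices share the z grid"
            )
        if any(v <= 0 for v in self.recon_voxel_mm) or self.radial_bin_size_mm <= 0:
            raise InvalidSpecError(f"{self.name}: bin and voxel sizes must be positive")
        if self.osem_subsets < 1 or self.osem_iterations < 1:
            raise InvalidSpecError(f"{self.name}: OSEM defaults must be >= 1")

    # -- derived geometry -------------------------------------------------

    @property
    def fov_radius_mm(self) -> float:
        """Transaxial radius covered by the radial sinogram bins."""
        return self.n_radial * self.radial_bin_size_mm / 2.0

    @property
    def plane_spacing_mm(self) -> float:
        return self.recon_voxel_mm[2]

    @property
    def axial_half_extent_mm(self) -> float:
        return self.n_planes * self.plane_spacing_mm / 2.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["energy_window_kev"] = list(self.energy_window_kev)
        d["recon_shape"] = list(self.recon_shape)
        d["recon_voxel_mm"] = list(self.recon_voxel_mm)
        return d


def load_scanner(name_or_path: str | Path) -> ScannerModel:
    """Load a built-in model by name or any model from a YAML path."""
    name = str(name_or_path)
    if name in BUILTIN_SCANNERS:
        text = (importlib.resources.files("neuropetsim") / "data" / f"{name}.yaml").read_text()
    else:
        p = Path(name_or_path)
        if not p.exists():
            raise InvalidSpecError(
                f"unknown scanner {name!r}: not one of {BUILTIN_SCANNERS} and no such file"
            )
        text = p.read_text()
    raw = yaml.safe_load(text)
    try:
        return ScannerModel(**raw)
    except TypeError as e:
        raise InvalidSpecError(f"scanner YAML {name}: {e}") from e


def save_scanner(model: ScannerModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def rescale_scanner(model: ScannerModel, recon_shape, n_radial=None, n_angles=None,
                    name: str | None = None) -> ScannerModel:
    """Derive a coarser (or finer) variant of a model preserving its FOV.

    Useful for fast experiments: the reconstruction grid is resized keeping
    the physical field of view, and the sinogram sampling is rescaled to
    match.  Ring geometry and energy response are untouched.
    """
    recon_shape = tuple(int(v) for v in recon_shape)
    old_extent = [model.recon_shape[i] * model.recon_voxel_mm[i] for i in range(3)]
    voxel = tuple(old_extent[i] / recon_shape[i] for i in range(3))
    n_radial = int(n_radial) if n_radial else max(4, round(model.n_radial * recon_shape[0] / model.recon_shape[0]))
    n_angles = int(n_angles) if n_angles else max(4, round(model.n_angles * recon_shape[0] / model.recon_shape[0]))
    radial_extent = model.n_radial * model.radial_bin_size_mm
    import math

    subsets = math.gcd(model.osem_subsets, n_angles)
    d = model.to_dict()
    d.update(
        osem_subsets=subsets,
        name=name or f"{model.name}_{recon_shape[0]}x{recon_shape[1]}x{recon_shape[2]}",
        n_radial=n_radial,
        n_angles=n_angles,
        n_planes=recon_shape[2],
        radial_bin_size_mm=radial_extent / n_radial,
        recon_shape=list(recon_shape),
        recon_voxel_mm=list(voxel),
    )
    return ScannerModel(**d)
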