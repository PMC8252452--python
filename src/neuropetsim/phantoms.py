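"""Digital brain phantoms and initial activity/attenuation maps.

Two entry points serve two workflows:

* :func:`generate_brain_phantom` creates a fully synthetic head — nested
  ellipsoidal compartments (scalp soft tissue > skull bone > CSF > a
  convoluted gray-matter shell > white-matter core, plus a central
  ventricle) — with per-tissue activity ratios (gray:white:csf defaulting to
  the Hoffman-phantom convention 4:1:0), an optional smooth multiplicative
  variability field emulating physiological voxel-wise variation, and
  optional spherical lesions.

* :func:`build_initial_maps` replicates the map-initialisation stage of the
  iterative refinement loop: a piecewise-uniform activity map filled from a
  tissue segmentation, and an attenuation map joining a CT-derived bone mask
  with the head support (soft tissue everywhere inside the head that is not
  bone, zero in air).

Attenuation coefficients are linear attenuation at 511 keV in cm^-1; the
defaults (0.096 for water-like tissue, 0.151 for bone) are standard values
and fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .errors import GeometryError, InvalidSpecError, SemanticsError
from .volume import TISSUES, TissueSegmentation, VolumeImage, centered_origin

#: Default linear attenuation coefficients at 511 keV (cm^-1).
DEFAULT_MU_CM = {
    "air": 0.0,
    "csf": 0.096,
    "white_matter": 0.096,
    "gray_matter": 0.096,
    "soft_tissue": 0.096,
    "bone": 0.151,
}

#: Default relative activity per tissue (gray:white:csf = 4:1:0; modest
#: extracerebral soft-tissue uptake).
DEFAULT_ACTIVITY_RATIOS = {
    "air": 0.0,
    "csf": 0.0,
    "white_matter": 1.0,
    "gray_matter": 4.0,
    "bone": 0.0,
    "soft_tissue": 0.25,
}

#: Canonical label ids used by generated segmentations.
LABELS = {name: i for i, name in enumerate(TISSUES)}


@dataclass
class Lesion:
    center_mm: tuple[float, float, float]
    radius_mm: float
    activity_factor: float

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise InvalidSpecError("lesion radius must be > 0")
        if self.activity_factor < 0:
            raise InvalidSpecError("lesion activity factor must be >= 0")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 31)
    voxel_size_mm: tuple[float, float, float] = (3.9, 3.9, 4.96)
    activity_ratios: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVITY_RATIOS))
    attenuation_cm: dict = field(default_factory=lambda: dict(DEFAULT_MU_CM))
    lesions: list = field(default_factory=list)
    variability_amplitude: float = 0.0
    variability_fwhm_mm: float = 12.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if min(self.shape) < 16:
            raise InvalidSpecError(
                f"grid {self.shape} too small to contain the smallest compartment; >= 16 per axis required"
            )
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidSpecError("voxel sizes must be positive")
        if any(r < 0 for r in self.activity_ratios.values()):
            raise InvalidSpecError("activity ratios must be >= 0")
        if any(m < 0 for m in self.attenuation_cm.values()):
            raise InvalidSpecError("attenuation coefficients must be >= 0")
        self.lesions = [l if isinstance(l, Lesion) else Lesion(**l) for l in self.lesions]
        if self.variability_amplitude < 0:
            raise InvalidSpecError("variability amplitude must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _smooth_unit_field(shape, voxel_size_mm, fwhm_mm, rng) -> np.ndarray:
    """Zero-mean, unit-std smooth Gaussian random field (clipped at +-3)."""
    noise = rng.standard_normal(shape)
    sigma_vox = [max(fwhm_mm / 2.3548200450309493 / v, 1e-6) for v in voxel_size_mm]
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return np.clip((f - f.mean()) / sd, -3.0, 3.0)


def generate_brain_phantom(spec: PhantomSpec):
    """Build a synthetic head phantom.

    Returns ``(activity, attenuation, segmentation)`` on the grid defined by
    the spec, centered on the world origin.  Deterministic for a fixed seed.
    """
    shape, voxel = spec.shape, spec.voxel_size_mm
    origin = centered_origin(shape, voxel)
    rng = np.random.default_rng(spec.seed)

    coords = np.meshgrid(
        *[origin[a] + voxel[a] * np.arange(shape[a]) for a in range(3)], indexing="ij"
    )
    half = [shape[a] * voxel[a] / 2.0 for a in range(3)]
    # normalized radial coordinate of nested ellipsoids (1 = grid half-extent)
    u = [coords[a] / half[a] for a in range(3)]
    rho = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)

    theta = np.arccos(np.clip(u[2] / np.maximum(rho, 1e-9), -1, 1))
    phi = np.arctan2(u[1], u[0])
    # convoluted gray/white boundary: sinusoidally modulated radius
    gw = 0.50 + 0.08 * np.sin(5 * theta + 1.0) * np.cos(3 * phi) + 0.04 * np.cos(7 * phi)

    labels = np.full(shape, LABELS["air"], dtype=np.int16)
    labels[rho < 0.90] = LABELS["soft_tissue"]
    labels[rho < 0.82] = LABELS["bone"]
    labels[rho < 0.74] = LABELS["csf"]
    labels[rho < 0.68] = LABELS["gray_matter"]
    labels[rho < gw] = LABELS["white_matter"]
    labels[rho < 0.12] = LABELS["csf"]  # central ventricle

    legend = {v: k for k, v in LABELS.items()}
    seg = TissueSegmentation(
        labels=VolumeImage(labels, voxel, origin, semantics="label"), legend=legend
    )

    activity = np.zeros(shape, dtype=np.float64)
    attenuation = np.zeros(shape, dtype=np.float64)
    for tissue, lab in LABELS.items():
        m = labels == lab
        activity[m] = spec.activity_ratios.get(tissue, 0.0)
        attenuation[m] = spec.attenuation_cm.get(tissue, 0.0)
    # activity is physically zero in air and bone regardless of ratios
    activity[(labels == LABELS["air"]) | (labels == LABELS["bone"])] = 0.0

    if spec.variability_amplitude > 0:
        fieldv = _smooth_unit_field(shape, voxel, spec.variability_fwhm_mm, rng)
        activity *= np.clip(1.0 + spec.variability_amplitude * fieldv, 0.1, None)

    for les in spec.lesions:
        d2 = sum((coords[a] - les.center_mm[a]) ** 2 for a in range(3))
        activity[d2 <= les.radius_mm ** 2] *= les.activity_factor

    act = VolumeImage(activity, voxel, origin, semantics="activity")
    mu = VolumeImage(attenuation, voxel, origin, semantics="attenuation")
    return act, mu, seg


def hu_to_bone_mask(ct: VolumeImage, threshold_hu: float = 600.0) -> VolumeImage:
    """Binary bone mask from a CT-like volume: 1 where HU >= threshold.

    The comparison is inclusive at the threshold.
    """
    if ct.semantics != "hounsfield":
        raise SemanticsError(f"expected a hounsfield volume, got semantics={ct.semantics!r}")
    return ct.like((np.asarray(ct.data) >= threshold_hu).astype(np.uint8), semantics="mask")


def build_initial_maps(seg: TissueSegmentation, bone_mask: VolumeImage, ratios: dict | None = None,
                       attenuation_cm: dict | None = None):
    """Initial piecewise-uniform activity and attenuation maps.

    Activity fills each segmented tissue with its ratio value (missing
    tissues default to zero) and is forced to zero on the bone mask.
    Attenuation is the bone coefficient on the bone mask, the soft-tissue
    coefficient on the remaining head support, and zero in air.
    """
    ratios = dict(DEFAULT_ACTIVITY_RATIOS if ratios is None else ratios)
    mu_cm = dict(DEFAULT_MU_CM if attenuation_cm is None else attenuation_cm)
    if bone_mask.semantics != "mask":
        raise SemanticsError("bone_mask must have semantics='mask'")
    if not seg.labels.same_grid(bone_mask):
        raise GeometryError("segmentation and bone mask must share the grid")

    labels = np.asarray(seg.labels.data)
    activity = np.zeros(labels.shape, dtype=np.float64)
    for lab, tissue in seg.legend.items():
        activity[labels == lab] = ratios.get(tissue, 0.0)
    bone = np.asarray(bone_mask.data).astype(bool)
    activity[bone] = 0.0

    head = np.asarray(seg.head_mask().data).astype(bool) | bone
    attenuation = np.zeros(labels.shape, dtype=np.float64)
    attenuation[head] = mu_cm.get("soft_tissue", 0.096)
    attenuation[bone] = mu_cm.get("bone", 0.151)

    act = seg.labels.like(activity, semantics="activity")
    mu = seg.labels.like(attenuation, semantics="attenuation")
    return act, mu
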