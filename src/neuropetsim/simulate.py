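"""Monte Carlo acquisition simulation and its analytic noise-free twin.

The number of decays actually tracked is the physical positron yield
``(D0/lambda)(1 - exp(-lambda T)) * branching`` scaled by a dimensionless
``sensitivity_scale`` calibration (absolute detector efficiency is not part
of the model; outputs are in relative units).  ``n_decays`` can override
the dose calculation directly.

``simulate`` is one MC realization (seed-deterministic).
``noise_free_projection`` returns the exact expectation of the trues
sinogram under the same acquisition model: an attenuated forward projection
scaled by the decay count, angular/radial bin widths, and the energy-window
acceptance for unscattered photons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _mc
from .errors import EmptySourceError, GeometryError, InvalidSpecError
from .projector import Sinogram, attenuation_sinogram, forward_project, on_scanner_grid, sinogram_geometry
from .scanners import ScannerModel
from .volume import VolumeImage

F18_HALF_LIFE_S = 6586.2
F18_BRANCHING = 0.967
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class SimulationConfig:
    dose_mbq: float = 245.0
    duration_s: float = 1200.0
    half_life_s: float = F18_HALF_LIFE_S
    branching: float = F18_BRANCHING
    sensitivity_scale: float = 2.0e-5
    n_decays: int | None = None       # overrides the dose/duration calculation
    noise: str = "poisson"            # "poisson" | "none"
    seed: int = 0
    noncollinearity: bool = True
    noncollinearity_fwhm_deg: float = 0.25
    positron_range: bool = False
    positron_range_fwhm_mm: float = 0.54

    def __post_init__(self):
        if self.dose_mbq <= 0 or self.duration_s <= 0:
            raise InvalidSpecError("dose and duration must be positive")
        if not 0 < self.branching <= 1:
            raise InvalidSpecError("positron branching must be in (0, 1]")
        if self.sensitivity_scale <= 0:
            raise InvalidSpecError("sensitivity_scale must be positive")
        if self.noise not in ("poisson", "none"):
            raise InvalidSpecError("noise must be 'poisson' or 'none'")


@dataclass
class SinogramSet:
    trues: Sinogram
    scatter: Sinogram
    prompts: Sinogram
    n_decays_simulated: int
    n_detected: int
    n_absorbed: int = 0
    n_escaped: int = 0
    n_window_rejected: int = 0

    def __post_init__(self):
        if not np.array_equal(self.prompts.data, self.trues.data + self.scatter.data):
            raise InvalidSpecError("prompts must equal trues + scatter binwise")
        if self.n_detected > 2 * self.n_decays_simulated:
            raise InvalidSpecError("detected coincidences exceed emitted pairs")

    @property
    def scatter_fraction(self) -> float:
        p = self.prompts.total_counts
        return self.scatter.total_counts / p if p > 0 else 0.0


def expected_decays(config: SimulationConfig) -> float:
    """Physical positron emissions over the scan: (D0/l)(1-e^(-lT)) * branching."""
    d0 = config.dose_mbq * 1e6  # decays / s
    lam = math.log(2.0) / config.half_life_s
    # -expm1 keeps the short-scan / long-half-life limits exact
    return d0 / lam * (-math.expm1(-lam * config.duration_s)) * config.branching


def n_simulated_decays(config: SimulationConfig) -> int:
    if config.n_decays is not None:
        return int(config.n_decays)
    return int(round(expected_decays(config) * config.sensitivity_scale))


def _prepare_maps(activity: VolumeImage, attenuation: VolumeImage | None, scanner: ScannerModel):
    if activity.semantics != "activity":
        raise InvalidSpecError("activity volume required (semantics='activity')")
    if np.any(np.asarray(activity.data) < 0):
        raise InvalidSpecError("activity map has negative values")
    if attenuation is not None:
        if attenuation.semantics != "attenuation":
            raise InvalidSpecError("attenuation volume required (semantics='attenuation')")
        if not activity.same_grid(attenuation):
            raise GeometryError("activity and attenuation maps must share the grid")
    act = on_scanner_grid(activity, scanner)
    act = act.like(np.clip(np.asarray(act.data, dtype=np.float64), 0.0, None))
    mu = on_scanner_grid(attenuation, scanner) if attenuation is not None else None
    if mu is not None:
        mu = mu.like(np.clip(np.asarray(mu.data, dtype=np.float64), 0.0, None))
    if float(np.sum(act.data)) <= 0:
        raise EmptySourceError("activity map contains no activity")
    return act, mu


def _window_acceptance(scanner: ScannerModel) -> float:
    """Probability that an unscattered (511 keV) photon passes the window."""
    sig = scanner.energy_resolution_fwhm_fraction * 511.0 * _FWHM_TO_SIGMA
    lo, hi = scanner.energy_window_kev
    return 0.5 * (math.erf((hi - 511.0) / (sig * math.sqrt(2.0)))
                  - math.erf((lo - 511.0) / (sig * math.sqrt(2.0))))


def simulate(activity: VolumeImage, attenuation: VolumeImage | None, scanner: ScannerModel,
             config: SimulationConfig) -> SinogramSet:
    """One Monte Carlo realization of the acquisition.

    With ``noise='poisson'`` the tracked decay count is itself Poisson
    distributed, which makes every sinogram bin exactly Poisson; with
    ``noise='none'`` the decay count is fixed at its expectation (the
    analytic expectation is available from :func:`noise_free_projection`).
    """
    act, mu = _prepare_maps(activity, attenuation, scanner)
    rng = np.random.default_rng(config.seed)
    n_exp = n_simulated_decays(config)
    n_dec = int(rng.poisson(n_exp)) if config.noise == "poisson" else n_exp
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    shape = act.shape
    voxel = act.voxel_size_mm
    xlo = act.origin_mm[0] - voxel[0] / 2.0
    ylo = act.origin_mm[1] - voxel[1] / 2.0
    zlo = act.origin_mm[2] - voxel[2] / 2.0

    a = np.asarray(act.data, dtype=np.float64).ravel()
    cdf = np.cumsum(a)
    cdf /= cdf[-1]

    mu_mm = (np.asarray(mu.data, dtype=np.float64) / 10.0 if mu is not None
             else np.zeros(shape, dtype=np.float64))
    mu_max = float(mu_mm.max())

    cos_a, sin_a, svals = sinogram_geometry(scanner)
    dims = (scanner.n_planes, scanner.n_angles, scanner.n_radial)
    trues = np.zeros(dims, dtype=np.int64)
    scatter = np.zeros(dims, dtype=np.int64)

    sig511 = scanner.energy_resolution_fwhm_fraction * 511.0 * _FWHM_TO_SIGMA
    nc_sigma = (math.radians(config.noncollinearity_fwhm_deg) * _FWHM_TO_SIGMA
                if config.noncollinearity else 0.0)
    pr_sigma = (config.positron_range_fwhm_mm * _FWHM_TO_SIGMA
                if config.positron_range else 0.0)

    counters = _mc.mc_kernel(
        cdf, shape[0], shape[1], shape[2], voxel[0], voxel[1], voxel[2], xlo, ylo, zlo,
        np.ascontiguousarray(mu_mm), mu_max, _mc._kn_total(1.0),
        scanner.ring_radius_mm, scanner.axial_half_extent_mm,
        act.origin_mm[2], voxel[2], scanner.n_planes,
        sig511, scanner.energy_window_kev[0], scanner.energy_window_kev[1],
        n_dec, kernel_seed, nc_sigma, pr_sigma,
        scanner.n_angles, scanner.n_radial, scanner.radial_bin_size_mm, float(svals[0]),
        trues, scatter,
    )
    mk = lambda d, kind: Sinogram(d, kind=kind, scanner_name=scanner.name,
                                  radial_bin_size_mm=scanner.radial_bin_size_mm)
    return SinogramSet(
        trues=mk(trues, "trues"),
        scatter=mk(scatter, "scatter"),
        prompts=mk(trues + scatter, "prompts"),
        n_decays_simulated=n_dec,
        n_detected=int(counters[0]),
        n_absorbed=int(counters[1]),
        n_escaped=int(counters[2]),
        n_window_rejected=int(counters[3]),
    )


def noise_free_projection(activity: VolumeImage, attenuation: VolumeImage | None,
                          scanner: ScannerModel, config: SimulationConfig) -> Sinogram:
    """Expected trues sinogram of :func:`simulate` — no randomness.

    Per bin: ``N * dphi/pi * ds * FP(activity) / (sum(a) * vx * vy) * w^2 / ACF``
    where ``w`` is the single-photon energy-window acceptance at 511 keV.
    """
    act, mu = _prepare_maps(activity, attenuation, scanner)
    # unrounded expectation: the analytic sinogram is exactly linear in dose
    n_dec = (float(config.n_decays) if config.n_decays is not None
             else expected_decays(config) * config.sensitivity_scale)
    w = _window_acceptance(scanner)
    dphi = math.pi / scanner.n_angles
    ds = scanner.radial_bin_size_mm
    vx, vy, _ = act.voxel_size_mm
    total = float(np.sum(act.data))
    scale = n_dec * dphi * ds * w * w / (math.pi * total * vx * vy)
    fp = forward_project(act, scanner)
    data = scale * fp.data
    if mu is not None:
        acf = attenuation_sinogram(mu, scanner)
        data = data / acf.data
    return Sinogram(data, kind="expected", scanner_name=scanner.name,
                    radial_bin_size_mm=scanner.radial_bin_size_mm)
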