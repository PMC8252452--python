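"""Canned studies used by the examples, tests and reproduction script.

The self-consistency study mirrors the clinical phantom-generation setting
at desk scale: a synthetic head phantom is simulated and reconstructed to
produce a "measured" target PET image (scatter-corrected, as clinical
images are), and the refinement loop is then started from uniform-fill
initial maps using only the segmentation, the bone mask and the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .brainviset import BrainVISETConfig, BrainVISETHistory, run_brainviset
from .phantoms import PhantomSpec, generate_brain_phantom
from .projector import Sinogram, attenuation_sinogram
from .recon import ReconConfig, osem
from .scanners import ScannerModel, load_scanner, rescale_scanner
from .simulate import SimulationConfig, simulate
from .volume import TissueSegmentation, VolumeImage


def study_scanner(base: str = "discovery_st", shape=(64, 64, 31),
                  n_radial: int = 125, n_angles: int = 105) -> ScannerModel:
    """Reduced-grid variant of a built-in scanner preserving its FOV."""
    return rescale_scanner(load_scanner(base), shape, n_radial=n_radial,
                           n_angles=n_angles, name=f"{base}_study")


@dataclass
class SelfConsistencyResult:
    history: BrainVISETHistory
    truth_activity: VolumeImage
    segmentation: TissueSegmentation
    target: VolumeImage
    n_decays: int


def smoothed_scatter_estimate(scatter: Sinogram, sigma=(1, 2, 2)) -> Sinogram:
    """Smooth an MC scatter sinogram for use as an additive recon term."""
    return Sinogram(ndimage.gaussian_filter(np.asarray(scatter.data, dtype=np.float64), sigma),
                    kind="expected", scanner_name=scatter.scanner_name,
                    radial_bin_size_mm=scatter.radial_bin_size_mm)


def self_consistency_study(seed: int = 1, n_decays: int = 5_000_000,
                           scanner: ScannerModel | None = None,
                           variability_amplitude: float = 0.1,
                           bv_config: BrainVISETConfig | None = None) -> SelfConsistencyResult:
    """Generate a target by MC simulation + reconstruction, then refine.

    The target acquisition uses Poisson noise at ``n_decays`` tracked decays
    and is reconstructed with attenuation correction and the simulation's
    own (smoothed) scatter sinogram as the scatter estimate.  The
    refinement loop runs with analytic noise-free simulation at the same
    decay count.
    """
    scanner = scanner or study_scanner()
    spec = PhantomSpec(shape=scanner.recon_shape,
                       voxel_size_mm=tuple(scanner.recon_voxel_mm),
                       variability_amplitude=variability_amplitude, seed=seed)
    activity, mu, seg = generate_brain_phantom(spec)

    sim = SimulationConfig(n_decays=n_decays, noise="poisson", seed=seed + 1)
    sset = simulate(activity, mu, scanner, sim)
    acf = attenuation_sinogram(mu, scanner)
    target = osem(sset.prompts, scanner,
                  ReconConfig(attenuation=acf,
                              scatter_estimate=smoothed_scatter_estimate(sset.scatter)))

    bone = seg.labels.like(np.asarray(seg.mask_for("bone")).astype(np.uint8), semantics="mask")
    hist = run_brainviset(
        target, seg, bone, scanner,
        sim_config=SimulationConfig(n_decays=n_decays, noise="none"),
        bv_config=bv_config or BrainVISETConfig(seed=seed + 2),
    )
    return SelfConsistencyResult(history=hist, truth_activity=activity, segmentation=seg,
                                 target=target, n_decays=n_decays)
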