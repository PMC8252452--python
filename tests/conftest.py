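"""Shared fixtures: reduced-dimension scanner variants and small phantoms.

All test data are generated programmatically; the reduced scanners preserve
the Discovery-ST field of view so that physical quantities (chord lengths,
attenuation factors) keep their clinical magnitudes.
"""

import numpy as np
import pytest

import neuropetsim as nps


@pytest.fixture(scope="session")
def tiny_scanner():
    """32x32x5 grid, 33 radial bins, 24 angles — for fast algebraic checks."""
    return nps.rescale_scanner(nps.load_scanner("discovery_st"), (32, 32, 5),
                               n_radial=33, n_angles=24, name="tiny")


@pytest.fixture(scope="session")
def small_scanner():
    """64x64x9 grid, 99 radial bins, 42 angles — for MC statistics checks."""
    return nps.rescale_scanner(nps.load_scanner("discovery_st"), (64, 64, 9),
                               n_radial=99, n_angles=42, name="small")


@pytest.fixture(scope="session")
def head_scanner():
    """64x64x31 grid — the refinement-loop study geometry."""
    return nps.rescale_scanner(nps.load_scanner("discovery_st"), (64, 64, 31),
                               n_radial=125, n_angles=105, name="discovery_st_64")


def make_cylinder(scanner, radius_mm=80.0, activity=1.0, mu_cm=0.096, supersample=1):
    """Uniform water cylinder phantom on a scanner's recon grid.

    ``supersample > 1`` antialiases the rim with partial-volume fractions
    (n x n subvoxel coverage), which keeps line integrals close to the
    continuous cylinder's chords.
    """
    shape = scanner.recon_shape
    vx, vy, _ = scanner.recon_voxel_mm
    act = nps.VolumeImage(np.zeros(shape), scanner.recon_voxel_mm, semantics="activity")
    x = act.axis_coords_mm(0)[:, None]
    y = act.axis_coords_mm(1)[None, :]
    if supersample <= 1:
        cov = ((x ** 2 + y ** 2) <= radius_mm ** 2).astype(float)
    else:
        n = supersample
        off = (np.arange(n) + 0.5) / n - 0.5
        cov = np.zeros(shape[:2])
        for ox in off:
            for oy in off:
                cov += ((x + ox * vx) ** 2 + (y + oy * vy) ** 2) <= radius_mm ** 2
        cov /= n * n
    act.data[:] = activity * cov[:, :, None]
    mu = nps.VolumeImage(mu_cm * cov[:, :, None] * np.ones((1, 1, shape[2])),
                         scanner.recon_voxel_mm, semantics="attenuation")
    return act, mu


@pytest.fixture(scope="session")
def water_cylinder(small_scanner):
    return make_cylinder(small_scanner, supersample=4)


@pytest.fixture(scope="session")
def head_phantom(head_scanner):
    spec = nps.PhantomSpec(shape=head_scanner.recon_shape,
                           voxel_size_mm=tuple(head_scanner.recon_voxel_mm),
                           variability_amplitude=0.1, seed=1)
    return nps.generate_brain_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
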