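"""Refinement loop: correlation metric, fixed points, recovery, determinism."""

import numpy as np
import pytest

import neuropetsim as nps
from neuropetsim.errors import UndefinedCorrelationError


def _vol(data, voxel=(2.0, 2.0, 2.0)):
    return nps.VolumeImage(np.asarray(data, dtype=float), voxel)


def test_pearson_affine_invariance_and_sign(rng):
    a = _vol(rng.random((10, 10, 5)))
    mask = np.ones(a.shape, dtype=bool)
    b = a.like(3.0 * np.asarray(a.data) + 7.0)
    assert nps.pearson_r(a, b, mask) == pytest.approx(1.0, abs=1e-12)
    c = a.like(-np.asarray(a.data))
    assert nps.pearson_r(a, c, mask) == pytest.approx(-1.0, abs=1e-12)


def test_pearson_matches_two_pass_formula(rng):
    a = _vol(rng.random((10, 10, 10)))
    b = _vol(rng.random((10, 10, 10)))
    mask = rng.random((10, 10, 10)) > 0.2
    x = np.asarray(a.data)[mask]
    y = np.asarray(b.data)[mask]
    # textbook two-pass formula, computed independently
    xm, ym = x.mean(), y.mean()
    oracle = np.sum((x - xm) * (y - ym)) / np.sqrt(np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2))
    assert nps.pearson_r(a, b, mask) == pytest.approx(oracle, abs=1e-12)


def test_pearson_zero_variance_is_an_error(rng):
    a = _vol(np.ones((4, 4, 4)))
    b = _vol(rng.random((4, 4, 4)))
    with pytest.raises(UndefinedCorrelationError):
        nps.pearson_r(a, b, np.ones((4, 4, 4), dtype=bool))


@pytest.fixture(scope="module")
def refinement_setup(head_scanner, head_phantom):
    act, mu, seg = head_phantom
    acf = nps.attenuation_sinogram(mu, head_scanner)
    bone = seg.labels.like(seg.mask_for("bone").astype(np.uint8), semantics="mask")
    return act, mu, seg, bone, acf


def test_fixed_point_target_converges_immediately(head_scanner, refinement_setup):
    """A target equal to the reconstruction of the initial maps gives r ~ 1."""
    act, mu, seg, bone, acf = refinement_setup
    a0, mu0 = nps.build_initial_maps(seg, bone)
    sim = nps.SimulationConfig(n_decays=5_000_000, noise="none")
    target = nps.osem(nps.noise_free_projection(a0, mu0, head_scanner, sim), head_scanner,
                      nps.ReconConfig(attenuation=nps.attenuation_sinogram(mu0, head_scanner)))
    hist = nps.run_brainviset(target, seg, bone, head_scanner, sim_config=sim)
    assert hist.converged and hist.n_iterations == 1
    assert hist.r_values[0] > 0.999


def test_refinement_recovers_tissue_contrast_and_lesion_ratio(head_scanner):
    """High-count self-consistent target: contrast and a 30 % hypometabolic
    GM lesion are recovered within 10 %."""
    les = dict(center_mm=(70.0, 0.0, 0.0), radius_mm=14.0, activity_factor=0.7)
    spec = nps.PhantomSpec(shape=head_scanner.recon_shape,
                           voxel_size_mm=tuple(head_scanner.recon_voxel_mm),
                           variability_amplitude=0.1, lesions=[les], seed=1)
    act, mu, seg = nps.generate_brain_phantom(spec)
    sim = nps.SimulationConfig(n_decays=5_000_000, noise="none")
    acf = nps.attenuation_sinogram(mu, head_scanner)
    target = nps.osem(nps.noise_free_projection(act, mu, head_scanner, sim), head_scanner,
                      nps.ReconConfig(attenuation=acf))
    bone = seg.labels.like(seg.mask_for("bone").astype(np.uint8), semantics="mask")
    hist = nps.run_brainviset(
        target, seg, bone, head_scanner, sim_config=sim,
        bv_config=nps.BrainVISETConfig(r_threshold=0.9995, max_iterations=12, seed=3))
    assert hist.converged
    fa = np.asarray(hist.final_activity.data)
    gm = seg.mask_for("gray_matter")
    wm = seg.mask_for("white_matter")
    truth = np.asarray(act.data)
    assert fa[gm].mean() / fa[wm].mean() == pytest.approx(
        truth[gm].mean() / truth[wm].mean(), rel=0.10)
    x = act.axis_coords_mm(0)[:, None, None]
    y = act.axis_coords_mm(1)[None, :, None]
    z = act.axis_coords_mm(2)[None, None, :]
    inles = (((x - 70.0) ** 2 + y ** 2 + z ** 2) <= 14.0 ** 2) & gm
    contra = (((x + 70.0) ** 2 + y ** 2 + z ** 2) <= 14.0 ** 2) & gm
    assert fa[inles].mean() / fa[contra].mean() == pytest.approx(
        truth[inles].mean() / truth[contra].mean(), rel=0.10)
    # activity stays >= 0 and zero outside the head at every tracked stage
    head = np.asarray(seg.head_mask().data) > 0
    assert np.all(fa >= 0) and np.all(fa[~head] == 0)


def test_refinement_seed_deterministic(head_scanner, refinement_setup):
    act, mu, seg, bone, acf = refinement_setup
    sim = nps.SimulationConfig(n_decays=1_000_000, noise="poisson", seed=0)
    target = nps.osem(nps.simulate(act, mu, head_scanner, sim).prompts, head_scanner,
                      nps.ReconConfig(attenuation=acf))
    bv = nps.BrainVISETConfig(max_iterations=2, r_threshold=0.999, seed=5)
    h1 = nps.run_brainviset(target, seg, bone, head_scanner,
                            sim_config=nps.SimulationConfig(n_decays=500_000, seed=1),
                            bv_config=bv)
    h2 = nps.run_brainviset(target, seg, bone, head_scanner,
                            sim_config=nps.SimulationConfig(n_decays=500_000, seed=1),
                            bv_config=bv)
    assert h1.r_values == h2.r_values
    np.testing.assert_array_equal(h1.final_activity.data, h2.final_activity.data)


def test_best_so_far_r_is_reported(head_scanner, refinement_setup):
    act, mu, seg, bone, acf = refinement_setup
    sim = nps.SimulationConfig(n_decays=5_000_000, noise="none")
    target = nps.osem(nps.noise_free_projection(act, mu, head_scanner, sim), head_scanner,
                      nps.ReconConfig(attenuation=acf))
    hist = nps.run_brainviset(target, seg, bone, head_scanner, sim_config=sim,
                              bv_config=nps.BrainVISETConfig(r_threshold=0.99999,
                                                             max_iterations=4))
    assert hist.best_r == max(hist.r_values)
    running_best = np.maximum.accumulate(hist.r_values)
    assert np.all(np.diff(running_best) >= 0)
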