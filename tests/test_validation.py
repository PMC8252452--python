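"""Smoothing, voxel-difference statistics, and cluster-thresholded t maps."""

import numpy as np
import pytest
from scipy import stats

import neuropetsim as nps
from neuropetsim.errors import InvalidSpecError


def _vol(data, voxel=(2.0, 2.0, 2.0)):
    return nps.VolumeImage(np.asarray(data, dtype=float), voxel)


# -- Gaussian smoothing -----------------------------------------------------

def test_smoothing_kernel_width_from_fwhm():
    """8 mm FWHM -> sigma = 3.397 mm, measured on a smoothed delta."""
    vol = _vol(np.zeros((41, 41, 41)), voxel=(1.0, 1.0, 1.0))
    vol.data[20, 20, 20] = 1.0
    sm = nps.gaussian_smooth(vol, 8.0)
    x = sm.axis_coords_mm(0) - sm.axis_coords_mm(0)[20]
    marg = np.asarray(sm.data).sum(axis=(1, 2))
    sigma = np.sqrt(np.sum(marg * x ** 2) / np.sum(marg))
    assert sigma == pytest.approx(8.0 / 2.3548, rel=0.01)
    assert np.asarray(sm.data).sum() == pytest.approx(1.0, abs=1e-6)


def test_smoothing_identity_cases(rng):
    vol = _vol(rng.random((12, 12, 12)))
    np.testing.assert_array_equal(nps.gaussian_smooth(vol, 0.0).data, vol.data)
    const = _vol(3.14 * np.ones((12, 12, 12)))
    np.testing.assert_allclose(nps.gaussian_smooth(const, 8.0).data, 3.14, rtol=1e-9)


# -- Bland-Altman voxel differences ----------------------------------------

def test_identical_images_give_zero_differences(rng):
    a = _vol(rng.random((10, 10, 10)) + 0.5)
    res = nps.bland_altman(a, a.like(np.asarray(a.data).copy()))
    assert np.all(res.evoxel_map.data == 0)
    assert res.fraction_below[5.0] == 1.0
    assert res.fraction_below[10.0] == 1.0


def test_evoxel_direct_arithmetic():
    a = _vol(1.05 * np.ones((2, 2, 2)))
    b = _vol(0.95 * np.ones((2, 2, 2)))
    res = nps.bland_altman(a, b)
    np.testing.assert_allclose(res.evoxel_map.data, 0.1, rtol=1e-12)


def test_evoxel_antisymmetry_and_bounds(rng):
    a = _vol(rng.random((12, 12, 6)))
    b = _vol(rng.random((12, 12, 6)))
    mask = (np.asarray(a.data) + np.asarray(b.data)) > 0.2
    r1 = nps.bland_altman(a, b, mask)
    r2 = nps.bland_altman(b, a, mask)
    np.testing.assert_allclose(np.asarray(r1.evoxel_map.data),
                               -np.asarray(r2.evoxel_map.data), atol=1e-12)
    vals = np.asarray(r1.evoxel_map.data)[np.asarray(r1.mask.data) > 0]
    assert np.all(np.abs(vals) <= 2.0)
    # fractions are monotone in the threshold
    res = nps.bland_altman(a, b, mask, thresholds=(1, 5, 10, 50))
    fr = [res.fraction_below[t] for t in (1.0, 5.0, 10.0, 50.0)]
    assert all(x <= y for x, y in zip(fr, fr[1:]))


def test_empty_mask_is_an_error():
    a = _vol(np.zeros((4, 4, 4)))
    with pytest.raises(InvalidSpecError):
        nps.bland_altman(a, a.like(np.zeros((4, 4, 4))))


# -- voxel-wise t tests ------------------------------------------------------

def test_identical_groups_give_null_map(rng):
    group = [_vol(rng.random((8, 8, 4))) for _ in range(5)]
    res = nps.voxelwise_ttest(group, [g.like(np.asarray(g.data).copy()) for g in group],
                              nps.StatTestConfig(design="paired", cluster_k=1))
    assert np.all(res.t_map.data == 0)
    assert res.clusters == []


def test_single_voxel_paired_t_value():
    """Hand check: diffs (1.2,0.8,1.0,1.1,0.9) -> t = mean/(sd/sqrt(n)) = 14.142."""
    diffs = [1.2, 0.8, 1.0, 1.1, 0.9]
    a = [_vol(np.full((1, 1, 1), d)) for d in diffs]
    b = [_vol(np.zeros((1, 1, 1))) for _ in diffs]
    res = nps.voxelwise_ttest(a, b, nps.StatTestConfig(design="paired", cluster_k=1))
    t_oracle = stats.ttest_1samp(diffs, 0.0).statistic  # independent implementation
    assert t_oracle == pytest.approx(1.0 / (np.std(diffs, ddof=1) / np.sqrt(5)), rel=1e-12)
    assert float(res.t_map.data[0, 0, 0]) == pytest.approx(t_oracle, rel=1e-12)


def test_contrast_flip_negates_t(rng):
    a = [_vol(rng.random((6, 6, 3))) for _ in range(4)]
    b = [_vol(rng.random((6, 6, 3))) for _ in range(4)]
    t1 = nps.voxelwise_ttest(a, b, nps.StatTestConfig(contrast="A_gt_B", cluster_k=1)).t_map
    t2 = nps.voxelwise_ttest(a, b, nps.StatTestConfig(contrast="A_lt_B", cluster_k=1)).t_map
    np.testing.assert_allclose(np.asarray(t1.data), -np.asarray(t2.data), atol=1e-12)


def test_injected_regional_effect_is_detected(rng):
    """A 15 % regional reduction in one group is found as a cluster covering
    >= 80 % of the injected region (smoothed images, n = 10 per group)."""
    shape = (16, 16, 16)
    region = np.zeros(shape, dtype=bool)
    region[5:10, 5:10, 5:10] = True
    groupA, groupB = [], []
    for i in range(10):
        base = 1.0 + 0.05 * rng.standard_normal(shape)
        groupA.append(nps.gaussian_smooth(_vol(base), 4.0))
        base = 1.0 + 0.05 * rng.standard_normal(shape)
        base[region] *= 0.85
        groupB.append(nps.gaussian_smooth(_vol(base), 4.0))
    res = nps.voxelwise_ttest(groupA, groupB,
                              nps.StatTestConfig(design="two_sample", contrast="A_gt_B",
                                                 cluster_k=20))
    assert res.clusters, "no cluster detected for the injected effect"
    t_thr = res.t_threshold
    supra = np.asarray(res.t_map.data) > t_thr
    from scipy import ndimage

    labeled, _ = ndimage.label(supra, structure=nps.validation.CONNECTIVITY_26)
    best = max(res.clusters, key=lambda c: c.size)
    in_cluster = labeled == labeled[best.peak_index]
    assert (in_cluster & region).sum() / region.sum() >= 0.8


def test_permutation_fwe_assigns_small_p_to_strong_effect(rng):
    shape = (10, 10, 10)
    region = np.zeros(shape, dtype=bool)
    region[3:7, 3:7, 3:7] = True
    groupA, groupB = [], []
    for _ in range(8):
        groupA.append(_vol(1.0 + 0.05 * rng.standard_normal(shape)))
        b = 1.0 + 0.05 * rng.standard_normal(shape)
        b[region] *= 0.7
        groupB.append(_vol(b))
    cfg = nps.StatTestConfig(design="paired", contrast="A_gt_B", cluster_k=5,
                             correction="permutation_fwe", n_permutations=199, seed=0)
    res = nps.voxelwise_ttest(groupA, groupB, cfg)
    assert res.clusters
    assert min(c.corrected_p for c in res.clusters) <= 0.05
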