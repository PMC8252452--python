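"""Ray tracing, forward/back projection, and attenuation factors."""

import numpy as np
import pytest

import neuropetsim as nps
from neuropetsim.errors import GeometryError, InvalidSpecError
from tests.conftest import make_cylinder


# -- siddon_path ------------------------------------------------------------

def test_axis_aligned_ray_through_ten_voxels():
    grid = nps.VolumeImage(np.ones((10, 3, 3)), (2.0, 2.0, 2.0))
    path = nps.siddon_path((-50.0, 0.0, 0.0), (50.0, 0.0, 0.0), grid)
    assert len(path.voxels) == 10
    assert np.allclose(path.lengths_mm, 2.0)


def test_ray_outside_grid_gives_empty_path():
    grid = nps.VolumeImage(np.ones((4, 4, 4)), (1.0, 1.0, 1.0))
    path = nps.siddon_path((100.0, 100.0, 0.0), (100.0, 100.0, 50.0), grid)
    assert path.voxels == [] and path.lengths_mm == []


def test_identical_endpoints_rejected():
    grid = nps.VolumeImage(np.ones((4, 4, 4)), (1.0, 1.0, 1.0))
    with pytest.raises(InvalidSpecError):
        nps.siddon_path((1.0, 1.0, 1.0), (1.0, 1.0, 1.0), grid)


def test_path_lengths_sum_to_chord_length(rng):
    grid = nps.VolumeImage(rng.random((9, 11, 7)), (1.5, 2.0, 3.0))
    for _ in range(50):
        p1 = rng.uniform(-40, 40, 3)
        p2 = rng.uniform(-40, 40, 3)
        if np.allclose(p1, p2):
            continue
        path = nps.siddon_path(p1, p2, grid)
        if not path.voxels:
            continue
        # chord of the segment clipped to the grid bounding box
        u = (p2 - p1) / np.linalg.norm(p2 - p1)
        tmin, tmax = 0.0, np.linalg.norm(p2 - p1)
        for a in range(3):
            lo = grid.origin_mm[a] - grid.voxel_size_mm[a] / 2
            hi = lo + grid.shape[a] * grid.voxel_size_mm[a]
            if abs(u[a]) > 1e-12:
                t1, t2 = sorted([(lo - p1[a]) / u[a], (hi - p1[a]) / u[a]])
                tmin, tmax = max(tmin, t1), min(tmax, t2)
        assert path.total_length() == pytest.approx(tmax - tmin, rel=1e-6)


def test_siddon_integral_matches_fine_quadrature(rng):
    """Sum of mu*length along 100 random rays vs dense sampling at 0.01 mm."""
    grid = nps.VolumeImage(rng.random((16, 16, 8)), (4.0, 4.0, 6.0))
    data = np.asarray(grid.data)
    n_checked = 0
    total_exact = 0.0
    total_quad = 0.0
    for _ in range(100):
        p1 = rng.uniform(-60, 60, 3)
        p2 = rng.uniform(-60, 60, 3)
        if np.linalg.norm(p2 - p1) < 1.0:
            continue
        path = nps.siddon_path(p1, p2, grid)
        exact = path.integrate(grid)
        length = np.linalg.norm(p2 - p1)
        n = int(length / 0.01) + 1
        ts = (np.arange(n) + 0.5) / n
        pts = p1[None, :] + ts[:, None] * (p2 - p1)[None, :]
        idx = [np.floor((pts[:, a] - grid.origin_mm[a]) / grid.voxel_size_mm[a] + 0.5).astype(int)
               for a in range(3)]
        inside = np.all([(i >= 0) & (i < s) for i, s in zip(idx, grid.shape)], axis=0)
        approx = float(data[idx[0][inside], idx[1][inside], idx[2][inside]].sum() * length / n)
        if approx > 1e-6:
            assert exact == pytest.approx(approx, rel=1e-2)  # per-ray sanity
            total_exact += exact
            total_quad += approx
            n_checked += 1
    assert n_checked >= 50
    # boundary-quantisation errors average out over the ray ensemble
    assert total_exact == pytest.approx(total_quad, rel=1e-3)


# -- forward / back projection ---------------------------------------------

def test_central_lor_through_uniform_disk_equals_chord(tiny_scanner):
    sc = nps.rescale_scanner(nps.load_scanner("discovery_st"), (96, 96, 3),
                             n_radial=95, n_angles=16, name="diskfp")
    R = 60.0
    act, _ = make_cylinder(sc, radius_mm=R, activity=2.0, supersample=4)
    fp = nps.forward_project(act, sc)
    central = fp.data[1, :, (sc.n_radial - 1) // 2]
    assert np.allclose(central, 2.0 * 2 * R * np.ones_like(central), rtol=0.01)


def test_forward_projection_linearity_and_zero(tiny_scanner, rng):
    a = nps.VolumeImage(rng.random(tiny_scanner.recon_shape), tiny_scanner.recon_voxel_mm)
    b = nps.VolumeImage(rng.random(tiny_scanner.recon_shape), tiny_scanner.recon_voxel_mm)
    ab = nps.VolumeImage(np.asarray(a.data) + np.asarray(b.data), tiny_scanner.recon_voxel_mm)
    fa = nps.forward_project(a, tiny_scanner).data
    fb = nps.forward_project(b, tiny_scanner).data
    fab = nps.forward_project(ab, tiny_scanner).data
    np.testing.assert_allclose(fab, fa + fb, atol=1e-10 * max(1.0, fab.max()))
    zero = nps.VolumeImage(np.zeros(tiny_scanner.recon_shape), tiny_scanner.recon_voxel_mm)
    assert nps.forward_project(zero, tiny_scanner).data.sum() == 0.0


@pytest.mark.parametrize("scanner_fixture", ["tiny_scanner", "small_scanner", "head_scanner"])
def test_adjoint_inner_product_identity(scanner_fixture, rng, request):
    sc = request.getfixturevalue(scanner_fixture)
    x = nps.VolumeImage(rng.random(sc.recon_shape), sc.recon_voxel_mm)
    y = rng.random((sc.n_planes, sc.n_angles, sc.n_radial))
    fp = nps.forward_project(x, sc).data
    bp = nps.back_project(nps.Sinogram(y, kind="expected"), sc).data
    lhs = float(np.sum(fp * y))
    rhs = float(np.sum(np.asarray(x.data) * bp))
    assert lhs == pytest.approx(rhs, rel=1e-6)


def test_backprojection_zero_and_single_bin(tiny_scanner):
    dims = (tiny_scanner.n_planes, tiny_scanner.n_angles, tiny_scanner.n_radial)
    zero = nps.back_project(nps.Sinogram(np.zeros(dims), kind="expected"), tiny_scanner)
    assert np.all(np.asarray(zero.data) == 0)
    one = np.zeros(dims)
    one[2, 5, 16] = 1.0
    bp = nps.back_project(nps.Sinogram(one, kind="expected"), tiny_scanner)
    data = np.asarray(bp.data)
    assert data[:, :, 2].sum() == data.sum() > 0  # only the LOR's plane is touched
    # nonzero voxels all lie within one radial bin width of the LOR line
    cos_a, sin_a, svals = nps.projector.sinogram_geometry(tiny_scanner)
    xs = bp.axis_coords_mm(0)[:, None] * np.ones((1, data.shape[1]))
    ys = np.ones((data.shape[0], 1)) * bp.axis_coords_mm(1)[None, :]
    dist = np.abs(-xs * sin_a[5] + ys * cos_a[5] - svals[16])
    nz = data[:, :, 2] > 0
    assert np.all(dist[nz] <= tiny_scanner.radial_bin_size_mm)


def test_backprojection_dim_mismatch_rejected(tiny_scanner):
    wrong = nps.Sinogram(np.zeros((2, 3, 4)), kind="expected")
    with pytest.raises(GeometryError):
        nps.back_project(wrong, tiny_scanner)


# -- attenuation sinogram ---------------------------------------------------

def test_acf_is_one_without_attenuation(tiny_scanner):
    mu = nps.VolumeImage(np.zeros(tiny_scanner.recon_shape), tiny_scanner.recon_voxel_mm,
                         semantics="attenuation")
    acf = nps.attenuation_sinogram(mu, tiny_scanner)
    np.testing.assert_allclose(acf.data, 1.0, atol=1e-12)


def test_acf_water_cylinder_closed_form():
    # 20 cm water cylinder, central LOR: exp(0.096 * 20) within 1 %
    sc = nps.rescale_scanner(nps.load_scanner("discovery_st"), (128, 128, 3),
                             n_radial=127, n_angles=16, name="acfcheck")
    _, mu = make_cylinder(sc, radius_mm=100.0, supersample=4)
    acf = nps.attenuation_sinogram(mu, sc)
    central = acf.data[1, :, (sc.n_radial - 1) // 2]
    assert np.allclose(central, np.exp(1.92), rtol=0.01)


def test_acf_monotone_under_added_bone(small_scanner, water_cylinder):
    act, mu = water_cylinder
    acf1 = nps.attenuation_sinogram(mu, small_scanner).data
    harder = np.asarray(mu.data).copy()
    harder[28:36, 28:36, :] = 0.151
    acf2 = nps.attenuation_sinogram(mu.like(harder), small_scanner).data
    assert np.all(acf2 >= acf1 - 1e-12)


def test_negative_attenuation_rejected(tiny_scanner):
    bad = nps.VolumeImage(np.zeros(tiny_scanner.recon_shape), tiny_scanner.recon_voxel_mm,
                          semantics="activity")
    bad.data[0, 0, 0] = -1
    with pytest.raises(InvalidSpecError):
        nps.attenuation_sinogram(bad, tiny_scanner)
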