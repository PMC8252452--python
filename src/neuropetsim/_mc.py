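"""Numba photon-transport kernel.

Physics model (documented in docs/methods.md):

* Decays are sampled proportionally to the activity map; annihilation
  photon pairs are emitted back-to-back with in-plane azimuth uniform in
  [0, pi) (direct-plane acquisition model) and optional in-plane
  non-collinearity jitter on the second photon.
* Free paths are sampled by Woodcock (delta) tracking against the grid
  majorant.  The attenuation map stores the 511 keV total linear
  attenuation; its energy dependence is modeled by scaling with the total
  Klein-Nishina cross section ratio plus an E^-3 photoelectric term with a
  water-like branching fraction at 511 keV.
* Compton scattering angles are sampled from Klein-Nishina by Kahn's
  composition-rejection method; scattered photons acquire a 3D direction.
* Photons reaching the detector ring receive a Gaussian energy blur
  (variance scaling linearly with energy) and must pass the energy window.
* Coincidences are binned on the (plane, angle, radial) sinogram from the
  two detection positions; pairs with any Compton interaction are scatter,
  the rest trues.  Randoms are not modeled.

Every decay is classified into exactly one of: detected, absorbed,
escaped (axially or outside the sinogram support), or window-rejected.
"""

import math

import numpy as np
from numba import njit

# water-like photoelectric / total branching at 511 keV
_PE_FRACTION_511 = 2.0e-4
# photons below this energy (keV) are treated as locally absorbed
_E_CUTOFF_KEV = 30.0

DETECTED, ABSORBED, ESCAPED, REJECTED = 0, 1, 2, 3


@njit(cache=True, fastmath=True)
def _kn_total(alpha):
    """Total Klein-Nishina cross section (units of 2*pi*re^2)."""
    a = alpha
    t1 = (1.0 + a) / (a * a) * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - math.log(1.0 + 2.0 * a) / a)
    t2 = math.log(1.0 + 2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / ((1.0 + 2.0 * a) ** 2)
    return t1 + t2 - t3


_KN_511 = None  # filled lazily outside jit


@njit(cache=True, fastmath=True)
def _sample_kahn(alpha):
    """Sample eta = E/E' from Klein-Nishina; returns (cos theta, eta)."""
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * alpha) / (9.0 + 2.0 * alpha):
            eta = 1.0 + 2.0 * alpha * r2
            if r3 <= 4.0 * (1.0 / eta - 1.0 / (eta * eta)):
                cost = 1.0 - (eta - 1.0) / alpha
                return cost, eta
        else:
            eta = (1.0 + 2.0 * alpha) / (1.0 + 2.0 * alpha * r2)
            cost = 1.0 - (eta - 1.0) / alpha
            if r3 <= 0.5 * (cost * cost + 1.0 / eta):
                return cost, eta


@njit(cache=True, fastmath=True)
def _rotate(dx, dy, dz, cost, psi):
    """Rotate direction d by polar angle acos(cost), azimuth psi."""
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    # orthonormal frame (a, b, d)
    if abs(dz) < 0.999999:
        nrm = math.sqrt(dx * dx + dy * dy)
        ax = -dy / nrm
        ay = dx / nrm
        az = 0.0
    else:
        ax, ay, az = 1.0, 0.0, 0.0
    # b = d x a
    bx = dy * az - dz * ay
    by = dz * ax - dx * az
    bz = dx * ay - dy * ax
    cp = math.cos(psi)
    sp = math.sin(psi)
    ex = cost * dx + sint * (cp * ax + sp * bx)
    ey = cost * dy + sint * (cp * ay + sp * by)
    ez = cost * dz + sint * (cp * az + sp * bz)
    nrm = math.sqrt(ex * ex + ey * ey + ez * ez)
    return ex / nrm, ey / nrm, ez / nrm


@njit(cache=True, fastmath=True)
def _track(x, y, z, dx, dy, dz, mu511, mu_max, kn511,
           nx, ny, nz, vx, vy, vz, xlo, ylo, zlo,
           ring_radius, axial_half, sig511, elow, ehigh):
    """Track one photon; returns (status, xd, yd, zd, scattered)."""
    xhi = xlo + nx * vx
    yhi = ylo + ny * vy
    zhi = zlo + nz * vz
    E = 511.0
    scattered = 0
    if mu_max > 1e-12:
        while True:
            alpha = E / 511.0
            knr = _kn_total(alpha) / kn511
            pe = _PE_FRACTION_511 * (511.0 / E) ** 3
            f = knr + pe
            step = -math.log(np.random.random()) / (mu_max * f)
            x += step * dx
            y += step * dy
            z += step * dz
            if x <= xlo or x >= xhi or y <= ylo or y >= yhi or z <= zlo or z >= zhi:
                break
            i = int((x - xlo) / vx)
            j = int((y - ylo) / vy)
            k = int((z - zlo) / vz)
            mu_here = mu511[i, j, k]
            if np.random.random() * mu_max < mu_here:
                # real interaction
                if np.random.random() * f < pe:
                    return ABSORBED, 0.0, 0.0, 0.0, scattered
                cost, eta = _sample_kahn(alpha)
                E = E / eta
                scattered = 1
                if E < _E_CUTOFF_KEV:
                    return ABSORBED, 0.0, 0.0, 0.0, scattered
                psi = 2.0 * math.pi * np.random.random()
                dx, dy, dz = _rotate(dx, dy, dz, cost, psi)
    # free flight to the detector ring
    a2 = dx * dx + dy * dy
    if a2 < 1e-12:
        return ESCAPED, 0.0, 0.0, 0.0, scattered
    b = x * dx + y * dy
    c = x * x + y * y - ring_radius * ring_radius
    disc = b * b - a2 * c
    if disc <= 0.0:
        return ESCAPED, 0.0, 0.0, 0.0, scattered
    # larger root = outward ring crossing of the flight line; a Woodcock step
    # may have overshot past the ring, in which case t < 0 still locates the
    # same geometric crossing point
    t = (-b + math.sqrt(disc)) / a2
    zd = z + t * dz
    if abs(zd) > axial_half:
        return ESCAPED, 0.0, 0.0, 0.0, scattered
    xd = x + t * dx
    yd = y + t * dy
    eobs = E + sig511 * math.sqrt(E / 511.0) * np.random.standard_normal()
    if eobs < elow or eobs > ehigh:
        return REJECTED, xd, yd, zd, scattered
    return DETECTED, xd, yd, zd, scattered


@njit(cache=True)
def mc_kernel(cdf, nx, ny, nz, vx, vy, vz, xlo, ylo, zlo,
              mu511, mu_max, kn511,
              ring_radius, axial_half, zp0, vzp, n_planes,
              sig511, elow, ehigh,
              n_decays, seed, nc_sigma, pr_sigma,
              n_angles, n_radial, ds, smin,
              trues, scatter):
    """Simulate ``n_decays`` decays; fills trues/scatter, returns counters.

    counters = [detected, absorbed, escaped, window_rejected]; sums to
    n_decays exactly.
    """
    np.random.seed(seed)
    counters = np.zeros(4, dtype=np.int64)
    nyz = ny * nz
    for _ in range(n_decays):
        u = np.random.random()
        v = np.searchsorted(cdf, u)
        if v >= cdf.shape[0]:
            v = cdf.shape[0] - 1
        i = v // nyz
        rem = v - i * nyz
        j = rem // nz
        k = rem - j * nz
        x = xlo + (i + np.random.random()) * vx
        y = ylo + (j + np.random.random()) * vy
        z = zlo + (k + np.random.random()) * vz
        if pr_sigma > 0.0:
            x += pr_sigma * np.random.standard_normal()
            y += pr_sigma * np.random.standard_normal()
            z += pr_sigma * np.random.standard_normal()
        phi = math.pi * np.random.random()
        d1x = math.cos(phi)
        d1y = math.sin(phi)
        if nc_sigma > 0.0:
            delta = nc_sigma * np.random.standard_normal()
        else:
            delta = 0.0
        d2x = -math.cos(phi + delta)
        d2y = -math.sin(phi + delta)

        s1, x1, y1, z1, sc1 = _track(x, y, z, d1x, d1y, 0.0, mu511, mu_max, kn511,
                                     nx, ny, nz, vx, vy, vz, xlo, ylo, zlo,
                                     ring_radius, axial_half, sig511, elow, ehigh)
        s2, x2, y2, z2, sc2 = _track(x, y, z, d2x, d2y, 0.0, mu511, mu_max, kn511,
                                     nx, ny, nz, vx, vy, vz, xlo, ylo, zlo,
                                     ring_radius, axial_half, sig511, elow, ehigh)
        if s1 == ABSORBED or s2 == ABSORBED:
            counters[1] += 1
            continue
        if s1 == ESCAPED or s2 == ESCAPED:
            counters[2] += 1
            continue
        if s1 == REJECTED or s2 == REJECTED:
            counters[3] += 1
            continue
        ddx = x2 - x1
        ddy = y2 - y1
        if ddx * ddx + ddy * ddy < 1e-12:
            counters[2] += 1
            continue
        alpha_l = math.atan2(ddy, ddx)
        if alpha_l < 0.0:
            alpha_l += math.pi
        if alpha_l >= math.pi:
            alpha_l -= math.pi
        ia = int(alpha_l / math.pi * n_angles)
        if ia >= n_angles:
            ia = n_angles - 1
        sv = -x1 * math.sin(alpha_l) + y1 * math.cos(alpha_l)
        ir = int(math.floor((sv - smin) / ds + 0.5))
        zm = 0.5 * (z1 + z2)
        ip = int(math.floor((zm - zp0) / vzp + 0.5))
        if 0 <= ir < n_radial and 0 <= ip < n_planes:
            if sc1 or sc2:
                scatter[ip, ia, ir] += 1
            else:
                trues[ip, ia, ir] += 1
            counters[0] += 1
        else:
            counters[2] += 1
    return counters
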