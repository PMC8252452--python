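"""Numba kernels for ray-driven projection.

Sinogram parameterisation: an LOR in plane ``p`` with azimuth ``phi`` (bin
centers at ``(a + 0.5) * pi / n_angles``) and signed radial offset ``s``
(uniform bins centered on the isocenter) is the 2D line
``x(t) = s * (-sin phi, cos phi) + t * (cos phi, sin phi)``.  Planes map
one-to-one onto z slices of the volume grid; all kernels therefore traverse
2D slices with an Amanatides-Woo stepper whose step lengths are exact
voxel-chord lengths in mm.
"""

import numpy as np
from numba import njit, prange


@njit(cache=True, fastmath=True)
def _line_integral_2d(img, nx, ny, vx, vy, xmin, ymin, px, py, ux, uy):
    """Exact line integral (value * mm) of one ray through a 2D slice."""
    xmax = xmin + nx * vx
    ymax = ymin + ny * vy
    tmin = -1.0e30
    tmax = 1.0e30
    if abs(ux) < 1e-12:
        if px <= xmin or px >= xmax:
            return 0.0
    else:
        t1 = (xmin - px) / ux
        t2 = (xmax - px) / ux
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    if abs(uy) < 1e-12:
        if py <= ymin or py >= ymax:
            return 0.0
    else:
        t1 = (ymin - py) / uy
        t2 = (ymax - py) / uy
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    if tmax <= tmin:
        return 0.0

    t = tmin
    x = px + t * ux
    y = py + t * uy
    ix = int(np.floor((x - xmin) / vx))
    iy = int(np.floor((y - ymin) / vy))
    if ix < 0:
        ix = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    if iy > ny - 1:
        iy = ny - 1

    if ux > 0:
        stepx, tdx = 1, vx / ux
        tx = ((ix + 1) * vx + xmin - px) / ux
    elif ux < 0:
        stepx, tdx = -1, -vx / ux
        tx = (ix * vx + xmin - px) / ux
    else:
        stepx, tdx, tx = 0, 1.0e30, 1.0e30
    if uy > 0:
        stepy, tdy = 1, vy / uy
        ty = ((iy + 1) * vy + ymin - py) / uy
    elif uy < 0:
        stepy, tdy = -1, -vy / uy
        ty = (iy * vy + ymin - py) / uy
    else:
        stepy, tdy, ty = 0, 1.0e30, 1.0e30

    acc = 0.0
    while t < tmax - 1e-12:
        if tx < ty:
            tnext = tx if tx < tmax else tmax
            seg = tnext - t
            if seg > 0:
                acc += img[ix, iy] * seg
            t = tnext
            if tnext == tx:
                ix += stepx
                tx += tdx
                if ix < 0 or ix >= nx:
                    break
        else:
            tnext = ty if ty < tmax else tmax
            seg = tnext - t
            if seg > 0:
                acc += img[ix, iy] * seg
            t = tnext
            if tnext == ty:
                iy += stepy
                ty += tdy
                if iy < 0 or iy >= ny:
                    break
    return acc


@njit(cache=True, fastmath=True)
def _backproject_ray_2d(img, nx, ny, vx, vy, xmin, ymin, px, py, ux, uy, val):
    """Adjoint of :func:`_line_integral_2d`: add ``val * length`` per voxel."""
    xmax = xmin + nx * vx
    ymax = ymin + ny * vy
    tmin = -1.0e30
    tmax = 1.0e30
    if abs(ux) < 1e-12:
        if px <= xmin or px >= xmax:
            return
    else:
        t1 = (xmin - px) / ux
        t2 = (xmax - px) / ux
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    if abs(uy) < 1e-12:
        if py <= ymin or py >= ymax:
            return
    else:
        t1 = (ymin - py) / uy
        t2 = (ymax - py) / uy
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    if tmax <= tmin:
        return

    t = tmin
    x = px + t * ux
    y = py + t * uy
    ix = int(np.floor((x - xmin) / vx))
    iy = int(np.floor((y - ymin) / vy))
    if ix < 0:
        ix = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    if iy > ny - 1:
        iy = ny - 1

    if ux > 0:
        stepx, tdx = 1, vx / ux
        tx = ((ix + 1) * vx + xmin - px) / ux
    elif ux < 0:
        stepx, tdx = -1, -vx / ux
        tx = (ix * vx + xmin - px) / ux
    else:
        stepx, tdx, tx = 0, 1.0e30, 1.0e30
    if uy > 0:
        stepy, tdy = 1, vy / uy
        ty = ((iy + 1) * vy + ymin - py) / uy
    elif uy < 0:
        stepy, tdy = -1, -vy / uy
        ty = (iy * vy + ymin - py) / uy
    else:
        stepy, tdy, ty = 0, 1.0e30, 1.0e30

    while t < tmax - 1e-12:
        if tx < ty:
            tnext = tx if tx < tmax else tmax
            seg = tnext - t
            if seg > 0:
                img[ix, iy] += val * seg
            t = tnext
            if tnext == tx:
                ix += stepx
                tx += tdx
                if ix < 0 or ix >= nx:
                    break
        else:
            tnext = ty if ty < tmax else tmax
            seg = tnext - t
            if seg > 0:
                img[ix, iy] += val * seg
            t = tnext
            if tnext == ty:
                iy += stepy
                ty += tdy
                if iy < 0 or iy >= ny:
                    break


@njit(cache=True, parallel=True)
def fp_kernel(volz, sino, cos_a, sin_a, svals, vx, vy, xmin, ymin):
    """Forward project. volz: (nz, nx, ny); sino: (nz, n_angles, n_radial)."""
    nz, nx, ny = volz.shape
    n_angles = cos_a.shape[0]
    n_radial = svals.shape[0]
    for p in prange(nz):
        sl = volz[p]
        for a in range(n_angles):
            ux = cos_a[a]
            uy = sin_a[a]
            nxv = -sin_a[a]
            nyv = cos_a[a]
            for r in range(n_radial):
                s = svals[r]
                sino[p, a, r] = _line_integral_2d(
                    sl, nx, ny, vx, vy, xmin, ymin, s * nxv, s * nyv, ux, uy
                )


@njit(cache=True, parallel=True)
def bp_kernel(sino, volz, cos_a, sin_a, svals, vx, vy, xmin, ymin):
    """Back project (adjoint of fp_kernel). Accumulates into volz."""
    nz, nx, ny = volz.shape
    n_angles = cos_a.shape[0]
    n_radial = svals.shape[0]
    for p in prange(nz):
        sl = volz[p]
        for a in range(n_angles):
            ux = cos_a[a]
            uy = sin_a[a]
            nxv = -sin_a[a]
            nyv = cos_a[a]
            for r in range(n_radial):
                val = sino[p, a, r]
                if val != 0.0:
                    _backproject_ray_2d(
                        sl, nx, ny, vx, vy, xmin, ymin, svals[r] * nxv, svals[r] * nyv, ux, uy, val
                    )
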