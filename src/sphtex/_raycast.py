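"""Numba kernels for radial mean-intensity ray casting.

Rays start at the geometric cube center, advance with a fixed step, and stop
at the first sample outside the mask (nearest-neighbor lookup) or the cube
bounds (first-exit rule; concave re-entries are ignored). Intensity at a
sample is the mask-weighted multilinear interpolation
``interp(values * mask) / interp(mask)``: near the object boundary this
estimates the in-mask intensity without diluting it with the zeroed
background, so a constant object projects to an exact constant.
"""

import numba
import numpy as np


@numba.njit(cache=True, inline="always")
def _trilinear(vol, z, y, x):
    z0 = int(np.floor(z))
    y0 = int(np.floor(y))
    x0 = int(np.floor(x))
    nz, ny, nx = vol.shape
    z1 = min(z0 + 1, nz - 1)
    y1 = min(y0 + 1, ny - 1)
    x1 = min(x0 + 1, nx - 1)
    fz = z - z0
    fy = y - y0
    fx = x - x0
    c00 = vol[z0, y0, x0] * (1 - fx) + vol[z0, y0, x1] * fx
    c01 = vol[z0, y1, x0] * (1 - fx) + vol[z0, y1, x1] * fx
    c10 = vol[z1, y0, x0] * (1 - fx) + vol[z1, y0, x1] * fx
    c11 = vol[z1, y1, x0] * (1 - fx) + vol[z1, y1, x1] * fx
    c0 = c00 * (1 - fy) + c01 * fy
    c1 = c10 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@numba.njit(cache=True, inline="always")
def _bilinear(img, y, x):
    y0 = int(np.floor(y))
    x0 = int(np.floor(x))
    ny, nx = img.shape
    y1 = min(y0 + 1, ny - 1)
    x1 = min(x0 + 1, nx - 1)
    fy = y - y0
    fx = x - x0
    c0 = img[y0, x0] * (1 - fx) + img[y0, x1] * fx
    c1 = img[y1, x0] * (1 - fx) + img[y1, x1] * fx
    return c0 * (1 - fy) + c1 * fy


@numba.njit(cache=True)
def cast_rays_3d(values, mask, maskf, dirs, step):
    """Mean in-mask intensity along rays from the cube center.

    Parameters
    ----------
    values : (S, S, S) float64 array, intensity (zero outside mask).
    mask : (S, S, S) uint8 binary array; maskf is the same as float64.
    dirs : (n, 3) float64 array of unit direction vectors in (z, y, x) order.
    step : float, ray sampling step in voxels.

    Returns
    -------
    (n,) float64 array of per-ray mean intensities. The center sample always
    contributes, so no ray is empty.
    """
    S = values.shape[0]
    c = (S - 1) / 2.0
    n = dirs.shape[0]
    out = np.empty(n, dtype=np.float64)
    hi = S - 1.0
    for i in range(n):
        dz, dy, dx = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        total = 0.0
        count = 0
        t = 0.0
        while True:
            z = c + t * dz
            y = c + t * dy
            x = c + t * dx
            if z < 0.0 or z > hi or y < 0.0 or y > hi or x < 0.0 or x > hi:
                break
            iz = int(np.rint(z))
            iy = int(np.rint(y))
            ix = int(np.rint(x))
            if count > 0 and mask[iz, iy, ix] == 0:
                break
            w = _trilinear(maskf, z, y, x)
            if w > 1e-12:
                total += _trilinear(values, z, y, x) / w
            count += 1
            t += step
        out[i] = total / count
    return out


@numba.njit(cache=True)
def cast_rays_2d(values, mask, maskf, dirs, step):
    """2D analog of :func:`cast_rays_3d`; dirs are (n, 2) in (y, x) order."""
    S = values.shape[0]
    c = (S - 1) / 2.0
    n = dirs.shape[0]
    out = np.empty(n, dtype=np.float64)
    hi = S - 1.0
    for i in range(n):
        dy, dx = dirs[i, 0], dirs[i, 1]
        total = 0.0
        count = 0
        t = 0.0
        while True:
            y = c + t * dy
            x = c + t * dx
            if y < 0.0 or y > hi or x < 0.0 or x > hi:
                break
            iy = int(np.rint(y))
            ix = int(np.rint(x))
            if count > 0 and mask[iy, ix] == 0:
                break
            w = _bilinear(maskf, y, x)
            if w > 1e-12:
                total += _bilinear(values, y, x) / w
            count += 1
            t += step
        out[i] = total / count
    return out
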