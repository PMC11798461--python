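"""Spherical-harmonic analysis/synthesis on the Gauss-Legendre grid.

Real spherical harmonics under the geodesy 4-pi normalization: each basis
function has mean-square value 1 over the sphere, so the sum of squared
coefficients of a normalized signal equals its variance. Coefficients are
computed by an FFT in longitude followed by exact Gauss-Legendre quadrature
in latitude; with nlat nodes the quadrature integrates products of
band-limited functions up to degree L = nlat - 1 exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import assoc_legendre_p_all

_legendre_cache: dict = {}


def legendre_bar(lmax: int, x: np.ndarray) -> np.ndarray:
    """Geodesy 4-pi normalized associated Legendre functions.

    Returns ``P[l, m, j]`` for l, m = 0..lmax evaluated at ``x`` such that
    the real basis functions ``P[l, m] * cos(m*phi)`` and
    ``P[l, m] * sin(m*phi)`` have mean-square value 1 on the sphere:
    ``int P[l, m]^2 dx = 2`` for m = 0 and ``4`` for m > 0.
    """
    x = np.asarray(x, dtype=np.float64)
    # scipy's norm=True is orthonormal on [-1, 1]: int P~^2 dx = 1
    p = assoc_legendre_p_all(lmax, lmax, x, norm=True)[0]
    p = np.ascontiguousarray(p[:, : lmax + 1, :])  # keep m >= 0
    scale = np.full(lmax + 1, 2.0)
    scale[0] = np.sqrt(2.0)
    return p * scale[None, :, None]


def _grid_key(nlat: int, lmax: int):
    return (nlat, lmax)


def _cached_legendre(colat: np.ndarray, lmax: int) -> np.ndarray:
    key = _grid_key(colat.size, lmax)
    hit = _legendre_cache.get(key)
    if hit is not None and np.array_equal(hit[0], colat):
        return hit[1]
    P = legendre_bar(lmax, np.cos(colat))
    if len(_legendre_cache) > 8:  # bound memory across many grid sizes
        _legendre_cache.clear()
    _legendre_cache[key] = (colat.copy(), P)
    return P


def analyze(values, colatitudes, weights, lmax: int | None = None):
    """Expand a grid function in real 4-pi normalized spherical harmonics.

    Parameters
    ----------
    values : (nlat, nlon) array on the Gauss-Legendre grid.
    colatitudes, weights : quadrature nodes (as colatitude) and weights.
    lmax : bandlimit; defaults to nlat - 1. Requires nlon >= 2*lmax + 1.

    Returns
    -------
    (ccos, csin) : two (lmax+1, lmax+1) arrays, coefficients of
    ``P[l,m] cos(m phi)`` and ``P[l,m] sin(m phi)`` (csin row m=0 is zero).
    The coefficient of the constant is the area-weighted mean.
    """
    values = np.asarray(values, dtype=np.float64)
    nlat, nlon = values.shape
    if lmax is None:
        lmax = nlat - 1
    if lmax > nlat - 1:
        raise ValueError(f"lmax {lmax} exceeds quadrature bandlimit {nlat - 1}")
    if nlon < 2 * lmax + 1:
        raise ValueError(
            f"nlon={nlon} too small for bandlimit {lmax}; need >= {2 * lmax + 1}"
        )
    P = _cached_legendre(np.asarray(colatitudes), lmax)
    G = np.fft.rfft(values, axis=1)  # (nlat, nlon//2 + 1)
    m_arr = G[:, : lmax + 1]
    # c_lm = (1/4pi) * (2pi/nlon) * sum_j w_j P[l,m](x_j) * (sum_k f cos/sin)
    wre = weights[:, None] * m_arr.real  # (nlat, lmax+1)
    wim = weights[:, None] * m_arr.imag
    ccos = np.einsum("lmj,jm->lm", P, wre) / (2.0 * nlon)
    csin = -np.einsum("lmj,jm->lm", P, wim) / (2.0 * nlon)
    csin[:, 0] = 0.0
    # zero the upper triangle (m > l), where P is zero anyway up to fp noise
    tri = np.tril(np.ones((lmax + 1, lmax + 1), dtype=bool))
    ccos[~tri] = 0.0
    csin[~tri] = 0.0
    return ccos, csin


def synthesize(ccos, csin, colatitudes, nlon: int) -> np.ndarray:
    """Evaluate a coefficient set back onto the grid (inverse of analyze)."""
    lmax = ccos.shape[0] - 1
    if nlon < 2 * lmax + 1:
        raise ValueError("nlon too small for the coefficient bandlimit")
    P = _cached_legendre(np.asarray(colatitudes), lmax)
    A = np.einsum("lm,lmj->jm", ccos, P)  # (nlat, lmax+1)
    B = np.einsum("lm,lmj->jm", csin, P)
    H = np.zeros((colatitudes.size, nlon // 2 + 1), dtype=np.complex128)
    H[:, : lmax + 1] = (A - 1j * B) * (nlon / 2.0)
    H[:, 0] = A[:, 0] * nlon
    return np.fft.irfft(H, n=nlon, axis=1)


def power_per_degree(ccos, csin) -> np.ndarray:
    """Rotationally invariant power spectrum S(l) = sum_m (c^2 + s^2)."""
    return (ccos**2 + csin**2).sum(axis=1)


def basis_function(l: int, m: int, colatitudes, longitudes) -> np.ndarray:
    """One real 4-pi normalized basis function sampled on the grid.

    ``m >= 0`` selects the cos(m phi) branch, ``m < 0`` the sin(|m| phi)
    branch, mirroring the real-coefficient layout of :func:`analyze`.
    """
    if abs(m) > l:
        raise ValueError(f"invalid (l, m) = ({l}, {m}): need |m| <= l")
    P = legendre_bar(l, np.cos(np.atleast_1d(colatitudes)))
    lat_part = P[l, abs(m), :]
    lon = np.atleast_1d(longitudes)
    lon_part = np.cos(m * lon) if m >= 0 else np.sin(-m * lon)
    return lat_part[:, None] * lon_part[None, :]


def basis_value(l: int, m: int, theta, phi) -> np.ndarray:
    """Real 4-pi normalized basis function at arbitrary directions.

    ``theta``/``phi`` are broadcastable arrays of colatitude/longitude.
    """
    if abs(m) > l:
        raise ValueError(f"invalid (l, m) = ({l}, {m}): need |m| <= l")
    theta = np.asarray(theta, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    flat = np.cos(theta).ravel()
    P = assoc_legendre_p_all(l, abs(m), flat, norm=True)[0][l, abs(m), :]
    P = P.reshape(theta.shape) * (np.sqrt(2.0) if m == 0 else 2.0)
    lon_part = np.cos(m * phi) if m >= 0 else np.sin(-m * phi)
    return P * lon_part
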