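"""Polarization: projection peak direction and angle to a reference.

The peak direction is the grid direction of the maximum projection value,
a proxy for object polarization (e.g. a cell's leading edge). Depending on
the data it can help to band-pass the projection to the wavelength range of
interest first. The angle between two directions is the shortest rotation
between them, so its maximum is pi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import harmonics
from .errors import BandError
from .projection import CircularProjection, SphericalProjection


@dataclass
class PeakDirection:
    """Direction of the projection maximum.

    2D: ``angle`` on [0, 2*pi), ``colatitude`` is None.
    3D: (colatitude, longitude) pair with ``angle`` holding the longitude.
    """

    angle: float
    peak_value: float
    colatitude: float | None = None

    @property
    def is_3d(self) -> bool:
        return self.colatitude is not None


def bandpass(proj, lo: int, hi: int):
    """Reconstruct a projection from degrees (frequencies) in [lo, hi] only.

    Linear and idempotent for input already band-limited to the band.
    """
    if isinstance(proj, SphericalProjection):
        lmax = proj.nlat - 1
        if not (1 <= lo <= hi <= lmax):
            raise BandError(f"invalid band [{lo}, {hi}] for bandlimit {lmax}")
        ccos, csin = harmonics.analyze(
            proj.values, proj.colatitudes, proj.weights, lmax=lmax
        )
        keep = np.zeros(lmax + 1, dtype=bool)
        keep[lo : hi + 1] = True
        ccos = ccos * keep[:, None]
        csin = csin * keep[:, None]
        values = harmonics.synthesize(ccos, csin, proj.colatitudes, proj.nlon)
        return replace(proj, values=values)
    if isinstance(proj, CircularProjection):
        kmax = proj.n // 2
        if not (1 <= lo <= hi <= kmax):
            raise BandError(f"invalid band [{lo}, {hi}] for bandlimit {kmax}")
        F = np.fft.rfft(proj.values)
        keep = np.zeros(F.size, dtype=bool)
        keep[lo : hi + 1] = True
        values = np.fft.irfft(F * keep, n=proj.n)
        return replace(proj, values=values)
    raise TypeError(f"unsupported projection type: {type(proj).__name__}")


def peak_direction(proj, band: tuple[int, int] | None = None) -> PeakDirection:
    """Grid direction of the maximum projection value.

    Ties are broken toward the smallest colatitude, then smallest longitude
    (2D: smallest angle) — np.argmax's first-occurrence rule on the
    row-major grid. Peaks are grid-resolution only (no sub-grid refinement).
    """
    if band is not None:
        proj = bandpass(proj, *band)
    values = proj.values
    if np.ptp(values) == 0:
        warnings.warn("constant projection: no unique peak", stacklevel=2)
    flat = int(np.argmax(values))
    if isinstance(proj, SphericalProjection):
        i, j = np.unravel_index(flat, values.shape)
        return PeakDirection(
            angle=float(proj.longitudes[j]),
            colatitude=float(proj.colatitudes[i]),
            peak_value=float(values[i, j]),
        )
    return PeakDirection(
        angle=float(proj.angles[flat]), peak_value=float(values[flat])
    )


def _to_unit_vector(d: PeakDirection) -> np.ndarray:
    theta, phi = d.colatitude, d.angle
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def angle_between(a, b) -> float:
    """Shortest angle between two directions, in [0, pi].

    Accepts plain angles (2D), (colatitude, longitude) pairs (3D), or
    :class:`PeakDirection` objects. 2D uses wrap-around distance on the
    circle; 3D the great-circle angle.
    """
    if isinstance(a, PeakDirection) and isinstance(b, PeakDirection):
        if a.is_3d != b.is_3d:
            raise ValueError("cannot mix 2D and 3D directions")
        if a.is_3d:
            return angle_between((a.colatitude, a.angle), (b.colatitude, b.angle))
        return angle_between(a.angle, b.angle)
    if np.isscalar(a) and np.isscalar(b):
        d = abs(float(a) - float(b)) % (2 * np.pi)
        return min(d, 2 * np.pi - d)
    (ta, pa), (tb, pb) = a, b
    # spherical law of cosines, clipped against fp overshoot
    cosang = np.cos(ta) * np.cos(tb) + np.sin(ta) * np.sin(tb) * np.cos(pa - pb)
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))
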