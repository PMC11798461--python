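"""Power spectra, wavelength mapping, and the binned texture descriptor.

The normalized projection is decomposed into rotationally invariant power
per harmonic degree (3D) or per frequency (2D). Degrees are mapped to an
approximate cartesian wavelength through the Jeans relation
``lambda = 2*pi*R / sqrt(l*(l+1))`` on the unit sphere (R = 1), expressed as
a fraction of the full circle (rad/2pi), with the anchor ``lambda = 1`` at
degree 1 where the relation breaks down. Power is then integrated locally
into 20 log2-spaced wavelength bins, preserving the area under the curve:
for a unit-variance projection the descriptor sums to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import harmonics
from .projection import (
    DEFAULT_CUBE_SIDE,
    DEFAULT_NCIRCLE,
    DEFAULT_NLAT,
    DEFAULT_NLON,
    CircularProjection,
    LabeledImage,
    SphericalProjection,
    extract_object,
)

DEFAULT_NBINS = 20


@dataclass
class DegreeSpectrum:
    """Per-degree (3D) or per-frequency (2D) power with a wavelength axis.

    Index 0 is the mean term; it is zero for normalized input and carries no
    wavelength. For indices >= 1 the power of a normalized projection sums
    to 1 (Parseval).
    """

    power: np.ndarray  # (L+1,) non-negative
    wavelengths: np.ndarray  # (L+1,); entry 0 is NaN (mean term)
    ndim: int  # 3 for spherical harmonics, 2 for Fourier

    @property
    def lmax(self) -> int:
        return self.power.size - 1

    def total_power(self) -> float:
        return float(self.power[1:].sum())

    def centroid_wavelength(self) -> float:
        """Power-weighted geometric-mean wavelength (coarseness summary)."""
        p = self.power[1:]
        lam = self.wavelengths[1:]
        return float(2.0 ** ((p * np.log2(lam)).sum() / p.sum()))


@dataclass
class BinnedSpectrum:
    """The 20-value texture descriptor with log2-spaced wavelength bins.

    ``bin_edges`` has nbins + 1 wavelengths, decreasing from the longest
    (coarsest, lambda = 1) to the shortest resolvable wavelength; values[0]
    is the longest-wavelength (coarsest) bin. The values sum to the total
    power of the source spectrum (area preservation).
    """

    values: np.ndarray  # (nbins,)
    bin_edges: np.ndarray  # (nbins + 1,), decreasing wavelengths
    label: int = 1
    size_pixels: int = 0
    ndim: int = 3

    @property
    def nbins(self) -> int:
        return self.values.size

    def centroid_wavelength(self) -> float:
        """Power-weighted geometric-mean of bin-center wavelengths."""
        centers = np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])
        v = self.values
        if v.sum() == 0:
            return float("nan")
        return float(2.0 ** ((v * np.log2(centers)).sum() / v.sum()))


def degree_to_wavelength(l: int) -> float:
    """Approximate angular wavelength of harmonic degree ``l`` in rad/2pi.

    Jeans relation on the unit sphere, anchored to 1 at degree 1 (one peak
    and one valley across the sphere).
    """
    if l < 1:
        raise ValueError("mean term has no wavelength (l must be >= 1)")
    if l == 1:
        return 1.0
    return 1.0 / np.sqrt(l * (l + 1.0))


def _wavelength_axis(lmax: int, ndim: int) -> np.ndarray:
    lam = np.empty(lmax + 1)
    lam[0] = np.nan
    ks = np.arange(1, lmax + 1, dtype=np.float64)
    if ndim == 3:
        lam[1:] = 1.0 / np.sqrt(ks * (ks + 1.0))
        lam[1] = 1.0
    else:
        lam[1:] = 1.0 / ks
    return lam


def sh_power_spectrum(
    proj: SphericalProjection, lmax: int | None = None
) -> DegreeSpectrum:
    """Spherical-harmonic power per degree of a normalized projection.

    Coefficients are computed under the geodesy 4-pi convention on the
    quadrature grid, so ``sum_{l>=1} S(l)`` equals the weighted variance (1
    for normalized input).
    """
    if not proj.normalized:
        raise ValueError("projection must be normalized first")
    if lmax is None:
        lmax = proj.nlat - 1
    ccos, csin = harmonics.analyze(
        proj.values, proj.colatitudes, proj.weights, lmax=lmax
    )
    power = harmonics.power_per_degree(ccos, csin)
    return DegreeSpectrum(power=power, wavelengths=_wavelength_axis(lmax, 3), ndim=3)


def fourier_power_spectrum(proj: CircularProjection) -> DegreeSpectrum:
    """Fourier power per frequency of a normalized circular projection.

    P(k) is scaled so that ``sum_{k>=1} P(k)`` equals the sample variance
    (1 for normalized input); the wavelength of frequency k is 1/k rad/2pi.
    """
    if not proj.normalized:
        raise ValueError("projection must be normalized first")
    n = proj.n
    F = np.fft.rfft(proj.values)
    power = np.abs(F) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist term is not doubled
    kmax = n // 2
    return DegreeSpectrum(
        power=power, wavelengths=_wavelength_axis(kmax, 2), ndim=2
    )


def bin_log2(spec: DegreeSpectrum, nbins: int = DEFAULT_NBINS) -> BinnedSpectrum:
    """Integrate the spectrum locally into log2-spaced wavelength bins.

    Bin edges are uniform in log2(lambda) from lambda(1) = 1 down to
    lambda(L); each degree's power is assigned wholly to the bin containing
    its wavelength (ties go to the longer-wavelength bin), so the total is
    conserved exactly.
    """
    lmax = spec.lmax
    if lmax < nbins:
        raise ValueError(
            f"spectrum has {lmax} degrees >= 1; need at least {nbins} to bin"
        )
    lam = spec.wavelengths[1:]
    t = -np.log2(lam)  # 0 at lambda=1, increasing toward fine scales
    width = t[-1] / nbins
    idx = np.ceil(t / width).astype(int) - 1
    idx = np.clip(idx, 0, nbins - 1)
    values = np.bincount(idx, weights=spec.power[1:], minlength=nbins)
    edges = 2.0 ** (-width * np.arange(nbins + 1))
    return BinnedSpectrum(values=values, bin_edges=edges, ndim=spec.ndim)


def spherical_texture(
    image: LabeledImage,
    label: int,
    *,
    cube_side: int = DEFAULT_CUBE_SIDE,
    nlat: int = DEFAULT_NLAT,
    nlon: int = DEFAULT_NLON,
    n_circle: int = DEFAULT_NCIRCLE,
    nbins: int = DEFAULT_NBINS,
    weighted: bool = True,
    zero_variance: str = "error",
) -> BinnedSpectrum:
    """Full pipeline: one labeled object to its binned texture descriptor.

    Composition of extract_object -> rescale_to_cube -> (spherical |
    circular) projection -> normalize -> power spectrum -> bin_log2. The
    result carries the object's label and its size in pixels (voxel count at
    the original resolution).

    ``zero_variance="zero"`` maps constant objects to an all-zero descriptor
    instead of raising, for batch runs.
    """
    from .estimator import SphericalTextureExtractor  # local: avoid cycle

    crop, mask = extract_object(image, label)
    est = SphericalTextureExtractor(
        cube_side=cube_side, nlat=nlat, nlon=nlon, n_circle=n_circle,
        nbins=nbins, weighted=weighted, zero_variance=zero_variance,
    )
    binned, _ = est.describe_object(crop, mask, label=label)
    return binned
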