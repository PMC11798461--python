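"""Object extraction, cube resampling, and angular mean-intensity projection.

A segmented object is cropped at its bounding box, resampled to a fixed cube
(default 80 voxels per side, each axis stretched independently, which makes
the descriptor tolerant of anisotropic voxels), and projected: rays are cast
from the cube center in directions covering a Gauss-Legendre quadrature
sphere grid (3D) or a uniform circle (2D), and each ray carries the mean
intensity of the voxels it traverses until it first leaves the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize

from ._raycast import cast_rays_2d, cast_rays_3d
from .errors import (
    CentroidOutsideMaskError,
    DegenerateObjectError,
    LabelNotFoundError,
    ZeroVarianceError,
)

DEFAULT_CUBE_SIDE = 80
DEFAULT_NLAT = 251
DEFAULT_NLON = 512
DEFAULT_NCIRCLE = 251

#: Ray sampling step in voxels (multilinear intensity, nearest-neighbor mask).
RAY_STEP = 0.5


@dataclass
class LabeledImage:
    """An intensity raster plus a co-registered integer label raster.

    Label 0 is background; objects are labeled >= 1. Axis order is assumed
    ZYX (3D) or YX (2D).
    """

    intensity: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity)
        self.labels = np.asarray(self.labels)
        if self.intensity.shape != self.labels.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != labels shape "
                f"{self.labels.shape}"
            )
        if self.intensity.ndim not in (2, 3):
            raise ValueError("only 2D or 3D images are supported")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer raster")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def ndim(self) -> int:
        return self.intensity.ndim

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class ObjectCube:
    """One object resampled to a cube of side ``side`` with a binary mask."""

    values: np.ndarray
    mask: np.ndarray
    label: int = 1

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        self.mask = np.ascontiguousarray(self.mask).astype(np.uint8)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        side = self.values.shape[0]
        if any(s != side for s in self.values.shape):
            raise ValueError("all cube axes must have equal length")
        if not self.mask.any():
            raise DegenerateObjectError("degenerate object: empty mask")

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def center_in_mask(self) -> bool:
        c = int(np.rint((self.side - 1) / 2.0))
        return bool(self.mask[(c,) * self.ndim])


def _gauss_legendre_grid(nlat: int, nlon: int):
    """Colatitude nodes/weights and longitudes for the quadrature sphere grid.

    Colatitudes are strictly increasing in (0, pi); the weights integrate a
    band-limited function exactly: sum_j w_j * (2*pi/nlon) * nlon = 4*pi for
    the unit function.
    """
    x, w = np.polynomial.legendre.leggauss(nlat)
    # leggauss returns x ascending in (-1, 1); theta = arccos(x) descending
    theta = np.arccos(x)[::-1].copy()
    w = w[::-1].copy()
    lon = np.arange(nlon) * (2 * np.pi / nlon)
    return theta, w, lon


@dataclass
class SphericalProjection:
    """Angular mean intensity on a Gauss-Legendre quadrature sphere grid."""

    values: np.ndarray  # (nlat, nlon)
    colatitudes: np.ndarray  # (nlat,)
    weights: np.ndarray  # (nlat,) Gauss-Legendre weights, sum = 2
    longitudes: np.ndarray  # (nlon,)
    normalized: bool = False

    @property
    def nlat(self) -> int:
        return self.values.shape[0]

    @property
    def nlon(self) -> int:
        return self.values.shape[1]

    def weighted_mean(self) -> float:
        w = self.weights / self.weights.sum()
        return float((w @ self.values).mean())

    def weighted_var(self) -> float:
        mu = self.weighted_mean()
        w = self.weights / self.weights.sum()
        return float((w @ (self.values - mu) ** 2).mean())


@dataclass
class CircularProjection:
    """Angular mean intensity on a uniform circle (2D variant)."""

    values: np.ndarray  # (n,)
    angles: np.ndarray  # (n,) uniform on [0, 2*pi), first angle 0
    normalized: bool = False

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def weighted_mean(self) -> float:
        return float(self.values.mean())

    def weighted_var(self) -> float:
        return float(self.values.var())


def extract_object(image: LabeledImage, label: int):
    """Tight bounding-box crop of one label.

    Returns ``(intensity crop, binary mask crop)``. Intensity outside the
    mask is retained in the crop; masking happens after the rescale step.
    Multi-component labels are processed as-is.
    """
    if label < 1:
        raise LabelNotFoundError(f"label must be >= 1, got {label}")
    where = image.labels == label
    if not where.any():
        raise LabelNotFoundError(f"label not found: {label}")
    slices = tuple(
        slice(int(idx.min()), int(idx.max()) + 1) for idx in np.nonzero(where)
    )
    return image.intensity[slices].copy(), where[slices].astype(np.uint8)


def rescale_to_cube(
    intensity: np.ndarray, mask: np.ndarray, side: int = DEFAULT_CUBE_SIDE, label: int = 1
) -> ObjectCube:
    """Resample a crop to ``side`` per axis and apply the resampled mask.

    Intensity is interpolated multilinearly; the mask with nearest neighbor
    (so it stays binary). Each axis is stretched independently. Intensity
    outside the resampled mask is set to zero.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    mask = np.asarray(mask)
    if intensity.ndim not in (2, 3):
        raise ValueError("crop must be 2D or 3D")
    shape = (side,) * intensity.ndim
    values = resize(
        intensity, shape, order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    rmask = resize(
        mask.astype(np.uint8), shape, order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ).astype(np.uint8)
    if not rmask.any():
        raise DegenerateObjectError("degenerate object: mask empty after resampling")
    values = values * rmask
    return ObjectCube(values=values, mask=rmask, label=label)


def _sphere_directions(theta: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Unit vectors (z, y, x) for every (colatitude, longitude) pair."""
    st = np.sin(theta)[:, None]
    dz = np.broadcast_to(np.cos(theta)[:, None], (theta.size, lon.size))
    dy = st * np.sin(lon)[None, :]
    dx = st * np.cos(lon)[None, :]
    return np.ascontiguousarray(
        np.stack([dz, dy, dx], axis=-1).reshape(-1, 3), dtype=np.float64
    )


def spherical_project(
    cube: ObjectCube,
    nlat: int = DEFAULT_NLAT,
    nlon: int = DEFAULT_NLON,
    step: float = RAY_STEP,
) -> SphericalProjection:
    """Cast center-to-surface rays over the quadrature grid (3D objects).

    Each grid cell receives the mean intensity along its ray; rays stop at
    the first sample outside the mask or the cube. The center sample always
    contributes, so values are defined for every direction.
    """
    if cube.ndim != 3:
        raise ValueError("spherical_project requires a 3D cube; use circular_project for 2D")
    if not cube.center_in_mask():
        raise CentroidOutsideMaskError("centroid outside mask")
    theta, w, lon = _gauss_legendre_grid(nlat, nlon)
    dirs = _sphere_directions(theta, lon)
    maskf = cube.mask.astype(np.float64)
    vals = cast_rays_3d(cube.values, cube.mask, maskf, dirs, step).reshape(nlat, nlon)
    return SphericalProjection(
        values=vals, colatitudes=theta, weights=w, longitudes=lon
    )


def circular_project(
    cube: ObjectCube, n: int = DEFAULT_NCIRCLE, step: float = RAY_STEP
) -> CircularProjection:
    """Cast rays along the equator only (2D objects)."""
    if cube.ndim != 2:
        raise ValueError("circular_project requires a 2D cube")
    if not cube.center_in_mask():
        raise CentroidOutsideMaskError("centroid outside mask")
    angles = np.arange(n) * (2 * np.pi / n)
    dirs = np.ascontiguousarray(
        np.stack([np.sin(angles), np.cos(angles)], axis=-1), dtype=np.float64
    )
    maskf = cube.mask.astype(np.float64)
    vals = cast_rays_2d(cube.values, cube.mask, maskf, dirs, step)
    return CircularProjection(values=vals, angles=angles)


def normalize(proj, weighted: bool = True):
    """Normalize a projection to mean 0 and variance 1.

    A spherical projection is first restricted to its band-limited component
    (degrees up to the grid's quadrature bandlimit) — the only part of the
    map the harmonic spectrum can represent — and the statistics are
    area-weighted with the quadrature weights by default, so that total
    spectral power equals the variance exactly (Parseval); set
    ``weighted=False`` for plain sample statistics. The circle's discrete
    Fourier basis is complete, so no restriction is needed there and weights
    are uniform.
    """
    from . import harmonics  # deferred: keep import graph light for 2D use

    if proj.normalized:
        raise ValueError("projection is already normalized")
    values = proj.values
    if isinstance(proj, SphericalProjection):
        lmax = min(proj.nlat - 1, (proj.nlon - 1) // 2)
        ccos, csin = harmonics.analyze(
            values, proj.colatitudes, proj.weights, lmax=lmax
        )
        values = harmonics.synthesize(ccos, csin, proj.colatitudes, proj.nlon)
        proj = replace(proj, values=values)
        if weighted:
            mu = float(ccos[0, 0])
            var = float((ccos**2 + csin**2).sum() - mu * mu)
        else:
            mu = float(values.mean())
            var = float(values.var())
    else:
        mu = float(values.mean())
        var = float(values.var())
    if var < 1e-12 * max(1.0, mu * mu):
        raise ZeroVarianceError(
            "zero-variance projection: the texture descriptor is undefined "
            "for constant objects (batch callers may map this to an all-zero "
            "descriptor)"
        )
    return replace(proj, values=(values - mu) / np.sqrt(var), normalized=True)
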