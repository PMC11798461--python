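"""Synthetic validation data: Perlin-noise volumes, shape masks, harmonic
patterns, and radial clipping.

These generators reproduce the study conditions used to validate the
descriptor: gradient-lattice (Perlin) noise rendered at controlled
coarseness inside sphere/cone/star masks, pure-harmonic intensity patterns
for basis-level checks, and radial shells to probe how signal placement
changes apparent scale. 2D variants are the middle plane of the 3D fields.
All generators are deterministic under a fixed seed, so no external data is
needed to exercise any pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import harmonics
from .errors import DegenerateObjectError
from .projection import DEFAULT_CUBE_SIDE, ObjectCube

DEFAULT_PERLIN_SIDE = 128


@dataclass
class PerlinSpec:
    """Parameters of a gradient-lattice noise volume.

    ``periods`` is the number of noise periods along each axis across the
    grid (the coarseness dial: fewer periods = coarser pattern); the side
    must be divisible by it (lattice constraint).
    """

    side: int = DEFAULT_PERLIN_SIDE
    periods: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.periods < 1:
            raise ValueError("periods must be a positive integer")
        if self.side % self.periods != 0:
            raise ValueError(
                f"side {self.side} not divisible by periods {self.periods}"
            )


def _fade(t: np.ndarray) -> np.ndarray:
    # quintic smoothstep: zero first and second derivative at lattice planes
    return t * t * t * (t * (t * 6 - 15) + 10)


def _unit_gradients(rng: np.random.Generator, shape) -> np.ndarray:
    g = rng.normal(size=shape)
    norm = np.sqrt((g**2).sum(axis=-1, keepdims=True))
    norm[norm == 0] = 1.0
    return g / norm


def perlin_volume(spec: PerlinSpec) -> np.ndarray:
    """Classical 3D Perlin noise on a cubic grid, values in [-1, 1].

    Gradients are seeded unit vectors on the lattice; cell interpolation
    uses the quintic fade, so values at lattice corners are exactly 0.
    """
    side, res = spec.side, spec.periods
    rng = np.random.default_rng(spec.seed)
    grads = _unit_gradients(rng, (res + 1, res + 1, res + 1, 3))
    return _perlin_blend(grads, side, res, ndim=3)


def perlin_image(spec: PerlinSpec) -> np.ndarray:
    """2D gradient-lattice noise, values in [-1, 1]."""
    side, res = spec.side, spec.periods
    rng = np.random.default_rng(spec.seed)
    grads = _unit_gradients(rng, (res + 1, res + 1, 2))
    return _perlin_blend(grads, side, res, ndim=2)


def _perlin_blend(grads: np.ndarray, side: int, res: int, ndim: int) -> np.ndarray:
    d = side // res
    # fractional position of every voxel within its lattice cell
    frac1 = (np.arange(side) % d) / d
    frac = np.meshgrid(*([frac1] * ndim), indexing="ij")
    fade = [_fade(f) for f in frac]
    out = np.zeros((side,) * ndim)
    for corner in np.ndindex(*(2,) * ndim):
        sl = tuple(slice(c, c + res) for c in corner)
        g = grads[sl]  # (res, ..., ndim) gradient per cell for this corner
        for ax in range(ndim):
            g = np.repeat(g, d, axis=ax)
        ramp = np.zeros((side,) * ndim)
        weight = np.ones((side,) * ndim)
        for ax, c in enumerate(corner):
            ramp += g[..., ax] * (frac[ax] - c)
            weight *= fade[ax] if c else 1.0 - fade[ax]
        out += weight * ramp
    return out


def shape_mask(kind: str, side: int = DEFAULT_CUBE_SIDE) -> np.ndarray:
    """Binary 3D mask of a test shape: ``sphere``, ``cone``, or ``star``.

    The sphere has radius side/2; the cone is axis-aligned with base
    diameter and height both equal to side; the star is built from eight
    sphere-octants pushed outward along their diagonals over a central ball,
    yielding a pointed, genuinely non-convex shape (center-to-surface rays
    can exit and re-enter) that is hard to map back to a sphere. All masks
    contain the center voxel.
    """
    if side % 2 != 0:
        raise ValueError("side must be even")
    c = (side - 1) / 2.0
    ax = np.arange(side) - c
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    if kind == "sphere":
        return (z**2 + y**2 + x**2 <= (side / 2) ** 2).astype(np.uint8)
    if kind == "cone":
        # base (full diameter) at z = 0, apex at z = side - 1
        height = side - 1.0
        frac = (z + c) / height  # 0 at base, 1 at apex
        radius = (side / 2.0) * (1.0 - frac)
        return (np.sqrt(y**2 + x**2) <= radius).astype(np.uint8)
    if kind == "star":
        d = round(0.15 * side)
        R = 0.35 * side
        mask = z**2 + y**2 + x**2 <= d**2  # central ball
        for sz in (-1, 1):
            for sy in (-1, 1):
                for sx in (-1, 1):
                    octant = (sz * z >= d) & (sy * y >= d) & (sx * x >= d)
                    ball = (
                        (z - sz * d) ** 2 + (y - sy * d) ** 2 + (x - sx * d) ** 2
                        <= R**2
                    )
                    mask |= octant & ball
        return mask.astype(np.uint8)
    raise ValueError(f"unknown shape kind: {kind!r}")


def _direction_angles(side: int, ndim: int):
    """Colatitude/longitude (3D) or angle (2D) of each voxel from center."""
    c = (side - 1) / 2.0
    ax = np.arange(side) - c
    if ndim == 3:
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(z**2 + y**2 + x**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.where(r > 0, z / np.maximum(r, 1e-300), 1.0))
        phi = np.arctan2(y, x) % (2 * np.pi)
        return theta, phi
    y, x = np.meshgrid(ax, ax, indexing="ij")
    return np.arctan2(y, x) % (2 * np.pi)


def harmonic_pattern(l: int, m: int, side: int = DEFAULT_CUBE_SIDE) -> ObjectCube:
    """Spherical object painted with one 4-pi normalized basis function.

    Intensity at each voxel is the real basis function of the voxel's
    direction from the center (radially constant), masked by the centered
    sphere. Projecting this cube recovers the basis function on the grid.
    """
    if abs(m) > l:
        raise ValueError(f"invalid (l, m) = ({l}, {m}): need |m| <= l")
    theta, phi = _direction_angles(side, 3)
    values = harmonics.basis_value(l, m, theta, phi)
    mask = shape_mask("sphere", side)
    return ObjectCube(values=values * mask, mask=mask)


def clip_to_radius(cube: ObjectCube, r_lo: float, r_hi: float) -> ObjectCube:
    """Zero intensity outside the spherical shell [r_lo, r_hi]; mask kept.

    Probes radial signal placement: the same pattern appears coarser when
    confined closer to the center.
    """
    side = cube.side
    if not (0 <= r_lo < r_hi <= side / 2):
        raise ValueError(f"invalid shell [{r_lo}, {r_hi}] for side {side}")
    c = (side - 1) / 2.0
    ax = np.arange(side) - c
    grids = np.meshgrid(*([ax] * cube.ndim), indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids))
    shell = (r >= r_lo) & (r <= r_hi)
    if not (shell & (cube.mask > 0)).any():
        raise DegenerateObjectError("empty shell: no foreground voxels in radius range")
    return ObjectCube(values=cube.values * shell, mask=cube.mask, label=cube.label)


def perlin_object(
    periods: int = 8,
    seed: int = 0,
    kind: str = "sphere",
    side: int = DEFAULT_CUBE_SIDE,
    noise_side: int = DEFAULT_PERLIN_SIDE,
    ndim: int = 3,
) -> ObjectCube:
    """A shape mask filled with the central crop of a Perlin noise field.

    Noise is generated on its own (larger) grid and cropped centrally to the
    shape's side, so the pattern scale is independent of the object size;
    ``ndim=2`` uses the middle plane of the noise and a middle slice of the
    mask (a disk for ``kind="sphere"``).
    """
    spec = PerlinSpec(side=noise_side, periods=periods, seed=seed)
    noise = perlin_volume(spec)
    lo = (noise_side - side) // 2
    crop = noise[(slice(lo, lo + side),) * 3]
    mask3 = shape_mask(kind, side)
    if ndim == 3:
        return ObjectCube(values=crop * mask3, mask=mask3)
    if ndim == 2:
        mid = side // 2
        img, mask2 = crop[mid], mask3[mid]
        return ObjectCube(values=img * mask2, mask=mask2)
    raise ValueError("ndim must be 2 or 3")


def stretch_axis(cube: ObjectCube, factor: float, axis: int = 0):
    """Anisotropy fixture: stretch one axis by ``factor`` via multilinear
    resampling (mask nearest-neighbor), keeping other axes unchanged.

    Returns plain ``(values, mask)`` arrays (no longer a cube); feed them to
    :func:`sphtex.projection.rescale_to_cube` to run the pipeline on an
    anisotropic rendering of the same object.
    """
    from skimage.transform import resize

    shape = list(cube.values.shape)
    shape[axis] = int(round(shape[axis] * factor))
    values = resize(
        cube.values, shape, order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    mask = resize(
        cube.mask, shape, order=0, mode="edge", anti_aliasing=False,
        preserve_range=True,
    ).astype(np.uint8)
    return values * mask, mask


def write_fixture(
    out_dir, n_objects: int = 3, periods: int = 8, seed: int = 0,
    side: int = 40, ndim: int = 3,
):
    """Write a small TIFF intensity/label pair with Perlin-noise spheres.

    Objects are disjoint spheres on a padded canvas, labeled 1..n; returns
    the two file paths. Used for command-line round-trip tests.
    """
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pad = 4
    span = side + pad
    canvas_shape = (side + 2 * pad,) * (ndim - 1) + (n_objects * span + pad,)
    intensity = np.zeros(canvas_shape, dtype=np.float32)
    labels = np.zeros(canvas_shape, dtype=np.uint16)
    for i in range(n_objects):
        cube = perlin_object(
            periods=periods, seed=seed + i, side=side,
            noise_side=max(DEFAULT_PERLIN_SIDE, side), ndim=ndim,
        )
        sl = (slice(pad, pad + side),) * (ndim - 1) + (
            slice(pad + i * span, pad + i * span + side),
        )
        intensity[sl] = cube.values
        labels[sl][cube.mask > 0] = i + 1
    img_path = out_dir / "intensity.tif"
    lbl_path = out_dir / "labels.tif"
    tifffile.imwrite(img_path, intensity)
    tifffile.imwrite(lbl_path, labels)
    return img_path, lbl_path
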