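import numpy as np
import pytest
from hypothesis import settings

from sphtex.projection import ObjectCube

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# small quadrature grid for fast spherical tests (bandlimit 24)
SMALL_NLAT, SMALL_NLON = 25, 52


def reference_project(cube: ObjectCube, dirs: np.ndarray, step: float) -> np.ndarray:
    """Independent dense-step ray-integration oracle (pure numpy/scipy).

    Same ray rule as the production caster — fixed step from the cube
    center, mask-weighted multilinear intensity, nearest-neighbor mask, stop
    at first sample outside mask or bounds, center sample always counted —
    but built on scipy.ndimage.map_coordinates and vectorized cumulative
    masking.
    """
    from scipy.ndimage import map_coordinates

    S = cube.side
    c = (S - 1) / 2.0
    nt = int(np.ceil(S * np.sqrt(cube.ndim) / 2 / step)) + 2
    ts = np.arange(nt) * step
    pts = c + dirs[:, None, :] * ts[None, :, None]  # (nrays, nt, ndim)
    in_bounds = np.all((pts >= 0) & (pts <= S - 1), axis=-1)
    nn = np.rint(pts).astype(int).clip(0, S - 1)
    mask_hit = cube.mask[tuple(nn[..., d] for d in range(cube.ndim))].astype(bool)
    ok = mask_hit & in_bounds
    ok[:, 0] = True  # inclusive start
    alive = np.logical_and.accumulate(ok, axis=1)
    coords = pts.reshape(-1, cube.ndim).T
    vals = map_coordinates(
        cube.values, coords, order=1, mode="nearest"
    ).reshape(pts.shape[:2])
    wts = map_coordinates(
        cube.mask.astype(float), coords, order=1, mode="nearest"
    ).reshape(pts.shape[:2])
    vals = np.where(wts > 1e-12, vals / np.maximum(wts, 1e-12), 0.0)
    return (vals * alive).sum(axis=1) / alive.sum(axis=1)


def smooth_cube(seed: int, side: int = 40) -> ObjectCube:
    """Seeded random smooth intensity inside a centered spherical mask."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    values = gaussian_filter(rng.normal(size=(side,) * 3), sigma=3.0)
    ax = np.arange(side) - (side - 1) / 2.0
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (z**2 + y**2 + x**2 <= (side / 2) ** 2).astype(np.uint8)
    return ObjectCube(values=values * mask, mask=mask)


def disk_cube(side: int = 80, paint=None) -> ObjectCube:
    """2D disk mask, optionally painted with ``paint(y, x)`` intensity."""
    ax = np.arange(side) - (side - 1) / 2.0
    y, x = np.meshgrid(ax, ax, indexing="ij")
    mask = (y**2 + x**2 <= (side / 2) ** 2).astype(np.uint8)
    values = np.ones_like(mask, dtype=float) if paint is None else paint(y, x)
    return ObjectCube(values=values * mask, mask=mask)


@pytest.fixture(scope="session")
def small_grid():
    return SMALL_NLAT, SMALL_NLON
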