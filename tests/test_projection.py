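"""Object extraction, cube resampling, and ray-cast projections."""

import numpy as np
import pytest

import sphtex
from sphtex import (
    CentroidOutsideMaskError,
    DegenerateObjectError,
    LabelNotFoundError,
    LabeledImage,
    ObjectCube,
    ZeroVarianceError,
)
from sphtex.projection import _gauss_legendre_grid, _sphere_directions

from conftest import SMALL_NLAT, SMALL_NLON, disk_cube, reference_project, smooth_cube


class TestExtractObject:
    def test_single_voxel_label(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[3, 3, 3] = 1
        img = LabeledImage(intensity=np.random.default_rng(0).random((8, 8, 8)), labels=labels)
        crop, mask = sphtex.extract_object(img, 1)
        assert crop.shape == (1, 1, 1)
        assert mask.shape == (1, 1, 1) and mask.all()

    def test_box_label_bounding_box(self):
        labels = np.zeros((64, 64, 64), dtype=np.int32)
        labels[5:15, 10:30, 20:50] = 7
        img = LabeledImage(intensity=np.ones((64, 64, 64)), labels=labels)
        crop, mask = sphtex.extract_object(img, 7)
        assert crop.shape == (10, 20, 30)
        assert mask.all()

    def test_disjoint_components_share_label(self):
        # oracle: exhaustive scan of voxel coordinates carrying the label
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels[2:5, 2:5, 2:5] = 3
        labels[15:18, 12:16, 9:11] = 3
        rng = np.random.default_rng(1)
        img = LabeledImage(intensity=rng.random((20, 20, 20)), labels=labels)
        crop, mask = sphtex.extract_object(img, 3)
        coords = np.argwhere(labels == 3)
        lo, hi = coords.min(axis=0), coords.max(axis=0) + 1
        assert crop.shape == tuple(hi - lo)
        expected_mask = (labels == 3)[tuple(slice(a, b) for a, b in zip(lo, hi))]
        np.testing.assert_array_equal(mask.astype(bool), expected_mask)
        np.testing.assert_array_equal(
            crop, img.intensity[tuple(slice(a, b) for a, b in zip(lo, hi))]
        )

    def test_absent_label_raises(self):
        img = LabeledImage(
            intensity=np.zeros((4, 4)), labels=np.ones((4, 4), dtype=np.int32)
        )
        with pytest.raises(LabelNotFoundError):
            sphtex.extract_object(img, 2)


class TestRescaleToCube:
    def test_identity_resample(self):
        rng = np.random.default_rng(2)
        vals = rng.random((16, 16, 16))
        mask = np.ones((16, 16, 16), dtype=np.uint8)
        cube = sphtex.rescale_to_cube(vals, mask, side=16)
        np.testing.assert_allclose(cube.values, vals, atol=1e-12)
        np.testing.assert_array_equal(cube.mask, mask)

    def test_constant_preserved_inside_mask(self):
        vals = np.full((11, 23, 7), 4.2)
        mask = np.ones_like(vals, dtype=np.uint8)
        cube = sphtex.rescale_to_cube(vals, mask, side=32)
        np.testing.assert_allclose(cube.values[cube.mask > 0], 4.2, atol=1e-12)

    def test_upsampled_ramp_matches_analytic_interpolant(self):
        # 40^3 ramp along x to 80^3: output sample i maps to input
        # coordinate (i + 0.5) * 0.5 - 0.5, clipped at the edges
        ramp = np.broadcast_to(np.arange(40, dtype=float), (40, 40, 40)).copy()
        mask = np.ones((40, 40, 40), dtype=np.uint8)
        cube = sphtex.rescale_to_cube(ramp, mask, side=80)
        expected = np.clip((np.arange(80) + 0.5) * 0.5 - 0.5, 0, 39)
        np.testing.assert_allclose(cube.values[40, 40, :], expected, atol=1e-10)
        # per-voxel increment halves in the interior
        inc = np.diff(cube.values[40, 40, 1:-1])
        np.testing.assert_allclose(inc, 0.5, atol=1e-10)

    def test_anisotropic_crop_stretched_per_axis(self):
        vals = np.ones((10, 20, 40))
        mask = np.ones_like(vals, dtype=np.uint8)
        cube = sphtex.rescale_to_cube(vals, mask, side=16)
        assert cube.values.shape == (16, 16, 16)

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateObjectError):
            ObjectCube(values=np.zeros((4, 4, 4)), mask=np.zeros((4, 4, 4)))


class TestSphericalProject:
    def test_constant_object_constant_projection(self):
        cube = smooth_cube(0, side=32)
        cube.values = cube.mask.astype(float)
        proj = sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON)
        np.testing.assert_array_equal(proj.values, 1.0)

    @pytest.mark.parametrize("kind", ["sphere", "cone"])
    def test_star_convex_constant_stays_one(self, kind):
        # monotone ray rule: any star-convex mask containing the center
        # yields a projection identically 1 for unit intensity
        from sphtex.synthetic import shape_mask

        mask = shape_mask(kind, side=40)
        cube = ObjectCube(values=mask.astype(float), mask=mask)
        proj = sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON)
        np.testing.assert_array_equal(proj.values, 1.0)

    def test_half_bright_step_in_colatitude(self):
        cube = smooth_cube(0, side=40)
        c = (40 - 1) / 2.0
        z = np.arange(40) - c
        cube.values = (z[:, None, None] > 0) * cube.mask.astype(float)
        proj = sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON)
        theta, _, lon = _gauss_legendre_grid(SMALL_NLAT, SMALL_NLON)
        dirs = _sphere_directions(theta, lon)
        oracle = reference_project(cube, dirs, step=0.05).reshape(SMALL_NLAT, SMALL_NLON)
        assert np.abs(proj.values - oracle).max() < 0.05
        # step behavior: bright toward the +z pole, dark toward -z
        assert proj.values[0].mean() > 0.9
        assert proj.values[-1].mean() < 0.1

    def test_recovers_low_degree_harmonic_pattern(self):
        # analytic oracle; rendered at side 160 because voxel-direction
        # quantization near the cube center limits fidelity at coarser sides
        from sphtex import harmonics
        from sphtex.synthetic import harmonic_pattern

        for l, m in [(2, 0), (2, 1)]:
            cube = harmonic_pattern(l, m, side=160)
            proj = sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON)
            ref = harmonics.basis_function(l, m, proj.colatitudes, proj.longitudes)
            assert np.abs(proj.values - ref).max() < 0.06

    def test_center_outside_mask_raises(self):
        mask = np.zeros((16, 16, 16), dtype=np.uint8)
        mask[:4] = 1
        cube = ObjectCube(values=mask.astype(float), mask=mask)
        with pytest.raises(CentroidOutsideMaskError):
            sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON)

    def test_grid_contract_and_quadrature(self):
        cube = smooth_cube(3, side=32)
        proj = sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON)
        assert proj.values.shape == (SMALL_NLAT, SMALL_NLON)
        assert np.all(np.diff(proj.colatitudes) > 0)
        assert proj.colatitudes[0] > 0 and proj.colatitudes[-1] < np.pi
        assert np.all(proj.weights > 0)
        # unit function integrates to the full sphere area
        total = proj.weights.sum() * (2 * np.pi / proj.nlon) * proj.nlon
        assert abs(total - 4 * np.pi) < 1e-9

    def test_2d_input_to_3d_path_rejected(self):
        cube = disk_cube(side=20)
        with pytest.raises(ValueError, match="3D"):
            sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_step_oracle(self, seed):
        # 10x finer ray step, independent implementation, same normalization
        from sphtex.projection import SphericalProjection
        from sphtex.synthetic import perlin_object

        cube = perlin_object(periods=4, seed=seed, side=40, noise_side=128)
        proj = sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON)
        theta, w, lon = _gauss_legendre_grid(SMALL_NLAT, SMALL_NLON)
        dirs = _sphere_directions(theta, lon)
        oracle = reference_project(cube, dirs, step=0.05).reshape(
            SMALL_NLAT, SMALL_NLON
        )
        oracle_proj = SphericalProjection(
            values=oracle, colatitudes=theta, weights=w, longitudes=lon
        )
        ours = sphtex.normalize(proj).values
        ref = sphtex.normalize(oracle_proj).values
        assert np.abs(ours - ref).max() < 0.05


class TestCircularProject:
    def test_constant_disk(self):
        cube = disk_cube(side=40)
        proj = sphtex.circular_project(cube, n=64)
        np.testing.assert_array_equal(proj.values, 1.0)
        assert proj.angles[0] == 0
        np.testing.assert_allclose(np.diff(proj.angles), 2 * np.pi / 64)

    def test_radial_cosine_paint(self):
        cube = disk_cube(side=80, paint=lambda y, x: np.cos(np.arctan2(y, x)))
        proj = sphtex.circular_project(cube)
        oracle = reference_project(
            cube,
            np.stack([np.sin(proj.angles), np.cos(proj.angles)], axis=-1),
            step=0.05,
        )
        assert np.abs(proj.values - oracle).max() < 0.05
        assert np.abs(proj.values - np.cos(proj.angles)).max() < 0.05

    def test_half_bright_disk(self):
        cube = disk_cube(side=80, paint=lambda y, x: (x > 0).astype(float))
        proj = sphtex.circular_project(cube)
        assert proj.values[0] > 0.9  # angle 0 -> +x
        mid = len(proj.values) // 2
        assert proj.values[mid] < 0.1  # angle ~pi


class TestNormalize:
    def test_two_level_equal_halves(self):
        n = 250
        angles = np.arange(n) * 2 * np.pi / n
        values = np.where(np.arange(n) < n // 2, 0.0, 2.0)
        proj = sphtex.CircularProjection(values=values, angles=angles)
        out = sphtex.normalize(proj)
        np.testing.assert_allclose(out.values, np.where(values == 0, -1.0, 1.0))
        assert out.normalized

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_weighted_moments_after_normalize(self, seed):
        cube = smooth_cube(seed, side=32)
        proj = sphtex.normalize(sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON))
        assert abs(proj.weighted_mean()) < 1e-9
        assert abs(proj.weighted_var() - 1.0) < 1e-9

    def test_plain_statistics_switch(self):
        cube = smooth_cube(4, side=32)
        proj = sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON)
        out = sphtex.normalize(proj, weighted=False)
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.var() - 1.0) < 1e-9

    def test_constant_projection_zero_variance(self):
        cube = disk_cube(side=40)
        proj = sphtex.circular_project(cube, n=64)
        with pytest.raises(ZeroVarianceError):
            sphtex.normalize(proj)

    def test_double_normalize_rejected(self):
        cube = smooth_cube(5, side=32)
        proj = sphtex.normalize(sphtex.spherical_project(cube, SMALL_NLAT, SMALL_NLON))
        with pytest.raises(ValueError, match="already"):
            sphtex.normalize(proj)
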