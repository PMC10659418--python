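"""Fiber segmentation, orientation geometry and directional variance."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abersim import orient3d as R


def _line_volume(direction, n=17, value=100.0):
    """Volume with a discretized line through the center voxel."""
    vol = np.zeros((n, n, n))
    c = n // 2
    d = np.asarray(direction, dtype=float)
    d /= np.abs(d).max()
    for t in range(-(n // 2), n // 2 + 1):
        z, y, x = (np.round(c + t * d[::-1])).astype(int)  # d is (x, y, z)
        if 0 <= z < n and 0 <= y < n and 0 <= x < n:
            vol[z, y, x] = value
    return vol


class TestSegmentation:
    def test_bimodal_image(self):
        img = np.zeros((16, 16, 16))
        img[4:8, 4:8, 4:8] = 100.0
        mask = R.segment_fibers(img)
        assert np.array_equal(mask, img == 100.0)

    def test_six_levels_use_five_thresholds(self):
        from skimage.filters import threshold_multiotsu
        rng = np.random.default_rng(1)
        img = rng.normal(size=(32, 32, 32)) + \
            5 * (rng.uniform(size=(32, 32, 32)) > 0.7)
        th = threshold_multiotsu(img, classes=6)
        assert len(th) == 5
        assert np.all(np.diff(th) > 0)
        mask = R.segment_fibers(img, levels=6)
        assert mask.sum() < img.size

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            R.segment_fibers(np.full((8, 8, 8), 3.0))


class TestLocalOrientation:
    def test_line_along_x(self):
        vol = _line_volume((1, 0, 0))
        mask = vol > 0
        c = vol.shape[0] // 2
        o = R.local_orientation(vol, mask, (c, c, c), R.WindowConfig(n=7))
        assert o.valid
        assert o.theta_deg == pytest.approx(0.0, abs=1e-9)
        assert o.phi_deg == pytest.approx(90.0, abs=1e-9)

    def test_diagonal_line_angles_and_identity(self):
        vol = _line_volume((1, 1, 1))
        mask = vol > 0
        c = vol.shape[0] // 2
        o = R.local_orientation(vol, mask, (c, c, c), R.WindowConfig(n=9))
        assert o.theta_deg == pytest.approx(45.0, abs=1e-6)
        assert o.beta_deg == pytest.approx(45.0, abs=1e-6)
        assert o.gamma_deg == pytest.approx(135.0, abs=1e-6)
        assert o.phi_deg == pytest.approx(
            math.degrees(math.acos(1 / math.sqrt(3))), abs=1e-6)
        t2phi = math.tan(math.radians(o.phi_deg)) ** 2
        assert t2phi == pytest.approx(2.0, abs=1e-9)

    def test_isolated_voxel_invalid(self):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 10.0
        o = R.local_orientation(vol, vol > 0, (4, 4, 4), R.WindowConfig(n=5))
        assert not o.valid

    def test_center_outside_mask_rejected(self):
        vol = _line_volume((1, 0, 0))
        with pytest.raises(ValueError):
            R.local_orientation(vol, vol > 0, (0, 0, 0))


class TestOrientationField:
    def test_parallel_lines_give_constant_theta(self):
        vol = np.zeros((9, 15, 15))
        vol[4, 3, 1:14] = 100.0
        vol[4, 7, 1:14] = 100.0
        vol[4, 11, 1:14] = 100.0
        field = R.orientation_field(vol, R.WindowConfig(n=5),
                                    mask=vol > 50)
        thetas = field.theta[field.valid]
        assert thetas.size > 0
        # interior of each line is oriented along +x
        assert np.nanmedian(thetas) == pytest.approx(0.0, abs=5.0)

    def test_empty_mask_gives_empty_field(self):
        vol = np.zeros((8, 8, 8))
        field = R.orientation_field(vol, mask=np.zeros((8, 8, 8), bool))
        assert field.valid.sum() == 0

    def test_in_plane_rotation_shifts_theta(self):
        vol_x = np.zeros((7, 21, 21))
        vol_x[3, 10, 2:19] = 100.0
        vol_y = np.transpose(vol_x, (0, 2, 1)).copy()  # rotate 90 deg in xy
        cfg = R.WindowConfig(n=5)
        f_x = R.orientation_field(vol_x, cfg, mask=vol_x > 50)
        f_y = R.orientation_field(vol_y, cfg, mask=vol_y > 50)
        tx = np.nanmedian(f_x.theta[f_x.valid])
        ty = np.nanmedian(f_y.theta[f_y.valid])
        assert (ty - tx) % 180.0 == pytest.approx(90.0, abs=5.0)


class TestDirectionalVariance:
    def test_parallel_field_is_zero(self):
        th, b, g, ph = R.angles_from_vector((0.3, 0.5, 0.8))
        s = R.directional_variance_from_angles(
            np.full(500, th), np.full(500, b), np.full(500, g),
            np.full(500, ph))
        assert s.dv == 0.0
        assert s.k == 500

    def test_single_voxel_is_zero(self):
        th, b, g, ph = R.angles_from_vector((1.0, 2.0, 3.0))
        s = R.directional_variance_from_angles([th], [b], [g], [ph])
        assert s.dv == 0.0

    def test_uniform_orientations_approach_one(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        a = R.angles_from_vectors(v)
        s = R.directional_variance_from_angles(a[:, 0], a[:, 1], a[:, 2],
                                               a[:, 3])
        assert s.dv > 0.8

    def test_dv_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = rng.normal(size=(50, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            a = R.angles_from_vectors(v)
            s = R.directional_variance_from_angles(a[:, 0], a[:, 1],
                                                   a[:, 2], a[:, 3])
            assert 0.0 <= s.dv <= 1.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_projection_identity_random_directions(self, seed):
        """tan^2(phi) = 1/tan^2(beta) + 1/tan^2(gamma) off the degenerate set."""
        rng = np.random.default_rng(seed)
        v = rng.normal(size=3)
        if np.any(np.abs(v) < 1e-3) or np.linalg.norm(v) < 1e-3:
            return
        th, b, g, ph = R.angles_from_vector(v)
        lhs = math.tan(math.radians(ph)) ** 2
        rhs = (1.0 / math.tan(math.radians(b)) ** 2
               + 1.0 / math.tan(math.radians(g)) ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-6, abs=1e-6)

    def test_empty_region_rejected(self):
        field = R.OrientationField(
            mask=np.zeros((4, 4, 4), bool), theta=np.full((4, 4, 4), np.nan),
            beta=np.full((4, 4, 4), np.nan), gamma=np.full((4, 4, 4), np.nan),
            phi=np.full((4, 4, 4), np.nan), valid=np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError):
            R.directional_variance(field)


class TestOrientationHistogram:
    def test_single_orientation_single_bin(self):
        thetas = np.full(200, 30.0)
        counts, edges, fwhm = R.orientation_histogram(thetas, bin_deg=5.0)
        assert (counts > 0).sum() == 1
        assert fwhm <= 5.0 + 1e-9
        assert counts.sum() == 200

    def test_uniform_theta_is_flat(self):
        rng = np.random.default_rng(4)
        thetas = rng.uniform(0, 180, size=100_000)
        counts, _, _ = R.orientation_histogram(thetas, bin_deg=10.0)
        expected = 100_000 / 18
        assert np.all(np.abs(counts - expected) < 5 * np.sqrt(expected))

    def test_mass_conservation_from_field(self):
        vol = _line_volume((1, 0, 0))
        field = R.orientation_field(vol, R.WindowConfig(n=5), mask=vol > 50)
        counts, _, _ = R.orientation_histogram(field, bin_deg=5.0)
        assert counts.sum() == field.valid.sum()
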