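"""Wedge filters, the cubic rotation group, and Fourier merging."""

import numpy as np
import pytest

from isotomo import geometry
from isotomo.geometry import (Rotation, WedgeSpec, apply_fourier_filter,
                              cube_rotations, fourier_merge, inverse_wedge_filter,
                              rotate_volume, training_rotations, wedge_filter)


class TestWedgeFilter:
    def test_equatorial_axis_sampled_polar_axis_missing(self):
        f = wedge_filter((16, 16, 16)).data
        assert f[0, 0, 1] == 1.0   # pure kx: in the tilt fan
        assert f[1, 0, 0] == 0.0   # pure kz: inside the wedge for +-60
        assert f[0, 0, 0] == 1.0   # DC is measured

    def test_independent_of_ky(self):
        f = wedge_filter((12, 12, 12)).data
        assert (f == f[:, :1, :]).all()

    def test_zero_fraction_matches_brute_force_count(self):
        shape = (64, 64, 64)
        f = wedge_filter(shape).data
        # independent oracle: direct angular test voxel by voxel
        kz = np.fft.fftfreq(64)
        kx = np.fft.fftfreq(64)
        KZ, KX = np.meshgrid(kz, kx, indexing="ij")
        ang = np.degrees(np.arctan2(np.abs(KZ), np.abs(KX)))
        missing_plane = ang > 60.0
        missing_plane[0, 0] = False
        expected_zero_fraction = missing_plane.mean()
        assert np.isclose(1.0 - f.mean(), expected_zero_fraction, atol=1e-6)
        # the analytic angular fraction of the fan is 1/3; the square grid
        # weights angles non-uniformly, so allow a discretization margin
        assert abs((1.0 - f.mean()) - 1.0 / 3.0) < 0.05

    def test_asymmetric_range(self):
        f = wedge_filter((16, 16, 16), WedgeSpec(-48, 66)).data
        # a direction at +60 deg is sampled, at -60 it is not
        assert f.sum() != wedge_filter((16, 16, 16)).data.sum()

    def test_inverse_is_complement_except_dc(self):
        w = WedgeSpec()
        f = wedge_filter((20, 20, 20), w).data
        inv = inverse_wedge_filter((20, 20, 20), w).data
        total = f + inv
        assert total[0, 0, 0] == 1.0  # DC: 1 in wedge filter, 0 in inverse
        assert (total.ravel()[1:] == 1.0).all()

    def test_inverse_zero_on_equator(self):
        inv = inverse_wedge_filter((16, 16, 16)).data
        assert inv[0, 0, 1] == 0.0

    def test_zero_count_complement(self):
        f = wedge_filter((32, 32, 32)).data
        inv = inverse_wedge_filter((32, 32, 32)).data
        # every voxel is 0 in exactly one of the two (DC: 1 in wedge, 0 in inverse)
        assert (f == 0).sum() + (inv == 0).sum() == f.size


class TestApplyFourierFilter:
    def test_all_ones_is_identity(self, random_volume):
        filt = geometry.FourierFilter(np.ones_like(random_volume))
        out = apply_fourier_filter(random_volume, filt)
        np.testing.assert_allclose(out, random_volume, atol=1e-5)

    def test_idempotent_for_binary_filter(self, random_volume):
        filt = wedge_filter(random_volume.shape)
        once = apply_fourier_filter(random_volume, filt)
        twice = apply_fourier_filter(once, filt)
        np.testing.assert_allclose(once, twice, atol=1e-4)

    def test_parseval_passband_power(self, random_volume):
        filt = wedge_filter(random_volume.shape)
        out = apply_fourier_filter(random_volume, filt)
        spec = np.abs(np.fft.fftn(random_volume)) ** 2
        expected = spec[filt.data > 0].sum() / random_volume.size
        assert np.isclose((out.astype(np.float64) ** 2).sum(), expected, rtol=1e-4)

    def test_shape_mismatch_raises(self, random_volume):
        with pytest.raises(ValueError):
            apply_fourier_filter(random_volume, wedge_filter((8, 8, 8)))


class TestCubeRotations:
    def test_twenty_four_distinct_proper_rotations(self):
        rots = cube_rotations()
        assert len(rots) == 24
        assert len(set(rots)) == 24
        for r in rots:
            assert round(np.linalg.det(r.matrix)) == 1

    def test_closed_under_composition(self):
        rots = cube_rotations()
        members = set(rots)
        for a in rots:
            for b in rots:
                assert Rotation(a.matrix @ b.matrix) in members

    def test_contains_identity(self):
        assert Rotation(np.eye(3, dtype=int)) in set(cube_rotations())


class TestTrainingRotations:
    def test_twenty_remain_four_excluded(self):
        tr = training_rotations()
        assert len(tr) == 20
        excluded = set(cube_rotations()) - set(tr)
        assert len(excluded) == 4

    def test_excluded_are_identity_and_axis_flips(self):
        excluded = set(cube_rotations()) - set(training_rotations())
        expected = {
            Rotation(np.diag([1, 1, 1])),
            Rotation(np.diag([1, -1, -1])),    # 180 about X
            Rotation(np.diag([-1, 1, -1])),    # 180 about Y
            Rotation(np.diag([-1, -1, 1])),    # 180 about Z
        }
        assert excluded == expected

    def test_every_training_rotation_moves_the_wedge(self):
        # brute force on a small centered grid for all 24 rotations
        w = WedgeSpec()
        for r in training_rotations(w):
            assert not geometry._preserves_wedge(r, w, n=9)

    def test_union_with_excluded_reconstitutes_group(self):
        tr = set(training_rotations())
        excluded = set(cube_rotations()) - tr
        assert tr | excluded == set(cube_rotations())


class TestRotateVolume:
    def test_identity(self, random_volume):
        r = Rotation(np.eye(3, dtype=int))
        np.testing.assert_array_equal(rotate_volume(random_volume, r),
                                      random_volume)

    def test_group_action_homomorphism(self, random_volume):
        rots = cube_rotations()
        for a, b in [(rots[3], rots[11]), (rots[7], rots[19])]:
            lhs = rotate_volume(random_volume, a @ b)
            rhs = rotate_volume(rotate_volume(random_volume, b), a)
            np.testing.assert_array_equal(lhs, rhs)

    def test_inverse_round_trip_bit_exact(self, random_volume):
        for r in cube_rotations():
            back = rotate_volume(rotate_volume(random_volume, r), r.inverse)
            np.testing.assert_array_equal(back, random_volume)

    def test_four_inplane_z_rotations_cycle(self, random_volume):
        z90 = Rotation(np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]]))
        v = random_volume
        for _ in range(4):
            v = rotate_volume(v, z90)
        np.testing.assert_array_equal(v, random_volume)

    def test_voxel_sum_invariant(self, random_volume):
        s = random_volume.sum(dtype=np.float64)
        for r in cube_rotations():
            assert np.isclose(rotate_volume(random_volume, r).sum(dtype=np.float64), s)

    def test_non_cubic_rejects_axis_swapping(self):
        v = np.zeros((4, 6, 8), dtype=np.float32)
        swap = Rotation(np.array([[0, 0, 1], [0, 1, 0], [-1, 0, 0]]))
        with pytest.raises(ValueError):
            rotate_volume(v, swap)


class TestFourierMerge:
    def test_zero_prediction_returns_original(self, random_volume):
        out = fourier_merge(random_volume, np.zeros_like(random_volume))
        np.testing.assert_allclose(out, random_volume, atol=1e-5)

    def test_ground_truth_self_consistency(self, random_volume):
        w = WedgeSpec()
        filtered = apply_fourier_filter(random_volume,
                                        wedge_filter(random_volume.shape, w))
        restored = fourier_merge(filtered, random_volume, w)
        np.testing.assert_allclose(restored, random_volume, atol=1e-4)

    def test_sampled_region_never_modified(self, random_volume, rng):
        w = WedgeSpec()
        predicted = rng.standard_normal(random_volume.shape).astype(np.float32)
        merged = fourier_merge(random_volume, predicted, w)
        sampled = wedge_filter(random_volume.shape, w).data.astype(bool)
        fo = np.fft.fftn(random_volume)[sampled]
        fm = np.fft.fftn(merged)[sampled]
        assert np.abs(fm - fo).max() / np.abs(fo).mean() < 1e-4

    def test_merge_idempotent_for_wedge_empty_original(self, random_volume, rng):
        # measured data has nothing in the wedge; merging is then idempotent
        w = WedgeSpec()
        original = apply_fourier_filter(random_volume,
                                        wedge_filter(random_volume.shape, w))
        predicted = rng.standard_normal(random_volume.shape).astype(np.float32)
        merged = fourier_merge(original, predicted, w)
        again = fourier_merge(original, merged, w)
        np.testing.assert_allclose(again, merged, atol=1e-4)


def test_wedge_spec_validates_range():
    with pytest.raises(ValueError):
        WedgeSpec(60, -60)
    with pytest.raises(ValueError):
        WedgeSpec(-95, 60)
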