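import numpy as np
import pytest
from scipy import ndimage

from larvreg.model import Grid, VolumetricImage
from larvreg.preprocess import (
    NoNeuropilSignalError,
    coarse_brain_mask,
    histogram_match,
    orient_dorsal_ventral,
    robust_rescale,
    signed_distance_transform,
    threshold_brain_mask,
    z_flip_candidates,
)


def _dice(a, b):
    a, b = a > 0, b > 0
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestHistogramMatch:
    def test_self_match_is_identity(self, small_image):
        out = histogram_match(small_image, small_image)
        assert np.array_equal(out.data, small_image.data)

    def test_halved_image_median_restored(self, rng):
        fixed = VolumetricImage(
            rng.integers(10, 240, size=(20, 20, 10)).astype(np.uint8), (1, 1, 1)
        )
        moving = fixed.copy(data=(fixed.data * 0.5).astype(np.uint8))
        matched = histogram_match(moving, fixed)
        assert abs(np.median(matched.data) - np.median(fixed.data)) <= 1.0

    def test_mapping_monotone_over_all_levels(self, rng):
        fixed = VolumetricImage(
            rng.integers(0, 255, size=(16, 16, 8)).astype(np.uint8), (1, 1, 1)
        )
        levels = np.tile(np.arange(256, dtype=np.uint8), 8)
        moving = VolumetricImage(levels.reshape(16, 16, 8), (1, 1, 1))
        matched = histogram_match(moving, fixed)
        lut = matched.data.ravel().astype(float)
        order = np.argsort(moving.data.ravel(), kind="stable")
        assert np.all(np.diff(lut[order]) >= 0)

    def test_constant_image_warns(self, small_image):
        const = small_image.copy(data=np.full_like(small_image.data, 7))
        with pytest.warns(UserWarning, match="constant"):
            out = histogram_match(const, small_image)
        assert np.array_equal(out.data, const.data)


class TestRobustRescale:
    def test_constant_image_is_zero(self, small_image):
        const = small_image.copy(data=np.full_like(small_image.data, 9))
        with pytest.warns(UserWarning):
            out = robust_rescale(const)
        assert np.all(out.data == 0)

    def test_saturated_outliers_clipped(self, rng):
        data = rng.uniform(20, 60, size=(20, 20, 10))
        flat = data.ravel()
        flat[rng.choice(flat.size, flat.size // 100, replace=False)] = 255.0
        img = VolumetricImage(data, (1, 1, 1))
        out = robust_rescale(img)
        assert np.isclose(out.data.max(), 1.0)
        body = out.data[img.data < 100]
        assert 0.0 <= body.min() and body.max() < 1.0
        # percentile oracle: the 99.8th percentile maps to 1.0
        hi = np.percentile(img.data, 99.8)
        lo = np.percentile(img.data, 1.0)
        expect = np.clip((50.0 - lo) / (hi - lo), 0, 1)
        got = out.data[np.isclose(img.data, 50.0, atol=0.5)].mean()
        assert abs(got - expect) < 0.02

    def test_range_always_unit_interval(self, small_image):
        out = robust_rescale(small_image)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0


class TestCoarseBrainMask:
    def test_speck_removed_ellipsoid_kept(self):
        shape = (64, 48, 16)
        grid = Grid(shape, (0.5, 0.5, 2.0))
        p = grid.physical_points()
        ellipsoid = (
            ((p[..., 0] - 16) / 10) ** 2
            + ((p[..., 1] - 12) / 8) ** 2
            + ((p[..., 2] - 16) / 10) ** 2
        ) <= 1
        data = np.where(ellipsoid, 200.0, 5.0)
        data[2:4, 2:4, 2] = 220.0  # 3-voxel-scale speck far from the body
        img = VolumetricImage(data, (0.5, 0.5, 2.0))
        mask = coarse_brain_mask(img)
        # connected-component oracle
        labels, n = ndimage.label(mask.data)
        assert n == 1
        assert mask.data[2:4, 2:4, 2].sum() == 0
        assert _dice(mask.data, ellipsoid) > 0.8

    def test_all_zero_image_raises(self):
        img = VolumetricImage(np.zeros((32, 32, 8)), (0.5, 0.5, 2.0))
        with pytest.raises(NoNeuropilSignalError, match="no neuropil"):
            coarse_brain_mask(img)

    def test_threshold_mask_agrees_on_clean_phantom(self, rigid_phantom):
        np_img = rigid_phantom.scan.np
        opened = coarse_brain_mask(np_img)
        thresholded = threshold_brain_mask(np_img)
        assert _dice(opened.data, thresholded.data) >= 0.95

    def test_salt_noise_invariance(self, rigid_phantom, rng):
        np_img = rigid_phantom.scan.np
        clean = coarse_brain_mask(np_img)
        noisy_data = np_img.data.copy()
        n_salt = int(noisy_data.size * 0.001)
        flat = rng.choice(noisy_data.size, n_salt, replace=False)
        noisy_data.ravel()[flat] = 255
        noisy = coarse_brain_mask(np_img.copy(data=noisy_data))
        assert _dice(clean.data, noisy.data) >= 0.99


class TestSignedDistanceTransform:
    def test_sphere_center_value(self):
        grid = Grid((40, 40, 20), (0.5, 0.5, 1.0))
        p = grid.physical_points()
        center = np.array([10.0, 10.0, 9.0])
        r = 6.0
        mask = VolumetricImage(
            (np.sum((p - center) ** 2, axis=-1) <= r**2).astype(np.uint8),
            (0.5, 0.5, 1.0), channel_label="mask",
        )
        sdt = signed_distance_transform(mask)
        ci = np.rint(grid.physical_to_index(center)).astype(int)
        assert abs(sdt.data[tuple(ci)] + r) <= 1.0  # -r within one voxel

    def test_boundary_magnitude_small(self):
        mask = VolumetricImage(np.zeros((12, 12, 12), dtype=np.uint8), (0.5, 0.5, 2.0))
        mask.data[4:8, 4:8, 4:8] = 1
        sdt = signed_distance_transform(mask)
        half_diag = 0.5 * np.linalg.norm(mask.spacing)
        boundary = mask.data.astype(bool) & ~ndimage.binary_erosion(mask.data.astype(bool))
        assert np.all(np.abs(sdt.data[boundary]) <= half_diag + 1e-9)

    def test_brute_force_oracle_11cubed(self, rng):
        spacing = np.array([0.5, 0.5, 2.0])
        mask_arr = rng.uniform(size=(11, 11, 11)) > 0.7
        mask_arr[5, 5, 5] = True  # guarantee both phases
        mask_arr[0, 0, 0] = False
        img = VolumetricImage(mask_arr.astype(np.uint8), tuple(spacing),
                              channel_label="mask")
        sdt = signed_distance_transform(img)
        pts = Grid((11, 11, 11), tuple(spacing)).physical_points().reshape(-1, 3)
        inside = mask_arr.ravel()
        d_in = np.array([
            np.min(np.linalg.norm(pts[~inside] - q, axis=1)) for q in pts[inside]
        ])
        d_out = np.array([
            np.min(np.linalg.norm(pts[inside] - q, axis=1)) for q in pts[~inside]
        ])
        brute = np.empty(len(pts))
        brute[inside] = -d_in
        brute[~inside] = d_out
        assert np.max(np.abs(sdt.data.ravel() - brute)) < 1e-6

    def test_eikonal_property_interior(self, rigid_phantom):
        mask = coarse_brain_mask(rigid_phantom.scan.np)
        sdt = signed_distance_transform(mask)
        gx, gy, gz = np.gradient(sdt.data.astype(float), *sdt.spacing)
        gmag = np.sqrt(gx**2 + gy**2 + gz**2)
        interior = ndimage.binary_erosion(mask.data.astype(bool), iterations=3)
        assert np.median(np.abs(gmag[interior] - 1.0)) < 0.1


class TestOrientation:
    def _blob_image(self, y_frac):
        grid = Grid((32, 48, 8), (1.0, 1.0, 2.0))
        p = grid.physical_points()
        c = np.array([15.5, y_frac * 47.0, 7.0])
        data = np.exp(-np.sum((p - c) ** 2, axis=-1) / 50.0)
        return VolumetricImage(data, (1.0, 1.0, 2.0))

    def test_top_half_mass_only_translates(self):
        img = self._blob_image(0.25)
        aligned, t = orient_dorsal_ventral(img, img.grid)
        com = ndimage.center_of_mass(aligned.data)
        assert np.allclose(
            aligned.index_to_physical(np.asarray(com)), img.grid.center, atol=1.5
        )
        from larvreg.transforms import LinearTransform
        assert isinstance(t, LinearTransform)  # no flip member

    def test_bottom_half_mass_flips(self):
        img = self._blob_image(0.75)
        aligned, t = orient_dorsal_ventral(img, img.grid)
        from larvreg.transforms import CompositeTransform
        assert isinstance(t, CompositeTransform)  # flip + translation
        com = ndimage.center_of_mass(aligned.data)
        assert np.allclose(
            aligned.index_to_physical(np.asarray(com)), img.grid.center, atol=1.5
        )

    def test_idempotent(self):
        img = self._blob_image(0.75)
        aligned, _ = orient_dorsal_ventral(img, img.grid)
        again, t2 = orient_dorsal_ventral(aligned, img.grid)
        from larvreg.transforms import LinearTransform
        assert isinstance(t2, LinearTransform)  # second call: no flip
        assert np.linalg.norm(t2.translation) < 1.5


class TestZFlip:
    def test_two_candidates_flip_twice_is_identity(self, small_image):
        candidates = z_flip_candidates(small_image)
        assert len(candidates) == 2
        flipped, t = candidates[1]
        back = z_flip_candidates(flipped)[1][0]
        assert np.array_equal(back.data, small_image.data)

    def test_symmetric_phantom_candidates_identical(self):
        data = np.zeros((8, 8, 9))
        data[3:5, 3:5, :] = np.arange(9)[None, None, :]
        data[..., :] = data[..., ::-1] + data  # symmetrize
        img = VolumetricImage(data, (1, 1, 1))
        a, b = z_flip_candidates(img)
        assert np.array_equal(a[0].data, b[0].data)

    def test_flip_transform_maps_z(self):
        # 200 μm-deep stack: landmark at z=10 μm maps to z=190 μm
        img = VolumetricImage(np.zeros((4, 4, 101)), (1.0, 1.0, 2.0))
        _, t = z_flip_candidates(img)[1]
        mapped = t.apply(np.array([2.0, 2.0, 10.0]))
        assert np.allclose(mapped, (2.0, 2.0, 190.0))
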