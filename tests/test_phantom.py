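"""Phantom generator, noise injection, and minority augmentation."""

import dataclasses

import numpy as np
import pytest

from pfb.errors import BalanceError, ParameterError, UndefinedMetricError
from pfb.image import Dataset, PfbImage
from pfb.phantom import (PROTOCOLS, PhantomSpec, add_gaussian_noise,
                         augment_minority, generate_dataset, generate_phantom)


def brute_force_circle_fit(points):
    """Least-squares circle (Kasa fit) through a point cloud: (cy, cx, r)."""
    y, x = points[:, 0].astype(float), points[:, 1].astype(float)
    A = np.column_stack([2 * y, 2 * x, np.ones(len(y))])
    b = y**2 + x**2
    (cy, cx, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    return cy, cx, np.sqrt(c + cy**2 + cx**2)


class TestGeneratePhantom:
    def test_noiseless_image_has_exactly_two_values(self):
        spec = PhantomSpec(salt_pepper_fraction=0.0, bone_intensity_sd=0.0,
                           protocol_gain=1.2)
        img, _ = generate_phantom(spec)
        assert set(np.unique(img.pixels)) == {1.2 * 30.0, 1.2 * 150.0}

    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(rng_seed=9)
        img1, m1 = generate_phantom(spec)
        img2, m2 = generate_phantom(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(m1.mask, m2.mask)

    def test_head_radius_recovered_by_circle_fit(self):
        """Brute-force circle fit to the head boundary arc recovers the radius."""
        spec = PhantomSpec(head_radius_px=20.0, neck_width_px=14.0, rng_seed=4,
                           salt_pepper_fraction=0.0, bone_intensity_sd=0.0)
        _, segmask = generate_phantom(spec)
        from pfb.phantom import phantom_mask_geometry
        _, head_center, _ = phantom_mask_geometry(spec)
        boundary = segmask.boundary[:-1]
        d = np.hypot(boundary[:, 0] - head_center[0], boundary[:, 1] - head_center[1])
        arc = boundary[np.abs(d - 20.0) < 3.0]  # head portion of the outline
        _, _, r = brute_force_circle_fit(arc)
        assert abs(r - 20.0) <= 1.0

    def test_right_side_is_mirror_of_left(self):
        left = PhantomSpec(rng_seed=5, side="left")
        right = dataclasses.replace(left, side="right")
        img_l, m_l = generate_phantom(left)
        img_r, m_r = generate_phantom(right)
        assert np.array_equal(img_r.pixels, img_l.pixels[:, ::-1])
        assert np.array_equal(m_r.mask, m_l.mask[:, ::-1])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            PhantomSpec(head_radius_px=5.0, neck_width_px=14.0)
        with pytest.raises(ParameterError):
            PhantomSpec(salt_pepper_fraction=1.5)

    def test_mask_single_component_and_filled(self):
        _, m = generate_phantom(PhantomSpec(rng_seed=11))
        from scipy import ndimage as ndi
        _, n = ndi.label(m.mask)
        assert n == 1
        assert np.array_equal(ndi.binary_fill_holes(m.mask), m.mask)


class TestGenerateDataset:
    def test_balanced_with_masks_and_unique_ids(self):
        ds = generate_dataset(5, separation=1.0, seed=3, size=96)
        assert len(ds) == 10
        assert np.bincount(ds.labels()).tolist() == [5, 5]
        assert all(m is not None for m in ds.masks)

    def test_protocol_table_totals(self):
        assert sum(p["referred"] for p in PROTOCOLS) == 284
        assert sum(p["healthy"] for p in PROTOCOLS) == 185
        assert sum(p["unhealthy"] for p in PROTOCOLS) == 99


class TestGaussianNoise:
    def test_vanishing_noise_limit(self, noisy_phantom):
        _, img, _ = noisy_phantom
        noisy = add_gaussian_noise(img, 60.0, rng_seed=1)
        rms = np.sqrt(np.mean(img.pixels**2))
        dev = np.sqrt(np.mean((noisy.pixels - img.pixels) ** 2))
        assert dev < 0.002 * rms

    @pytest.mark.parametrize("snr_db", [-4.0, 0.0, 10.0, 20.0])
    def test_noise_calibration(self, noisy_phantom, snr_db):
        """Realized SNR of the injected field within 0.5 dB of the request."""
        _, img, _ = noisy_phantom
        noisy = add_gaussian_noise(img, snr_db, rng_seed=7, clip=False)
        p_sig = np.mean(img.pixels**2)
        p_noise = np.mean((noisy - img.pixels) ** 2)
        assert abs(10 * np.log10(p_sig / p_noise) - snr_db) < 0.5

    def test_variance_matches_definition_at_0db(self, noisy_phantom):
        _, img, _ = noisy_phantom
        noisy = add_gaussian_noise(img, 0.0, rng_seed=3, clip=False)
        p_sig = np.mean(img.pixels**2)
        p_noise = np.mean((noisy - img.pixels) ** 2)
        assert abs(p_noise - p_sig) < 0.05 * p_sig

    def test_different_seeds_different_fields(self, noisy_phantom):
        _, img, _ = noisy_phantom
        a = add_gaussian_noise(img, 10.0, rng_seed=1)
        b = add_gaussian_noise(img, 10.0, rng_seed=2)
        assert not np.array_equal(a.pixels, b.pixels)

    def test_constant_image_rejected(self):
        flat = PfbImage(pixels=np.full((64, 64), 5.0))
        with pytest.raises(UndefinedMetricError):
            add_gaussian_noise(flat, 10.0, rng_seed=0)


def _tiny_dataset(n_healthy, n_unhealthy, seed=0):
    rng = np.random.default_rng(seed)
    images = []
    for i in range(n_healthy + n_unhealthy):
        label = 0 if i < n_healthy else 1
        pixels = np.clip(rng.normal(100, 10, (48, 48)), 0, None)
        images.append(PfbImage(pixels=pixels, label=label, subject_id=f"s{i}"))
    return Dataset(images=images)


class TestAugmentMinority:
    def test_cohort_counts_balanced(self):
        """The 185/99 class split balances to 185/185."""
        ds = _tiny_dataset(185, 99)
        out = augment_minority(ds, rng_seed=1)
        counts = np.bincount(out.labels())
        assert counts.tolist() == [185, 185]

    def test_already_balanced_is_noop(self):
        ds = _tiny_dataset(4, 4)
        assert augment_minority(ds, rng_seed=0) is ds

    def test_deficit_arithmetic_and_labels(self):
        out = augment_minority(_tiny_dataset(10, 3), rng_seed=2)
        assert len(out) == 20
        added = out.images[13:]
        assert len(added) == 7
        assert all(im.label == 1 for im in added)

    def test_originals_untouched(self):
        ds = _tiny_dataset(6, 2, seed=5)
        before = [im.pixels.copy() for im in ds.images]
        out = augment_minority(ds, rng_seed=3)
        for orig, after in zip(before, out.images[:8]):
            assert np.array_equal(orig, after.pixels)

    def test_single_class_rejected(self):
        with pytest.raises(BalanceError):
            augment_minority(_tiny_dataset(5, 0), rng_seed=0)
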