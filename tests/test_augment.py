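"""Augmentation chain invariants."""

import numpy as np
import pytest

from mfiseg import (
    AugmentationConfig,
    augment_dataset,
    elastic_deform,
    fit_landmarks,
    histogram_standardize,
    mirror_lr,
    normalize_labels,
    random_affine,
)
from mfiseg.augment import apply_affine, denormalize_labels
from mfiseg.dixon import SegmentationMask
from mfiseg.labels import MuscleGroup, MuscleLabelScheme


class TestMirrorLR:
    def test_double_application_is_identity(self, noiseless_phantom, scheme12):
        dix, mask, _ = noiseless_phantom
        images = [dix.fat, dix.water]
        once_imgs, once_mask = mirror_lr(images, mask, scheme12)
        twice_imgs, twice_mask = mirror_lr(once_imgs, once_mask, scheme12)
        assert np.array_equal(twice_mask.labels, mask.labels)
        for a, b in zip(twice_imgs, images):
            assert np.array_equal(a, b)

    def test_left_label_maps_to_right_label(self, scheme12):
        # MFSS is labelled left=2 / right=1
        labels = np.zeros((4, 3, 2), dtype=np.int16)
        labels[0, 1, 1] = 2
        _, mirrored = mirror_lr([np.zeros((4, 3, 2))], SegmentationMask(labels, (1, 1, 1)), scheme12)
        assert mirrored.labels[3, 1, 1] == 1
        assert (mirrored.labels == 2).sum() == 0

    def test_volume_multiset_preserved_per_group(self, noiseless_phantom, scheme12):
        _, mask, _ = noiseless_phantom
        _, mirrored = mirror_lr([mask.labels.astype(float)], mask, scheme12)
        for g in scheme12:
            before = {int((mask.labels == g.left_label).sum()),
                      int((mask.labels == g.right_label).sum())}
            after = {int((mirrored.labels == g.left_label).sum()),
                     int((mirrored.labels == g.right_label).sum())}
            assert before == after

    def test_unpaired_label_rejected(self, scheme12):
        labels = np.zeros((4, 3, 2), dtype=np.int16)
        labels[0, 0, 0] = 77
        with pytest.raises(ValueError, match="77"):
            mirror_lr([np.zeros((4, 3, 2))], SegmentationMask(labels, (1, 1, 1)), scheme12)


class TestElasticDeform:
    def test_zero_sigma_is_identity(self, noiseless_phantom):
        dix, mask, _ = noiseless_phantom
        (img,), out = elastic_deform([dix.fat], mask, control_points=3, sigma=0.0, seed=1)
        assert np.array_equal(img, dix.fat)
        assert np.array_equal(out.labels, mask.labels)

    def test_label_set_shrinks_or_stays(self, noiseless_phantom):
        _, mask, _ = noiseless_phantom
        _, out = elastic_deform([mask.labels.astype(float)], mask, 3, 8.0, seed=4)
        assert set(np.unique(out.labels)) <= set(np.unique(mask.labels))

    def test_seed_contract(self, noiseless_phantom):
        dix, mask, _ = noiseless_phantom
        (a,), am = elastic_deform([dix.fat], mask, 3, 6.0, seed=11)
        (b,), bm = elastic_deform([dix.fat], mask, 3, 6.0, seed=11)
        (c,), cm = elastic_deform([dix.fat], mask, 3, 6.0, seed=12)
        assert np.array_equal(a, b) and np.array_equal(am.labels, bm.labels)
        assert not np.array_equal(a, c)


class TestRandomAffine:
    def test_zero_ranges_identity(self, noiseless_phantom):
        dix, mask, _ = noiseless_phantom
        (img,), out, params = random_affine(
            [dix.fat], mask, scale_percent=0.0, rot_ranges_deg=(0, 0, 0), seed=3
        )
        assert np.array_equal(img, dix.fat)
        assert np.array_equal(out.labels, mask.labels)
        assert params["scales"] == (1.0, 1.0, 1.0)

    def test_pure_axis_scaling_tracks_analytic_volume(self):
        cube = np.zeros((100, 100, 8), dtype=np.int16)
        cube[10:90, 10:90, 1:7] = 1
        mask = SegmentationMask(cube, (1, 1, 1))
        scale = 1.05
        _, out = apply_affine([cube.astype(float)], mask, scales=(scale, 1.0, 1.0))
        ratio = (out.labels == 1).sum() / (cube == 1).sum()
        assert ratio == pytest.approx(scale, abs=0.02)

    def test_rotation_preserves_volume_of_interior_blob(self):
        grid = np.zeros((60, 60, 12), dtype=np.int16)
        grid[20:40, 20:40, 3:9] = 1
        mask = SegmentationMask(grid, (1, 1, 1))
        _, out = apply_affine([grid.astype(float)], mask, angles_deg=(0, 0, 5.0))
        ratio = (out.labels == 1).sum() / (grid == 1).sum()
        assert ratio == pytest.approx(1.0, abs=0.02)


class TestAugmentDataset:
    def _tiny_dataset(self, scheme, n=10):
        rng = np.random.default_rng(0)
        out = []
        for _ in range(n):
            labels = np.zeros((8, 8, 4), dtype=np.int16)
            labels[2:4, 2:4, 1:3] = 2
            labels[5:7, 2:4, 1:3] = 1
            img = rng.normal(size=(8, 8, 4))
            out.append(([img], SegmentationMask(labels, (1, 1, 1))))
        return out

    def test_zero_samples_empty_output(self, scheme12):
        cfg = AugmentationConfig(n_augmented=0, seed=1)
        samples, prov = augment_dataset(self._tiny_dataset(scheme12), cfg, scheme12)
        assert samples == [] and prov == []

    def test_all_zero_chain_reproduces_sources(self, scheme12):
        data = self._tiny_dataset(scheme12, n=3)
        cfg = AugmentationConfig(
            mirror_prob=0.0, elastic_sigma=0.0, scale_percent=0.0,
            rot_lr_deg=0.0, rot_ap_deg=0.0, rot_si_deg=0.0, n_augmented=6, seed=2,
        )
        samples, prov = augment_dataset(data, cfg, scheme12)
        for (imgs, mask), meta in zip(samples, prov):
            src_imgs, src_mask = data[meta["source"]]
            assert np.allclose(imgs[0], src_imgs[0])
            assert np.array_equal(mask.labels, src_mask.labels)

    def test_source_usage_roughly_uniform(self, scheme12):
        data = self._tiny_dataset(scheme12, n=10)
        cfg = AugmentationConfig(
            elastic_sigma=0.0, scale_percent=0.0,
            rot_lr_deg=0.0, rot_ap_deg=0.0, rot_si_deg=0.0,
            n_augmented=600, seed=0,
        )
        _, prov = augment_dataset(data, cfg, scheme12)
        counts = np.bincount([m["source"] for m in prov], minlength=10)
        assert counts.max() / counts.min() < 2.0

    def test_provenance_replays(self, scheme12):
        data = self._tiny_dataset(scheme12, n=4)
        cfg = AugmentationConfig(n_augmented=5, seed=9)
        s1, p1 = augment_dataset(data, cfg, scheme12)
        s2, p2 = augment_dataset(data, cfg, scheme12)
        assert p1 == p2
        for (ia, ma), (ib, mb) in zip(s1, s2):
            assert np.array_equal(ma.labels, mb.labels)
            assert np.allclose(ia[0], ib[0])


class TestHistogramStandardize:
    def test_self_fit_is_identity(self, rng):
        img = rng.gamma(2.0, 10.0, (16, 16, 4))
        lm = fit_landmarks([img])
        assert np.allclose(histogram_standardize(img, lm), img, atol=1e-9)

    def test_monotone_mapping(self, rng):
        img = rng.normal(50, 10, (12, 12, 4))
        lm = fit_landmarks([rng.gamma(2.0, 10.0, (12, 12, 4))])
        out = histogram_standardize(img, lm)
        order_in = np.argsort(img.ravel(), kind="stable")
        mapped = out.ravel()[order_in]
        assert np.all(np.diff(mapped) >= -1e-12)

    def test_linear_transform_pair_maps_together(self, rng):
        a = rng.gamma(2.0, 10.0, (16, 16, 4))
        b = 2.5 * a + 7.0
        lm = fit_landmarks([a])
        sa = histogram_standardize(a, lm)
        sb = histogram_standardize(b, lm)
        assert np.abs(sa - sb).max() < 1e-8

    def test_constant_image_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            out = histogram_standardize(np.full((4, 4, 2), 3.0), np.linspace(0, 1, 11))
        assert np.all(out == 3.0)


class TestNormalizeLabels:
    def test_default_scheme_is_identity_mapping(self, noiseless_phantom, scheme12):
        _, mask, _ = noiseless_phantom
        indexed, lookup = normalize_labels(mask, scheme12)
        assert np.array_equal(indexed.labels, mask.labels)
        assert lookup == {i: i for i in range(15)}

    def test_round_trip_bit_exact(self, noiseless_phantom, scheme12):
        _, mask, _ = noiseless_phantom
        indexed, lookup = normalize_labels(mask, scheme12)
        back = denormalize_labels(indexed, lookup)
        assert np.array_equal(back.labels, mask.labels)

    def test_sparse_labels_become_contiguous(self):
        scheme = MuscleLabelScheme(
            groups=(MuscleGroup(name="only", left_label=9, right_label=5),)
        )
        labels = np.zeros((4, 4, 2), dtype=np.int16)
        labels[0] = 5
        labels[1] = 9
        indexed, lookup = normalize_labels(SegmentationMask(labels, (1, 1, 1)), scheme)
        assert set(np.unique(indexed.labels)) == {0, 1, 2}
        assert lookup == {0: 0, 1: 5, 2: 9}

    def test_unknown_label_rejected(self, scheme12):
        labels = np.zeros((4, 4, 2), dtype=np.int16)
        labels[0, 0, 0] = 50
        with pytest.raises(ValueError, match="50"):
            normalize_labels(SegmentationMask(labels, (1, 1, 1)), scheme12)
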