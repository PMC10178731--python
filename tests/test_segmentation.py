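"""Block-Otsu baseline, patch handling, dataset splits, U-net plumbing."""

import numpy as np
import pytest

from vessel3d.segmentation import (
    PatchDataset,
    SegConfig,
    SegModel,
    extract_patches,
    otsu_block_segment,
    predict_mask,
    split_dataset,
    train_unet,
)


def otsu_oracle(values):
    """Exhaustive scan of all 256 thresholds maximizing between-class variance."""
    v = values.ravel().astype(float)
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo, hi = v[v <= t], v[v > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        var = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestOtsuBlock:
    def test_bimodal_block_threshold_between_modes(self, rng):
        img = np.full((32, 32), 200, dtype=np.uint8)
        img[:, :16] = 50
        mask = otsu_block_segment(img, block_size=32, min_contrast=10)
        t = otsu_oracle(img)
        assert 50 <= t < 200
        assert np.array_equal(mask, img <= t)

    def test_matches_oracle_on_random_blocks(self, rng):
        for _ in range(50):
            img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
            mask = otsu_block_segment(img, block_size=24, min_contrast=1)
            assert np.array_equal(mask, img <= otsu_oracle(img))

    def test_constant_image_all_background(self):
        img = np.full((64, 64), 128, dtype=np.uint8)
        assert not otsu_block_segment(img, block_size=32).any()

    def test_block_otsu_beats_global_under_illumination_offset(self):
        # two halves with the same vessel/background contrast but a strong
        # illumination offset: one global threshold misclassifies a half
        img = np.full((32, 64), 220, dtype=np.uint8)
        img[8:24, 8:24] = 120  # vessel, left half
        img[:, 32:] = 100  # darker right half
        img[8:24, 40:56] = 20  # vessel, right half
        truth = np.zeros((32, 64), bool)
        truth[8:24, 8:24] = True
        truth[8:24, 40:56] = True
        blocked = otsu_block_segment(img, block_size=32, min_contrast=10)
        global_ = otsu_block_segment(img, block_size=64, min_contrast=10)
        assert np.array_equal(blocked, truth)
        assert not np.array_equal(global_, truth)

    def test_oversized_block_falls_back_to_global(self, rng):
        img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        a = otsu_block_segment(img, block_size=500, min_contrast=1)
        assert np.array_equal(a, img <= otsu_oracle(img))

    def test_small_block_size_rejected(self):
        with pytest.raises(ValueError):
            otsu_block_segment(np.zeros((32, 32)), block_size=8)

    def test_bright_polarity_flag(self):
        img = np.full((32, 32), 50, dtype=np.uint8)
        img[:, 16:] = 200
        mask = otsu_block_segment(img, block_size=32, vessel_is_dark=False)
        assert np.array_equal(mask, img > otsu_oracle(img))


class TestExtractPatches:
    def test_448_tiles_into_four(self, rng):
        img = rng.integers(0, 255, (448, 448, 3)).astype(np.uint8)
        mask = rng.random((448, 448)) < 0.5
        ds = extract_patches(img, mask, 224, 224)
        assert len(ds) == 4
        assert ds.provenance == [(0, 0, 0), (0, 0, 224), (0, 224, 0), (0, 224, 224)]

    def test_exact_size_single_patch(self, rng):
        img = rng.integers(0, 255, (224, 224, 3)).astype(np.uint8)
        mask = rng.random((224, 224)) < 0.5
        ds = extract_patches(img, mask, 224, 224)
        assert len(ds) == 1
        assert np.array_equal(ds.patches[0][0], img)
        assert np.array_equal(ds.patches[0][1], mask)

    def test_remainder_mirror_padded(self, rng):
        img = rng.integers(0, 255, (300, 300, 3)).astype(np.uint8)
        mask = rng.random((300, 300)) < 0.5
        ds = extract_patches(img, mask, 224, 224)
        assert len(ds) == 4
        # bottom-right patch covers rows 224..447 of the reflect-padded
        # image; padded row 300 + k mirrors source row 298 - k
        br_img = ds.patches[3][0]
        real_cols = slice(0, 300 - 224)
        assert np.array_equal(br_img[75, real_cols], img[299, 224:300])  # last real row
        assert np.array_equal(br_img[76, real_cols], img[298, 224:300])
        assert np.array_equal(br_img[78, real_cols], img[296, 224:300])

    def test_mismatched_shapes_raise(self, rng):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((10, 10, 3)), np.zeros((12, 12)), 8, 8)


class TestSplitDataset:
    def _ds(self, n):
        patches = [(np.zeros((8, 8, 3), np.uint8), np.zeros((8, 8), bool)) for _ in range(n)]
        prov = [(0, i, 0) for i in range(n)]
        return PatchDataset(patches, prov, 8)

    def test_seventy_thirty(self):
        tr, va = split_dataset(self._ds(10), 0.7, seed=0)
        assert len(tr) == 7 and len(va) == 3

    def test_deterministic_and_exhaustive(self):
        ds = self._ds(13)
        tr1, va1 = split_dataset(ds, 0.7, seed=5)
        tr2, va2 = split_dataset(ds, 0.7, seed=5)
        assert tr1.provenance == tr2.provenance
        all_prov = sorted(tr1.provenance + va1.provenance)
        assert all_prov == sorted(ds.provenance)
        assert not (set(tr1.provenance) & set(va1.provenance))

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            split_dataset(self._ds(1), 0.7)


def _toy_patches(rng, n=6, size=32):
    """Trivially separable color patches: dark-purple blobs on pink."""
    patches = []
    for _ in range(n):
        mask = np.zeros((size, size), bool)
        r, c = rng.integers(4, size - 12, 2)
        mask[r : r + 8, c : c + 8] = True
        img = np.empty((size, size, 3), np.uint8)
        img[~mask] = (235, 205, 220)
        img[mask] = (110, 75, 140)
        patches.append((img, mask))
    return PatchDataset(patches, [(0, i, 0) for i in range(n)], size)


class TestTrainUnet:
    def test_zero_epochs_rejected(self, rng):
        ds = _toy_patches(rng)
        with pytest.raises(ValueError, match="max_epochs"):
            train_unet(ds, ds, SegConfig(patch_size=32, max_epochs=0))

    def test_loss_decreases_and_report_consistent(self, rng):
        ds = _toy_patches(rng, n=8)
        tr, va = split_dataset(ds, 0.75, seed=0)
        cfg = SegConfig(
            patch_size=32, max_epochs=20, base_channels=4, depth=2, batch_size=4,
            lr_max=5e-3, target_val_dice=95.0, seed=0,
        )
        model, report = train_unet(tr, va, cfg)
        assert report.train_loss[report.best_epoch] < report.train_loss[0] or report.best_epoch == 0
        assert report.best_val_dice_pct == pytest.approx(max(report.val_dice_pct))
        assert min(report.train_loss) < report.train_loss[0]


class TestPredictMask:
    def _background_model(self):
        model = SegModel(SegConfig(patch_size=32, base_channels=4, depth=2))
        head = model.net.head
        head.weight.value[...] = 0.0
        head.bias.value[...] = (5.0, -5.0)  # class 0 everywhere
        return model

    def test_background_model_gives_empty_mask(self, rng):
        model = self._background_model()
        img = rng.integers(0, 255, (50, 70, 3)).astype(np.uint8)
        assert not predict_mask(model, img, patch_size=32).any()

    def test_output_shape_matches_input(self, rng):
        model = self._background_model()
        for shape in ((32, 32), (45, 61), (70, 33)):
            img = rng.integers(0, 255, (*shape, 3)).astype(np.uint8)
            assert predict_mask(model, img, patch_size=32).shape == shape

    def test_single_patch_tiled_equals_whole(self, rng):
        model = SegModel(SegConfig(patch_size=32, base_channels=4, depth=2, seed=2))
        img = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        tiled = predict_mask(model, img, patch_size=32, overlap=0.5)
        whole = model.net.forward(
            (img.astype(float) / 255.0).transpose(2, 0, 1)[None]
        )[0].argmax(0) == 1
        assert (tiled == whole).mean() >= 0.99
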