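"""Mutual information, affine warps, chaining, and pair registration."""

import numpy as np
import pytest
from scipy import ndimage

from vessel3d.register_coarse import (
    PyramidConfig,
    compose_to_reference,
    mutual_information,
    register_pair_affine,
    warp_affine,
)
from vessel3d.types import AffineTransform2D


def entropy_bits(values, bins):
    hist, _ = np.histogram(values.ravel(), bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class TestMutualInformation:
    def test_self_mi_equals_entropy(self, rng):
        img = rng.random((64, 64)) * 255
        for bins in (16, 64):
            assert mutual_information(img, img, bins) == pytest.approx(
                entropy_bits(img, bins), abs=1e-9
            )

    def test_independent_noise_near_zero(self, rng):
        a = rng.random((256, 256))
        b = rng.random((256, 256))
        assert mutual_information(a, b, bins=16) < 0.05

    def test_symmetric(self, rng):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a))

    def test_invariant_under_bijective_relabeling(self, rng):
        a = rng.integers(0, 8, (64, 64)).astype(float)
        perm = rng.permutation(8).astype(float)
        relabeled = perm[a.astype(int)]
        b = rng.integers(0, 8, (64, 64)).astype(float)
        assert mutual_information(a, b, bins=8) == pytest.approx(
            mutual_information(relabeled, b, bins=8), abs=1e-9
        )

    def test_constant_image_gives_zero(self):
        assert mutual_information(np.full((16, 16), 3.0), np.eye(16)) == 0.0

    def test_bad_bins(self):
        with pytest.raises(ValueError):
            mutual_information(np.eye(4), np.eye(4), bins=1)


class TestWarpAffine:
    def test_identity_is_exact(self, rng):
        img = rng.random((31, 33))
        t = AffineTransform2D.identity()
        assert np.allclose(warp_affine(img, t), img)

    def test_integer_translation_is_exact_shift(self, rng):
        img = rng.random((32, 32))
        t = AffineTransform2D(np.array([[1, 0, 3], [0, 1, -2], [0, 0, 1.0]]))
        out = warp_affine(img, t)
        # active shift by (+3 cols, -2 rows): content moves right and up
        assert np.allclose(out[: 32 - 0, 3:][:30], img[2:, : 32 - 3][:30])

    def test_mask_stays_binary(self, rng):
        mask = rng.random((32, 32)) < 0.5
        t = AffineTransform2D(np.array([[1, 0, 0.5], [0, 1, 0.25], [0, 0, 1.0]]))
        out = warp_affine(mask, t, mode="mask")
        assert out.dtype == bool

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform2D(np.array([[1, 0, 0], [2, 0, 0], [0, 0, 1.0]]))


class TestComposeToReference:
    def test_identities_stay_identities(self):
        pairwise = [AffineTransform2D.identity(i + 1, i) for i in range(4)]
        absolute = compose_to_reference(pairwise, 0)
        for t in absolute:
            assert np.allclose(t.matrix, np.eye(3))

    def test_two_step_product_by_hand(self):
        t10 = np.array([[1, 0, 2], [0, 1, 1], [0, 0, 1.0]])
        t21 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        pairwise = [AffineTransform2D(t10, 1, 0), AffineTransform2D(t21, 2, 1)]
        absolute = compose_to_reference(pairwise, 0)
        assert np.allclose(absolute[2].matrix, t10 @ t21)
        assert np.allclose(absolute[1].matrix, t10)
        assert np.allclose(absolute[0].matrix, np.eye(3))

    def test_reference_in_the_middle(self):
        t10 = np.array([[1, 0, 2], [0, 1, 1], [0, 0, 1.0]])
        pairwise = [AffineTransform2D(t10, 1, 0)]
        absolute = compose_to_reference(pairwise, 1)
        assert np.allclose(absolute[0].matrix, np.linalg.inv(t10))
        assert np.allclose(absolute[1].matrix, np.eye(3))

    def test_broken_chain_raises(self):
        pairwise = [
            AffineTransform2D(np.eye(3), 1, 0),
            AffineTransform2D(np.eye(3), 3, 2),  # gap
        ]
        with pytest.raises(ValueError, match="chain"):
            compose_to_reference(pairwise, 0)


def _smooth_section(rendered, idx=3):
    return ndimage.gaussian_filter(rendered.images[idx].astype(float).mean(-1), 1.0)


def _corner_error(recovered, true, shape):
    h, w = shape
    corners = np.array(
        [
            [-(w - 1) / 2, -(h - 1) / 2, 1],
            [(w - 1) / 2, -(h - 1) / 2, 1],
            [-(w - 1) / 2, (h - 1) / 2, 1],
            [(w - 1) / 2, (h - 1) / 2, 1],
        ]
    ).T
    moved = (recovered.matrix @ true.matrix) @ corners
    return float(np.linalg.norm(moved[:2] - corners[:2], axis=0).mean())


class TestRegisterPairAffine:
    def test_identical_pair_recovers_identity(self, rendered):
        img = _smooth_section(rendered)[:96, :96]
        t = register_pair_affine(img, img, PyramidConfig(n_levels=2))
        assert _corner_error(t, AffineTransform2D.identity(), img.shape) < 0.1

    def test_translation_recovered(self, rendered):
        big = _smooth_section(rendered)
        crop = 128
        r0 = (big.shape[0] - crop) // 2
        fixed = big[r0 : r0 + crop, r0 : r0 + crop]
        true = AffineTransform2D(np.array([[1, 0, 5.0], [0, 1, -3.0], [0, 0, 1.0]]))
        moving = warp_affine(big, true)[r0 : r0 + crop, r0 : r0 + crop]
        rec = register_pair_affine(fixed, moving, PyramidConfig())
        # recovered active transform composed with the truth cancels
        err = np.abs((rec.matrix @ true.matrix)[:2, 2])
        assert err.max() < 0.5

    def test_rotation_recovered(self, rendered):
        big = _smooth_section(rendered)
        crop = 128
        r0 = (big.shape[0] - crop) // 2
        fixed = big[r0 : r0 + crop, r0 : r0 + crop]
        ang = np.deg2rad(5.0)
        c, s = np.cos(ang), np.sin(ang)
        true = AffineTransform2D(np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]))
        moving = warp_affine(big, true)[r0 : r0 + crop, r0 : r0 + crop]
        rec = register_pair_affine(fixed, moving, PyramidConfig())
        residual = rec.matrix @ true.matrix
        rec_deg = np.rad2deg(np.arctan2(residual[1, 0], residual[0, 0]))
        assert abs(rec_deg) < 0.2

    def test_objective_not_worse_than_identity(self, rendered):
        img = _smooth_section(rendered)[:96, :96]
        rng = np.random.default_rng(1)
        moving = img + rng.normal(0, 5, img.shape)
        t = register_pair_affine(img, moving, PyramidConfig(n_levels=2))
        # the objective is MI (maximized): never worse than doing nothing
        assert t.objective_at_solution >= t.objective_at_identity - 1e-12
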