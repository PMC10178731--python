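"""Phantom generation, sectioning geometry, stain rendering, misalignment."""

import numpy as np
import pytest
from scipy import ndimage

from vessel3d.metrics import to_grayscale
from vessel3d.synthetic import (
    STAIN_STYLES,
    generate_phantom,
    perturb_stack,
    read_stack,
    render_stack,
    render_stain,
    slice_phantom,
    synthetic_study_stack,
    undo_perturbation,
    write_stack,
)
from vessel3d.types import MaskStack, PerturbationSpec, SectionStack


class TestGeneratePhantom:
    def test_straight_tube_topology(self):
        ph = generate_phantom(n_tubes=1, n_bifurcations=0, curvature=0.0, seed=4)
        _, n = ndimage.label(ph.volume, structure=np.ones((3, 3, 3)))
        assert n == 1
        assert len(ph.centerline_endpoints()) == 2
        assert len(ph.centerline_junctions()) == 0

    def test_two_bifurcations_brute_force_degrees(self):
        ph = generate_phantom(n_bifurcations=2, seed=1)
        # brute-force degree enumeration over the stored polyline graph
        degs = [ph.centerline.degree(n) for n in ph.centerline.nodes]
        assert sum(1 for d in degs if d == 1) == 4
        assert sum(1 for d in degs if d >= 3) == 2

    def test_deterministic_for_fixed_seed(self):
        a = generate_phantom(seed=7)
        b = generate_phantom(seed=7)
        assert np.array_equal(a.volume, b.volume)

    def test_centerline_inside_grid(self, phantom):
        for z, y, x in phantom.centerline.nodes:
            assert phantom.volume[z, y, x]

    def test_subvoxel_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            generate_phantom(radius_range_um=(0.2, 0.3), seed=0)


class TestSlicePhantom:
    def test_section_count_for_28um_depth(self, phantom):
        assert phantom.depth_um() == 28.0
        stack = slice_phantom(phantom, thickness_um=4.0, pixel_um=0.28)
        assert len(stack) == 8

    def test_anisotropy_ratio(self):
        assert 4.0 / 0.28 == pytest.approx(14.29, abs=0.01)

    def test_empty_plane_gives_empty_mask(self):
        ph = generate_phantom(seed=3)
        ph.volume[:2] = False
        stack = slice_phantom(ph, thickness_um=1.0, pixel_um=1.0)
        assert not stack.masks[0].any()

    def test_thickness_finer_than_grid_rejected(self, phantom):
        with pytest.raises(ValueError, match="finer"):
            slice_phantom(phantom, thickness_um=0.5, pixel_um=0.28)


class TestRenderStain:
    def test_unknown_style_lists_valid_ones(self, mask_stack):
        with pytest.raises(ValueError, match="dab"):
            render_stain(mask_stack.masks[3], stain_style="giemsa")

    def test_deterministic(self, mask_stack):
        a = render_stain(mask_stack.masks[3], "he", seed=5)
        b = render_stain(mask_stack.masks[3], "he", seed=5)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("style", sorted(STAIN_STYLES))
    def test_vessel_background_color_separation(self, mask_stack, style):
        mask = mask_stack.masks[3]
        noise = 0.05
        img = render_stain(mask, style, noise_level=noise, seed=0).astype(float)
        diff = np.abs(img[mask].mean(axis=0) - img[~mask].mean(axis=0))
        assert diff.max() > noise * 255

    def test_empty_mask_renders_background_only(self):
        empty = np.zeros((64, 64), bool)
        img = render_stain(empty, "he", noise_level=0.02, seed=0).astype(float) / 255.0
        bg = np.array(STAIN_STYLES["he"]["background"])
        vessel = np.array(STAIN_STYLES["he"]["vessel"])
        d_bg = np.abs(img.mean(axis=(0, 1)) - bg).max()
        d_vessel = np.abs(img.mean(axis=(0, 1)) - vessel).max()
        assert d_bg < 0.1 and d_vessel > 0.2


class TestPerturbStack:
    def test_null_spec_is_identity(self, rendered, mask_stack):
        spec = PerturbationSpec(0, 0, 0, 0, 0, 0, seed=0)
        pstack, pmasks, truth = perturb_stack(rendered, mask_stack, spec)
        assert all(np.array_equal(a, b) for a, b in zip(pstack.images, rendered.images))
        assert all(np.array_equal(a, b) for a, b in zip(pmasks.masks, mask_stack.masks))
        for t in truth.affines:
            assert np.allclose(t.matrix, np.eye(3))
        for f in truth.flows:
            assert not f.displacement.any()

    def test_deterministic(self, rendered, mask_stack):
        spec = PerturbationSpec(seed=9)
        a, _, _ = perturb_stack(rendered, mask_stack, spec)
        b, _, _ = perturb_stack(rendered, mask_stack, spec)
        assert all(np.array_equal(x, y) for x, y in zip(a.images, b.images))

    def test_inverse_transforms_recover_slice(self, rendered, mask_stack):
        # smooth the section first: the round trip is exact up to
        # interpolation error, which is dominated by pixel noise otherwise
        smooth = [
            ndimage.gaussian_filter(im.astype(float), (2, 2, 0)) for im in rendered.images
        ]
        stack = SectionStack(smooth, rendered.pixel_um, rendered.thickness_um, "he")
        spec = PerturbationSpec(seed=3)
        pstack, _, truth = perturb_stack(stack, mask_stack, spec)
        i = 2
        rec = undo_perturbation(pstack.images[i], truth.affines[i], truth.flows[i], "image")
        orig = smooth[i]
        interior = (slice(40, -40), slice(40, -40))
        err = np.abs(rec[interior] - orig[interior]).mean()
        assert err < 0.03 * 255

    def test_crop_keeps_centre(self, rendered, mask_stack):
        spec = PerturbationSpec(0, 0, 0, 0, 0, 0, seed=0)
        pstack, pmasks, truth = perturb_stack(rendered, mask_stack, spec, crop_px=64)
        h, w = rendered.images[0].shape[:2]
        r0, c0 = (h - 64) // 2, (w - 64) // 2
        assert np.array_equal(pstack.images[0], rendered.images[0][r0 : r0 + 64, c0 : c0 + 64])
        assert pmasks.masks[0].shape == (64, 64)


class TestStackIO:
    def test_write_read_round_trip(self, tmp_path, rendered, mask_stack):
        spec = PerturbationSpec(seed=11)
        pstack, pmasks, truth = perturb_stack(rendered, mask_stack, spec, crop_px=96)
        write_stack(tmp_path / "s", pstack, pmasks, truth, seed=11)
        stack2, masks2, truth2 = read_stack(tmp_path / "s")
        assert len(stack2) == len(pstack)
        assert all(np.array_equal(a, b) for a, b in zip(stack2.images, pstack.images))
        assert all(np.array_equal(a, b) for a, b in zip(masks2.masks, pmasks.masks))
        assert np.allclose(truth2.affines[3].matrix, truth.affines[3].matrix)
        assert np.allclose(truth2.flows[3].displacement, truth.flows[3].displacement)

    def test_study_stack_shapes_and_determinism(self):
        o1, om1, p1, pm1, t1, ph1 = synthetic_study_stack(seed=5, crop_px=96)
        o2, _, p2, _, _, _ = synthetic_study_stack(seed=5, crop_px=96)
        assert len(p1) == 8
        assert p1.images[0].shape == (96, 96, 3)
        assert np.array_equal(p1.images[4], p2.images[4])
        assert np.array_equal(o1.images[4], o2.images[4])
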