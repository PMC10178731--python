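"""Synthetic vessel phantoms: 3D branching tubes, physical sectioning,
stain-like rendering, and recorded per-slice misalignment.

The generator emulates the acquisition geometry of serial-section histology:
a branching tubular structure embedded in a tissue block is cut into
consecutive sections (4 µm for H&E-like, 3 µm for DAB-like material) and each
section is imaged in-plane at 0.28 µm/pixel. Because each physical section is
mounted and scanned independently, consecutive images are misaligned by an
independent rigid/affine error plus a smooth elastic deformation; the
perturbation stage reproduces that and records the true transforms so every
downstream stage (segmentation, registration, reconstruction, skeleton
analysis) can be scored against ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import networkx as nx
import numpy as np
from scipy import ndimage

from .types import (
    AffineTransform2D,
    FlowField,
    GroundTruthRecord,
    MaskStack,
    PerturbationSpec,
    SectionStack,
    VesselPhantom,
)
from .warp import apply_flow, warp_affine

__all__ = [
    "generate_phantom",
    "sphere_phantom",
    "slice_phantom",
    "render_stain",
    "render_stack",
    "perturb_stack",
    "synthetic_study_stack",
    "undo_perturbation",
    "write_stack",
    "read_stack",
    "STAIN_STYLES",
]

# Mean RGB (0..1) of vessel and background pixels for each stain style.
# "he": hematoxylin-purple vessels on eosin-pink stroma; "dab": DAB-brown
# endothelium on a pale counterstain.
STAIN_STYLES: dict[str, dict[str, tuple[float, float, float]]] = {
    "he": {"background": (0.93, 0.80, 0.86), "vessel": (0.45, 0.30, 0.55)},
    "dab": {"background": (0.91, 0.87, 0.80), "vessel": (0.55, 0.35, 0.15)},
}


# ---------------------------------------------------------------------------
# Phantom generation


def _random_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    shape: tuple[int, int, int],
    n_steps: int,
    curvature: float,
    margin: float,
) -> list[np.ndarray]:
    """Unit-step random walk with bounded curvature, stopped at the grid margin."""
    pts = [start.copy()]
    d = direction / np.linalg.norm(direction)
    # tubes may run off the top/bottom cut faces (they continue into the
    # block), but must stay inside the lateral field of view
    lo = np.array([0.0, margin, margin])
    hi = np.asarray(shape, dtype=float) - 1 - np.array([0.0, margin, margin])
    p = start.astype(float)
    for _ in range(n_steps):
        if curvature > 0:
            d = d + rng.normal(0.0, curvature, size=3)
            d /= np.linalg.norm(d)
        p = p + d
        if np.any(p < lo) or np.any(p > hi):
            break
        pts.append(p.copy())
    return pts


def _polyline_to_graph(graph: nx.Graph, pts: list[np.ndarray], tree_id: int) -> None:
    prev = None
    for p in pts:
        node = tuple(int(round(v)) for v in p)
        if node not in graph:
            graph.add_node(node, tree=tree_id)
        if prev is not None and node != prev:
            graph.add_edge(prev, node)
        prev = node


def generate_phantom(
    grid_shape: tuple[int, int, int] = (29, 64, 64),
    n_tubes: int = 1,
    n_bifurcations: int = 2,
    radius_range_um: tuple[float, float] = (3.0, 6.0),
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    curvature: float = 0.03,
    axial_bias: float = 4.0,
) -> VesselPhantom:
    """Generate a branching-tube phantom with analytic centerline truth.

    Each tube is a bounded-curvature random-walk polyline spanning the grid
    depth, dilated to a tube by thresholding the Euclidean distance transform
    at the tube radius. ``n_bifurcations`` side branches are spawned from
    interior points. The draw is rejected and retried (deterministically)
    until the centerline graph is a clean tree per tube: ``2*n_tubes +
    n_bifurcations`` endpoints and ``n_bifurcations`` junction nodes.

    Raises
    ------
    ValueError
        If any sampled radius is below one in-plane voxel.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if any(s <= 0 for s in grid_shape):
        raise ValueError("grid_shape must be positive")
    nz, ny, nx_ = grid_shape
    in_plane_um = min(spacing_um[1], spacing_um[2])

    for attempt in range(64):
        rng = np.random.default_rng((seed, attempt))
        graph = nx.Graph()
        centerlines: list[tuple[int, list[np.ndarray]]] = []  # (tree_id, points)
        radii: list[float] = []

        for t in range(n_tubes):
            r_um = float(rng.uniform(*radius_range_um))
            if r_um / in_plane_um < 1.0:
                raise ValueError(
                    f"tube radius {r_um:.3f} um is below one voxel "
                    f"({in_plane_um:.3f} um in-plane)"
                )
            radii.append(r_um)
            margin = max(2.0, r_um / in_plane_um)
            # seed tubes near the in-plane centre: the ROI is chosen around
            # the vasculature, as a pathologist would crop it
            start = np.array(
                [
                    0.0,
                    (ny - 1) * rng.uniform(0.35, 0.65),
                    (nx_ - 1) * rng.uniform(0.35, 0.65),
                ]
            )
            d = rng.normal(size=3)
            d[0] = abs(d[0]) + axial_bias  # bias the trunk to traverse the cutting axis
            main = _random_walk(rng, start, d, grid_shape, n_steps=4 * max(grid_shape), curvature=curvature, margin=margin)
            centerlines.append((t, main))

        # distribute side branches over tubes round-robin
        for b in range(n_bifurcations):
            t = b % n_tubes
            tree_pts = [pts for tid, pts in centerlines if tid == t][0]
            if len(tree_pts) < 6:
                break
            k = int(rng.integers(2, len(tree_pts) - 2))
            parent_dir = tree_pts[min(k + 1, len(tree_pts) - 1)] - tree_pts[k - 1]
            dev = rng.normal(size=3)
            dev /= np.linalg.norm(dev)
            d = parent_dir / np.linalg.norm(parent_dir) + 1.2 * dev
            branch = _random_walk(
                rng,
                tree_pts[k],
                d,
                grid_shape,
                n_steps=max(grid_shape),
                curvature=curvature,
                margin=2.0,
            )
            centerlines.append((t, branch))

        for tid, pts in centerlines:
            _polyline_to_graph(graph, pts, tid)

        endpoints = [n for n in graph if graph.degree(n) == 1]
        junctions = [n for n in graph if graph.degree(n) >= 3]
        want_ep = 2 * n_tubes + n_bifurcations
        tree_ok = nx.number_connected_components(graph) == n_tubes and nx.is_forest(graph)
        if tree_ok and len(endpoints) == want_ep and len(junctions) == n_bifurcations:
            break
    else:
        raise RuntimeError("could not draw a clean branching tree; relax the request")

    volume = np.zeros(grid_shape, dtype=bool)
    for t in range(n_tubes):
        marks = np.zeros(grid_shape, dtype=bool)
        for tid, pts in centerlines:
            if tid != t:
                continue
            for p in pts:
                z, y, x = (int(round(v)) for v in p)
                marks[z, y, x] = True
        dist = ndimage.distance_transform_edt(~marks, sampling=spacing_um)
        volume |= dist <= radii[t]

    return VesselPhantom(volume=volume, spacing_um=tuple(spacing_um), centerline=graph, tube_radii_um=radii)


def sphere_phantom(
    radius_um: float,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    pad: int = 2,
) -> VesselPhantom:
    """A solid ball — the analytic-volume phantom for reconstruction checks."""
    half = [int(np.ceil(radius_um / s)) + pad for s in spacing_um]
    zz, yy, xx = np.mgrid[
        -half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1
    ]
    d2 = (zz * spacing_um[0]) ** 2 + (yy * spacing_um[1]) ** 2 + (xx * spacing_um[2]) ** 2
    vol = d2 <= radius_um**2
    g = nx.Graph()
    g.add_node((half[0], half[1], half[2]), tree=0)
    return VesselPhantom(volume=vol, spacing_um=tuple(spacing_um), centerline=g, tube_radii_um=[radius_um])


# ---------------------------------------------------------------------------
# Sectioning and rendering


def slice_phantom(phantom: VesselPhantom, thickness_um: float, pixel_um: float) -> MaskStack:
    """Cut the phantom into sections every ``thickness_um`` along z and
    resample each section in-plane to ``pixel_um``.

    The section count is ``floor(depth / thickness) + 1`` where depth is the
    physical z extent of the phantom grid. Sections at fractional grid planes
    are linearly interpolated between the two bounding planes.
    """
    sz, sy, sx = phantom.spacing_um
    if thickness_um < sz:
        raise ValueError(
            f"section thickness {thickness_um} um is finer than the phantom z spacing {sz} um"
        )
    depth = phantom.depth_um()
    n_sections = int(np.floor(depth / thickness_um)) + 1
    vol = phantom.volume.astype(float)
    masks = []
    for i in range(n_sections):
        zf = i * thickness_um / sz
        z0 = int(np.floor(zf))
        t = zf - z0
        plane = vol[z0] if t < 1e-9 else (1 - t) * vol[z0] + t * vol[min(z0 + 1, vol.shape[0] - 1)]
        zoomed = ndimage.zoom(plane, (sy / pixel_um, sx / pixel_um), order=1, grid_mode=True, mode="nearest")
        masks.append(zoomed >= 0.5)
    return MaskStack(masks=masks, pixel_um=pixel_um, thickness_um=thickness_um)


def render_stain(
    mask: np.ndarray,
    stain_style: str = "he",
    noise_level: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Render a binary vessel mask as a stain-like RGB image (uint8).

    Vessel and background pixels are drawn around distinct mean colours; a
    smooth multiplicative illumination field, a mid-frequency texture field
    and i.i.d. pixel noise (std ``noise_level`` of full range) are added on
    top. Deterministic for a fixed seed.
    """
    if stain_style not in STAIN_STYLES:
        raise ValueError(
            f"unknown stain_style {stain_style!r}; valid styles: {sorted(STAIN_STYLES)}"
        )
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    colors = STAIN_STYLES[stain_style]
    img = np.empty((h, w, 3), dtype=float)
    img[~mask] = colors["background"]
    img[mask] = colors["vessel"]

    # soft vessel edges, as in real sections where staining fades at the wall
    img = ndimage.gaussian_filter(img, sigma=(1.0, 1.0, 0))
    # slow illumination / staining-intensity field
    illum = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 4.0)
    if illum.std() > 0:
        illum = 1.0 + 0.08 * illum / illum.std()
    else:  # pragma: no cover - degenerate tiny images
        illum = np.ones((h, w))
    img *= illum[..., None]
    # mid-frequency tissue texture
    tex = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
    if tex.std() > 0:
        img += (0.03 * tex / tex.std())[..., None]
    # pixel noise
    img += rng.normal(0.0, noise_level, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def render_stack(
    masks: MaskStack,
    stain_style: str = "he",
    noise_level: float = 0.05,
    seed: int = 0,
) -> SectionStack:
    """Render every mask of a stack; each slice gets an independent sub-seed."""
    ss = np.random.SeedSequence([seed, 0xBEE])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(masks))]
    images = [
        render_stain(m, stain_style=stain_style, noise_level=noise_level, seed=s)
        for m, s in zip(masks.masks, seeds)
    ]
    return SectionStack(
        images=images,
        pixel_um=masks.pixel_um,
        thickness_um=masks.thickness_um,
        stain_style=stain_style,
    )


# ---------------------------------------------------------------------------
# Misalignment


def _sample_affine(rng: np.random.Generator, spec: PerturbationSpec, width: int) -> np.ndarray:
    rot = np.deg2rad(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg))
    tx = rng.uniform(-1, 1) * spec.max_translation_frac * width
    ty = rng.uniform(-1, 1) * spec.max_translation_frac * width
    shear = rng.uniform(-spec.max_shear, spec.max_shear)
    sx = 1.0 + rng.uniform(-spec.max_scale_dev, spec.max_scale_dev)
    sy = 1.0 + rng.uniform(-spec.max_scale_dev, spec.max_scale_dev)
    c, s = np.cos(rot), np.sin(rot)
    rot_m = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    shear_m = np.array([[1, shear, 0], [0, 1, 0], [0, 0, 1.0]])
    scale_m = np.diag([sx, sy, 1.0])
    trans_m = np.array([[1, 0, tx], [0, 1, ty], [0, 0, 1.0]])
    return trans_m @ rot_m @ shear_m @ scale_m


def _elastic_field(rng: np.random.Generator, shape: tuple[int, int], spec: PerturbationSpec) -> np.ndarray:
    if spec.elastic_amplitude_px == 0:
        return np.zeros((*shape, 2))
    noise = rng.standard_normal((*shape, 2))
    field = ndimage.gaussian_filter(noise, sigma=(spec.elastic_smoothness_px, spec.elastic_smoothness_px, 0))
    rms = np.sqrt(np.mean(np.sum(field**2, axis=-1)))
    if rms < 1e-12:  # pragma: no cover
        return np.zeros((*shape, 2))
    return field * (spec.elastic_amplitude_px / rms)


def _center_crop(arr: np.ndarray, size: int) -> np.ndarray:
    h, w = arr.shape[:2]
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image shape {(h, w)}")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return arr[r0 : r0 + size, c0 : c0 + size]


def perturb_stack(
    stack: SectionStack,
    masks: MaskStack,
    spec: PerturbationSpec,
    crop_px: int | None = None,
) -> tuple[SectionStack, MaskStack, GroundTruthRecord]:
    """Misalign every slice by an independent sampled affine followed by a
    smooth elastic field, applying the identical transforms to the masks and
    recording the truth.

    A perturbed slice is ``orig(A^{-1}(p + e(p)))``: the content is first
    moved by the active affine ``A`` then deformed by the backward flow ``e``.

    ``crop_px`` optionally cuts a centred square ROI from every output (and
    from the recorded true masks/flows) *after* perturbing, which emulates
    cropping a fixed ROI out of independently scanned whole-slide images —
    the misaligned content then fills the whole frame instead of leaving
    black borders. The centred crop keeps the affine's centre convention
    valid.
    """
    if len(stack) != len(masks):
        raise ValueError("stack and masks must be paired 1:1")

    def crop(a: np.ndarray) -> np.ndarray:
        return _center_crop(a, crop_px) if crop_px else a

    if spec.is_null():
        truth = GroundTruthRecord(
            affines=[AffineTransform2D.identity(i, i) for i in range(len(stack))],
            flows=[
                FlowField(np.zeros((*crop(m).shape, 2)), i, i) for i, m in enumerate(masks.masks)
            ],
            masks=[crop(m).copy() for m in masks.masks],
        )
        return (
            SectionStack(
                [crop(im).copy() for im in stack.images],
                stack.pixel_um,
                stack.thickness_um,
                stack.stain_style,
            ),
            MaskStack([crop(m).copy() for m in masks.masks], masks.pixel_um, masks.thickness_um),
            truth,
        )

    rng = np.random.default_rng(spec.seed)
    h, w = masks.masks[0].shape
    out_images, out_masks, affines, flows = [], [], [], []
    for i, (img, m) in enumerate(zip(stack.images, masks.masks)):
        a = AffineTransform2D(_sample_affine(rng, spec, w), moving_index=i, fixed_index=i)
        e = _elastic_field(rng, (h, w), spec)
        pert_img = apply_flow(warp_affine(img, a, mode="image"), e, mode="image")
        pert_mask = apply_flow(warp_affine(m, a, mode="mask"), e, mode="mask")
        out_images.append(crop(np.clip(pert_img, 0, 255)).astype(img.dtype))
        out_masks.append(crop(pert_mask))
        affines.append(a)
        flows.append(FlowField(crop(e), moving_index=i, fixed_index=i))
    truth = GroundTruthRecord(affines=affines, flows=flows, masks=[crop(m).copy() for m in masks.masks])
    return (
        SectionStack(out_images, stack.pixel_um, stack.thickness_um, stack.stain_style),
        MaskStack(out_masks, masks.pixel_um, masks.thickness_um),
        truth,
    )


def synthetic_study_stack(
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (29, 96, 96),
    n_tubes: int = 2,
    n_bifurcations: int = 2,
    thickness_um: float = 4.0,
    pixel_um: float = 0.28,
    stain_style: str = "he",
    noise_level: float = 0.05,
    crop_px: int = 224,
    spec: PerturbationSpec | None = None,
):
    """The canonical synthetic experiment: an 8-section H&E-like study.

    Generates a branching phantom in a (29, 96, 96) 1 µm grid, cuts it into
    ``floor(28/4)+1 = 8`` sections at 0.28 µm/pixel, renders the stain,
    misaligns every slice (default :class:`PerturbationSpec`) and crops a
    centred 224 px ROI. Returns ``(original_stack, original_masks,
    perturbed_stack, perturbed_masks, truth, phantom)`` where the originals
    are cropped to the same ROI for like-for-like evaluation.
    """
    ss = np.random.SeedSequence([seed, 0x57AC])
    s_phantom, s_render, s_perturb = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    phantom = generate_phantom(
        grid_shape=grid_shape, n_tubes=n_tubes, n_bifurcations=n_bifurcations, seed=s_phantom
    )
    masks_full = slice_phantom(phantom, thickness_um=thickness_um, pixel_um=pixel_um)
    stack_full = render_stack(masks_full, stain_style=stain_style, noise_level=noise_level, seed=s_render)
    if spec is None:
        spec = PerturbationSpec(seed=s_perturb)
    perturbed, perturbed_masks, truth = perturb_stack(stack_full, masks_full, spec, crop_px=crop_px)
    original = SectionStack(
        [_center_crop(im, crop_px).copy() for im in stack_full.images],
        pixel_um,
        thickness_um,
        stain_style,
    )
    original_masks = MaskStack(
        [_center_crop(m, crop_px).copy() for m in masks_full.masks], pixel_um, thickness_um
    )
    return original, original_masks, perturbed, perturbed_masks, truth, phantom


def undo_perturbation(
    image: np.ndarray,
    affine: AffineTransform2D,
    flow: FlowField,
    mode: str = "image",
) -> np.ndarray:
    """Invert a recorded perturbation (first-order elastic inverse, exact
    affine inverse); recovers the original up to interpolation error."""
    undone_elastic = apply_flow(image, -flow.displacement, mode=mode)
    return warp_affine(undone_elastic, affine.inverse(), mode=mode)


# ---------------------------------------------------------------------------
# Stack I/O: numbered images plus a JSON sidecar


def write_stack(
    out_dir: str | Path,
    stack: SectionStack,
    masks: MaskStack | None = None,
    truth: GroundTruthRecord | None = None,
    seed: int | None = None,
) -> Path:
    """Write numbered PNG sections, optional masks/truth, and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(stack.images):
        iio.imwrite(out / f"section_{i:03d}.png", np.asarray(img, dtype=np.uint8))
    if masks is not None:
        for i, m in enumerate(masks.masks):
            iio.imwrite(out / f"mask_{i:03d}.png", (m.astype(np.uint8) * 255))
    sidecar: dict = {
        "n_sections": len(stack),
        "pixel_um": stack.pixel_um,
        "thickness_um": stack.thickness_um,
        "stain_style": stack.stain_style,
        "seed": seed,
        "has_masks": masks is not None,
        "has_truth": truth is not None,
    }
    if truth is not None:
        sidecar["true_affines"] = [a.matrix.tolist() for a in truth.affines]
        np.savez_compressed(
            out / "truth_flows.npz", **{f"flow_{i:03d}": f.displacement for i, f in enumerate(truth.flows)}
        )
        for i, m in enumerate(truth.masks):
            iio.imwrite(out / f"true_mask_{i:03d}.png", (np.asarray(m).astype(np.uint8) * 255))
    (out / "stack.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_stack(
    in_dir: str | Path,
) -> tuple[SectionStack, MaskStack | None, GroundTruthRecord | None]:
    """Load a stack written by :func:`write_stack`."""
    d = Path(in_dir)
    meta = json.loads((d / "stack.json").read_text())
    n = meta["n_sections"]
    images = [np.asarray(iio.imread(d / f"section_{i:03d}.png")) for i in range(n)]
    stack = SectionStack(images, meta["pixel_um"], meta["thickness_um"], meta["stain_style"])
    masks = None
    if meta.get("has_masks"):
        ms = [np.asarray(iio.imread(d / f"mask_{i:03d}.png")) > 127 for i in range(n)]
        masks = MaskStack(ms, meta["pixel_um"], meta["thickness_um"])
    truth = None
    if meta.get("has_truth"):
        affines = [
            AffineTransform2D(np.array(m), moving_index=i, fixed_index=i)
            for i, m in enumerate(meta["true_affines"])
        ]
        with np.load(d / "truth_flows.npz") as z:
            flows = [FlowField(z[f"flow_{i:03d}"], i, i) for i in range(n)]
        tmasks = [np.asarray(iio.imread(d / f"true_mask_{i:03d}.png")) > 127 for i in range(n)]
        truth = GroundTruthRecord(affines=affines, flows=flows, masks=tmasks)
    return stack, masks, truth
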