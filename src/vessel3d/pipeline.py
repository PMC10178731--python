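"""End-to-end orchestration: one config, deterministic seeding, manifest.

``run_pipeline`` executes segment → coarse registration → fine registration
→ reconstruction → skeletonization → evaluation on a stack directory written
by :func:`vessel3d.synthetic.write_stack` (or any directory following the
same layout), writing every stage artifact plus a manifest recording the
inputs, the config hash and the seed. A single global seed fans out into
per-stage seeds so a run is reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .metrics import registration_report
from .register_coarse import PyramidConfig, register_stack_coarse, warp_affine
from .register_fine import FineConfig, register_stack_fine
from .segmentation import (
    SegConfig,
    build_patch_dataset,
    otsu_segment_stack,
    predict_mask,
    split_dataset,
    train_unet,
)
from .skeleton import branch_statistics, build_branch_graph, skeletonize_3d
from .synthetic import read_stack
from .types import MaskStack, SectionStack, VesselVolume
from .volume import export_volume, filter_small_objects, interpolate_stack
from .warp import apply_flow

__all__ = ["PipelineConfig", "VolumeConfig", "SkeletonConfig", "load_config", "save_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class VolumeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_voxels: int = Field(default=64, ge=0)
    format: str = Field(default="nifti", pattern="^(nifti|tiff)$")


class SkeletonConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # reconstructed voxels are ~0.28 µm; the skeleton does not need that
    # resolution, so the volume is downsampled by this factor first
    downsample: int = Field(default=4, ge=1)
    endpoint_budget: int = Field(default=12, ge=2)


class PipelineConfig(BaseModel):
    """Everything one run needs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    input_dir: str
    out_dir: str
    pixel_um: float = Field(gt=0)
    thickness_um: float = Field(gt=0)
    seed: int = 0
    seg: SegConfig = SegConfig()
    coarse: PyramidConfig = PyramidConfig()
    fine: FineConfig = FineConfig()
    volume: VolumeConfig = VolumeConfig()
    skeleton: SkeletonConfig = SkeletonConfig()


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; unknown keys raise."""
    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.model_validate(raw)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    return path


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True).encode()
    ).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence([seed, 0x3D])
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages on the input stack; returns the manifest dict.

    Any stage failure aborts with an exception naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "input_dir": config.input_dir,
        "config": config.model_dump(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    stage = "load"
    try:
        stack, gt_masks, _truth = read_stack(config.input_dir)
        if gt_masks is None:
            raise ValueError("input stack has no ground-truth masks")

        stage = "segment"
        seg_cfg = config.seg.model_copy(update={"seed": seeds[0]})
        ds = build_patch_dataset(stack, gt_masks, seg_cfg.patch_size, stride=seg_cfg.patch_size)
        train, val = split_dataset(ds, seg_cfg.train_frac, seed=seg_cfg.seed)
        model, report = train_unet(train, val, seg_cfg)
        pred_masks = MaskStack(
            [predict_mask(model, im, seg_cfg.patch_size) for im in stack.images],
            stack.pixel_um,
            stack.thickness_um,
        )
        otsu_masks = otsu_segment_stack(stack, vessel_is_dark=seg_cfg.vessel_is_dark)
        report.to_frame().to_csv(out / "train_report.csv", index=False)
        manifest["stages"]["segment"] = {
            "best_val_dice_pct": report.best_val_dice_pct,
            "train_report": "train_report.csv",
        }

        stage = "register_coarse"
        pairwise, absolute = register_stack_coarse(stack, config.coarse)
        coarse_images = [
            warp_affine(im, t, mode="image") for im, t in zip(stack.images, absolute)
        ]
        warp_masks = lambda ms, ts: MaskStack(
            [warp_affine(m, t, mode="mask") for m, t in zip(ms.masks, ts)],
            ms.pixel_um,
            ms.thickness_um,
        )
        coarse_gt = warp_masks(gt_masks, absolute)
        coarse_pred = warp_masks(pred_masks, absolute)
        (out / "affines.json").write_text(
            json.dumps(
                [
                    {
                        "moving_index": t.moving_index,
                        "fixed_index": t.fixed_index,
                        "matrix": t.matrix.tolist(),
                        "objective_at_identity": t.objective_at_identity,
                        "objective_at_solution": t.objective_at_solution,
                        "converged": t.converged,
                    }
                    for t in pairwise + absolute
                ],
                indent=2,
            )
        )
        manifest["stages"]["register_coarse"] = {"affines": "affines.json"}

        stage = "register_fine"
        fine_cfg = config.fine.model_copy(update={"seed": seeds[1]})
        _model, _pairwise_flows, abs_flows = register_stack_fine(coarse_images, fine_cfg)
        fine_images = [
            apply_flow(im, f, mode="image") for im, f in zip(coarse_images, abs_flows)
        ]
        fine_gt = MaskStack(
            [apply_flow(m, f, mode="mask") for m, f in zip(coarse_gt.masks, abs_flows)],
            gt_masks.pixel_um,
            gt_masks.thickness_um,
        )
        fine_pred = MaskStack(
            [apply_flow(m, f, mode="mask") for m, f in zip(coarse_pred.masks, abs_flows)],
            gt_masks.pixel_um,
            gt_masks.thickness_um,
        )
        np.savez_compressed(
            out / "flows.npz", **{f"flow_{i:03d}": f.displacement for i, f in enumerate(abs_flows)}
        )
        manifest["stages"]["register_fine"] = {"flows": "flows.npz"}

        stage = "reconstruct"
        vol_paths = {}
        for name, ms in (("gt", fine_gt), ("pred", fine_pred)):
            vol = filter_small_objects(interpolate_stack(ms), config.volume.min_voxels)
            ext = ".nii.gz" if config.volume.format == "nifti" else ".tif"
            vol_paths[name] = export_volume(vol, out / f"volume_{name}{ext}", config.volume.format).name
            if name == "gt":
                gt_volume = vol
        manifest["stages"]["reconstruct"] = vol_paths

        stage = "skeletonize"
        ds_factor = config.skeleton.downsample
        if ds_factor > 1:
            from scipy import ndimage as _ndi

            small = _ndi.zoom(gt_volume.voxels.astype(float), 1.0 / ds_factor, order=1) >= 0.5
            vol_sk = VesselVolume(small, tuple(s * ds_factor for s in gt_volume.spacing_um))
        else:
            vol_sk = gt_volume
        sk = skeletonize_3d(vol_sk)
        graph = build_branch_graph(sk)
        stats = branch_statistics(graph, config.skeleton.endpoint_budget)
        stats.branch_table.to_csv(out / "branches.csv", index=False)
        stats.per_component.to_csv(out / "branch_summary.csv", index=False)
        ext = ".nii.gz" if config.volume.format == "nifti" else ".tif"
        export_volume(VesselVolume(sk.voxels, sk.spacing_um), out / f"skeleton{ext}", config.volume.format)
        manifest["stages"]["skeletonize"] = {
            "branches": "branches.csv",
            "branch_summary": "branch_summary.csv",
            "skeleton": f"skeleton{ext}",
        }

        stage = "evaluate"
        rep = registration_report(
            {"original": stack.images, "coarse": coarse_images, "fine": fine_images},
            {"original": gt_masks.masks, "coarse": coarse_gt.masks, "fine": fine_gt.masks},
            {"original": pred_masks.masks, "coarse": coarse_pred.masks, "fine": fine_pred.masks},
        )
        rep.to_csv(out / "registration_report.csv", index=False)
        manifest["stages"]["evaluate"] = {"registration_report": "registration_report.csv"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
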