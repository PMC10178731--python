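"""Vessel segmentation per section: a block-based Otsu baseline and a
trainable U-net.

The Otsu baseline thresholds each block of the luminance image at the value
maximizing the between-class variance of its histogram, marking
low-dynamic-range blocks as background; whether the vessel class is the
darker or brighter side is a polarity flag (hematoxylin/DAB-stained vessels
are darker than the surrounding stroma on luminance).

The U-net is trained on ground-truth patches (default 224x224) split 70/30
into training and validation, with AdamW, a one-cycle learning-rate
schedule and the two-class softmax cross-entropy loss; the epoch checkpoint
with the best validation dice is returned, and training stops early once a
target validation dice (default 90%) is reached. Validation dice is pooled
over all validation-patch pixels rather than averaged per patch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .metrics import to_grayscale
from .nn import AdamW, OneCycleLR, UNet, softmax_cross_entropy
from .types import MaskStack, SectionStack

__all__ = [
    "SegConfig",
    "PatchDataset",
    "TrainReport",
    "SegModel",
    "otsu_block_segment",
    "otsu_segment_stack",
    "extract_patches",
    "build_patch_dataset",
    "split_dataset",
    "train_unet",
    "predict_mask",
]

logger = logging.getLogger(__name__)


class SegConfig(BaseModel):
    """U-net training recipe and Otsu polarity."""

    model_config = ConfigDict(extra="forbid")

    patch_size: int = Field(default=224, ge=16)
    train_frac: float = Field(default=0.7, gt=0.0, lt=1.0)
    max_epochs: int = Field(default=40, ge=0)
    base_channels: int = Field(default=8, ge=2)
    depth: int = Field(default=2, ge=1)
    lr_max: float = Field(default=3e-3, gt=0)
    weight_decay: float = Field(default=1e-4, ge=0)
    batch_size: int = Field(default=8, ge=1)
    target_val_dice: float = Field(default=90.0, ge=0, le=100)
    vessel_is_dark: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _patch_divisible(self):
        if self.patch_size % 2**self.depth:
            raise ValueError(f"patch_size must be divisible by 2^depth = {2**self.depth}")
        return self


@dataclass
class PatchDataset:
    """Image/mask patch pairs with provenance back to the source slices."""

    patches: list[tuple[np.ndarray, np.ndarray]]
    provenance: list[tuple[int, int, int]]  # (slice index, row offset, col offset)
    patch_size: int

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class TrainReport:
    """Per-epoch training history; best epoch is the validation-dice argmax."""

    train_loss: list[float] = field(default_factory=list)
    val_dice_pct: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice_pct: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_dice_pct": self.val_dice_pct,
            }
        )


# ---------------------------------------------------------------------------
# Block-based Otsu baseline


def _otsu_threshold(values: np.ndarray) -> int:
    """Exhaustive Otsu threshold on 8-bit values: the smallest t maximizing
    the between-class variance of {v <= t} vs {v > t}."""
    hist = np.bincount(values.ravel(), minlength=256).astype(float)
    n = hist.sum()
    w0 = np.cumsum(hist)
    mu = np.cumsum(hist * np.arange(256))
    mu_t = mu[-1]
    w1 = n - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * w0 - mu * n) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -1.0
    return int(np.argmax(between))


def otsu_block_segment(
    image: np.ndarray,
    block_size: int = 64,
    min_contrast: int = 10,
    vessel_is_dark: bool = True,
) -> np.ndarray:
    """Per-block Otsu thresholding of the luminance image.

    Blocks whose dynamic range is below ``min_contrast`` are marked
    all-background (they contain a single intensity class). A block size
    larger than the image falls back to one global block.
    """
    if block_size < 16:
        raise ValueError("block_size must be >= 16")
    lum = np.clip(np.round(to_grayscale(image)), 0, 255).astype(np.uint8)
    h, w = lum.shape
    if block_size > max(h, w):
        logger.info("block_size %d exceeds image %s; using one global block", block_size, (h, w))
        block_size = max(h, w)
    out = np.zeros((h, w), dtype=bool)
    for r0 in range(0, h, block_size):
        for c0 in range(0, w, block_size):
            blk = lum[r0 : r0 + block_size, c0 : c0 + block_size]
            if int(blk.max()) - int(blk.min()) < min_contrast:
                continue
            t = _otsu_threshold(blk)
            sel = blk <= t if vessel_is_dark else blk > t
            out[r0 : r0 + block_size, c0 : c0 + block_size] = sel
    return out


def otsu_segment_stack(stack: SectionStack, **kwargs) -> MaskStack:
    """Apply :func:`otsu_block_segment` to every section of a stack."""
    return MaskStack(
        [otsu_block_segment(im, **kwargs) for im in stack.images],
        stack.pixel_um,
        stack.thickness_um,
    )


# ---------------------------------------------------------------------------
# Patches and splits


def extract_patches(
    image: np.ndarray,
    mask: np.ndarray,
    patch_size: int = 224,
    stride: int | None = None,
    slice_index: int = 0,
) -> PatchDataset:
    """Tile an image/mask pair into patches; remainders are mirror-padded."""
    stride = stride or patch_size
    img = np.asarray(image)
    m = np.asarray(mask).astype(bool)
    if img.shape[:2] != m.shape:
        raise ValueError("image and mask must share height/width")
    h, w = m.shape
    # tile anchors: every stride step whose patch still contains new pixels
    rows = [r for r in range(0, h, stride) if r + patch_size - stride < h or r == 0]
    cols = [c for c in range(0, w, stride) if c + patch_size - stride < w or c == 0]
    pad_h = max(0, rows[-1] + patch_size - h)
    pad_w = max(0, cols[-1] + patch_size - w)
    if pad_h or pad_w:
        pimg = np.pad(img, ((0, pad_h), (0, pad_w)) + ((0, 0),) * (img.ndim - 2), mode="reflect")
        pm = np.pad(m, ((0, pad_h), (0, pad_w)), mode="reflect")
    else:
        pimg, pm = img, m
    patches, prov = [], []
    for r in rows:
        for c in cols:
            patches.append(
                (pimg[r : r + patch_size, c : c + patch_size].copy(), pm[r : r + patch_size, c : c + patch_size].copy())
            )
            prov.append((slice_index, r, c))
    return PatchDataset(patches, prov, patch_size)


def build_patch_dataset(
    stack: SectionStack,
    masks: MaskStack,
    patch_size: int = 224,
    stride: int | None = None,
    slice_indices: list[int] | None = None,
) -> PatchDataset:
    """Patch every (or selected) slice of a stack into one dataset."""
    idx = slice_indices if slice_indices is not None else range(len(stack))
    patches, prov = [], []
    for i in idx:
        ds = extract_patches(stack.images[i], masks.masks[i], patch_size, stride, slice_index=i)
        patches += ds.patches
        prov += ds.provenance
    return PatchDataset(patches, prov, patch_size)


def split_dataset(dataset: PatchDataset, train_frac: float = 0.7, seed: int = 0):
    """Shuffled, disjoint, exhaustive split; |train| = round(train_frac·N)."""
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 patches to split")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_frac * n))
    tr, va = order[:n_train], order[n_train:]
    pick = lambda idx: PatchDataset(
        [dataset.patches[i] for i in idx], [dataset.provenance[i] for i in idx], dataset.patch_size
    )
    return pick(tr), pick(va)


# ---------------------------------------------------------------------------
# U-net training and inference


class SegModel:
    """A trained two-class segmentation U-net."""

    def __init__(self, config: SegConfig):
        self.config = config
        self.net = UNet(
            in_ch=3, out_ch=2, base=config.base_channels, depth=config.depth, seed=config.seed
        )

    def logits(self, batch: np.ndarray) -> np.ndarray:
        return self.net.forward(batch)


def _to_batch(patches: list[tuple[np.ndarray, np.ndarray]]):
    x = np.stack([np.asarray(p, dtype=float) / 255.0 for p, _ in patches]).transpose(0, 3, 1, 2)
    y = np.stack([m.astype(np.int64) for _, m in patches])
    return x, y


def _pooled_dice_pct(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = np.count_nonzero(pred & truth)
    total = np.count_nonzero(pred) + np.count_nonzero(truth)
    if total == 0:
        return 100.0
    return 200.0 * inter / total


def train_unet(
    train: PatchDataset, validation: PatchDataset, config: SegConfig | None = None
) -> tuple[SegModel, TrainReport]:
    """Train the U-net on ground-truth patches; return the best checkpoint.

    Stops early once the pooled validation dice reaches
    ``config.target_val_dice``; aborts with ``RuntimeError`` on a non-finite
    loss.
    """
    cfg = config or SegConfig()
    if cfg.max_epochs == 0:
        raise ValueError("max_epochs must be >= 1 (no training would be performed)")
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("train and validation sets must be non-empty")
    model = SegModel(cfg)
    xtr, ytr = _to_batch(train.patches)
    xva, yva = _to_batch(validation.patches)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = AdamW(model.net.params(), lr=cfg.lr_max, weight_decay=cfg.weight_decay)
    n_batches = int(np.ceil(len(train) / cfg.batch_size))
    sched = OneCycleLR(cfg.lr_max, total_steps=cfg.max_epochs * n_batches)
    report = TrainReport()
    best_state = None
    step = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train))
        losses = []
        for b in range(n_batches):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            model.net.zero_grad()
            logits = model.net.forward(xtr[idx])
            loss, dlogits = softmax_cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            model.net.backward(dlogits)
            opt.step(sched.lr(step))
            step += 1
            losses.append(loss)
        preds = _predict_batches(model, xva, cfg.batch_size)
        vd = _pooled_dice_pct(preds, yva.astype(bool))
        report.train_loss.append(float(np.mean(losses)))
        report.val_dice_pct.append(vd)
        if best_state is None or vd > report.best_val_dice_pct:
            report.best_epoch = epoch
            report.best_val_dice_pct = vd
            best_state = model.net.state()
        logger.info("epoch %d: train loss %.4f, val dice %.2f%%", epoch, report.train_loss[-1], vd)
        if vd >= cfg.target_val_dice:
            logger.info("target validation dice %.1f%% reached; stopping", cfg.target_val_dice)
            break
    model.net.load_state(best_state)
    return model, report


def _predict_batches(model: SegModel, x: np.ndarray, batch_size: int) -> np.ndarray:
    preds = []
    for b in range(0, len(x), batch_size):
        logits = model.net.forward(x[b : b + batch_size])
        preds.append(logits.argmax(axis=1).astype(bool))
    return np.concatenate(preds)


def predict_mask(
    model: SegModel,
    image: np.ndarray,
    patch_size: int | None = None,
    overlap: float = 0.5,
) -> np.ndarray:
    """Tiled full-image inference with overlapping patches.

    Class probabilities are accumulated over overlapping tiles and the
    averaged map is argmaxed, so seams between tiles are blended away; the
    output mask has exactly the input's height and width.
    """
    ps = patch_size or model.config.patch_size
    img = np.asarray(image, dtype=float) / 255.0
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    h, w = img.shape[:2]
    stride = max(1, int(round(ps * (1 - overlap)))) if 0 < overlap < 1 else ps
    pad_h = max(ps - h, (-h) % stride)
    pad_w = max(ps - w, (-w) % stride)
    pimg = np.pad(img, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    ph, pw = pimg.shape[:2]
    prob = np.zeros((2, ph, pw))
    weight = np.zeros((ph, pw))
    anchors_r = sorted({min(r, ph - ps) for r in range(0, ph - ps + stride, stride)})
    anchors_c = sorted({min(c, pw - ps) for c in range(0, pw - ps + stride, stride)})
    for r in anchors_r:
        for c in anchors_c:
            tile = pimg[r : r + ps, c : c + ps].transpose(2, 0, 1)[None]
            logits = model.net.forward(tile)[0]
            z = logits - logits.max(axis=0, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=0, keepdims=True)
            prob[:, r : r + ps, c : c + ps] += p
            weight[r : r + ps, c : c + ps] += 1.0
    prob /= weight
    return (prob.argmax(axis=0) == 1)[:h, :w]
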