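"""Evaluation metrics: pairwise dice, sequence-wide mutual dice, SSIM, and
the per-stage registration report.

The dice score between two binary masks is ``2|X∩Y| / (|X|+|Y|) × 100``; the
mutual dice of a mask sequence generalizes it to the intersection of the
whole stack, ``n|X1∩…∩Xn| / Σ|Xi| × 100``. Both are 100 for identical masks
and 0 for disjoint ones. A ``legacy`` flag switches to the union-denominator
variants (``2|X∩Y|/|X∪Y|``, ``n|∩|/|∪|``) for comparison; note those score
identical masks at 200 and n·100/… respectively, so they are not used for
reporting.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = ["dice", "mutual_dice", "ssim_pair", "registration_report", "to_grayscale"]

logger = logging.getLogger(__name__)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool and not np.isin(np.unique(m), (0, 1)).all():
        raise ValueError("masks must be binary")
    return m.astype(bool)


def dice(mask_x: np.ndarray, mask_y: np.ndarray, legacy: bool = False) -> float:
    """Sørensen–Dice overlap of two binary masks, in percent."""
    x, y = _as_bool(mask_x), _as_bool(mask_y)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    inter = np.count_nonzero(x & y)
    if legacy:
        union = np.count_nonzero(x | y)
        if union == 0:
            logger.info("both masks empty; dice defined as 100")
            return 100.0
        return 200.0 * inter / union
    total = np.count_nonzero(x) + np.count_nonzero(y)
    if total == 0:
        logger.info("both masks empty; dice defined as 100")
        return 100.0
    return 200.0 * inter / total


def mutual_dice(masks: Sequence[np.ndarray], legacy: bool = False) -> float:
    """Overlap of an entire mask sequence, in percent.

    ``n |X1∩…∩Xn| / Σ|Xi| × 100``: 100 iff all masks are identical and
    non-empty, 0 as soon as the global intersection is empty.
    """
    if len(masks) < 2:
        raise ValueError("mutual dice needs at least 2 masks")
    bs = [_as_bool(m) for m in masks]
    shapes = {b.shape for b in bs}
    if len(shapes) > 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    inter = bs[0].copy()
    for b in bs[1:]:
        inter &= b
    n_inter = np.count_nonzero(inter)
    if legacy:
        union = bs[0].copy()
        for b in bs[1:]:
            union |= b
        n_union = np.count_nonzero(union)
        if n_union == 0:
            logger.info("all masks empty; mutual dice defined as 100")
            return 100.0
        return 100.0 * len(bs) * n_inter / n_union
    total = sum(np.count_nonzero(b) for b in bs)
    if total == 0:
        logger.info("all masks empty; mutual dice defined as 100")
        return 100.0
    return 100.0 * len(bs) * n_inter / total


def mutual_dice_windowed(masks: Sequence[np.ndarray], window: int) -> list[float]:
    """Mutual dice over overlapped batches of ``window`` consecutive masks.

    Useful for long stacks where vessels gradually leave the frame and the
    full-sequence intersection collapses to zero.
    """
    if window < 2 or window > len(masks):
        raise ValueError("window must be in [2, n_masks]")
    return [mutual_dice(masks[i : i + window]) for i in range(len(masks) - window + 1)]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance conversion (0.299 R + 0.587 G + 0.114 B), float64."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114


def ssim_pair(image_a: np.ndarray, image_b: np.ndarray, win_size: int = 7) -> float:
    """Mean local structural similarity of two grayscale images, in [-1, 1].

    Standard constants (K1=0.01, K2=0.03) and a uniform window; the data
    range is fixed to 255 for 8-bit-scaled inputs.
    """
    a = to_grayscale(image_a)
    b = to_grayscale(image_b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if min(a.shape) < win_size:
        raise ValueError(f"images smaller than the {win_size}-pixel SSIM window")
    return float(structural_similarity(a, b, win_size=win_size, data_range=255.0))


def registration_report(
    stacks_by_stage: dict[str, Sequence[np.ndarray]],
    gt_masks_by_stage: dict[str, Sequence[np.ndarray]],
    pred_masks_by_stage: dict[str, Sequence[np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Build the per-stage registration report.

    For every stage (``original``, ``coarse``, ``fine``) the report holds one
    row per consecutive image pair — SSIM %, dice % on ground-truth masks,
    dice % on predicted masks — followed by one full-sequence row with the
    average pairwise SSIM % and the mutual dice % of the whole stack.
    Negative SSIM values are clipped to 0 for reporting (with a warning).
    """
    frames = []
    for stage, images in stacks_by_stage.items():
        gt = gt_masks_by_stage[stage]
        pred = pred_masks_by_stage[stage] if pred_masks_by_stage else None
        n = len(images)
        if len(gt) != n or (pred is not None and len(pred) != n):
            raise ValueError(f"stage {stage!r}: images and masks differ in length")
        if n < 2:
            raise ValueError("need at least 2 slices for a registration report")
        rows = []
        ssims = []
        for i in range(n - 1):
            s = ssim_pair(images[i], images[i + 1]) * 100.0
            if s < 0:
                logger.warning("negative SSIM %.2f%% for pair %d,%d clipped to 0", s, i, i + 1)
                s = 0.0
            ssims.append(s)
            rows.append(
                {
                    "stage": stage,
                    "row": f"pair {i}, {i + 1}",
                    "ssim_pct": s,
                    "dice_gt_pct": dice(gt[i], gt[i + 1]),
                    "dice_pred_pct": dice(pred[i], pred[i + 1]) if pred is not None else np.nan,
                }
            )
        rows.append(
            {
                "stage": stage,
                "row": "full sequence",
                "ssim_pct": float(np.mean(ssims)),
                "dice_gt_pct": mutual_dice(list(gt)),
                "dice_pred_pct": mutual_dice(list(pred)) if pred is not None else np.nan,
            }
        )
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)
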