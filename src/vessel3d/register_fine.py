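"""Unsupervised deformable finetuning of a coarsely registered stack.

A compact convolutional encoder-decoder (shared across all consecutive pairs
of a stack) predicts a per-pixel backward-sampling flow for each pair. It is
trained without supervision by minimizing a bidirectional local normalized
cross-correlation (NCC) loss — the moving image warped by the forward flow
must correlate with the fixed image, and vice versa for the backward flow —
plus a flow-gradient smoothness penalty weighted by ``smooth_lambda``.
Training backpropagates analytically through the bilinear warp (spatial
transformer) into the network.

Local NCC is evaluated over all windows fully inside the frame ("valid"
windows); the loss is ``1 - mean(NCC)``, so 0 is perfect correlation and 2
is perfect anti-correlation.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage

from .metrics import to_grayscale
from .nn import AdamW, OneCycleLR, UNet
from .types import FlowField, SectionStack
from .warp import apply_flow, compose_flows

__all__ = [
    "FineConfig",
    "ncc_loss",
    "gradient_loss",
    "train_fine_registration",
    "register_stack_fine",
    "FlowModel",
    "apply_flow",
]

_EPS = 1e-10


class FineConfig(BaseModel):
    """Deformable-stage settings: NCC window, smoothness weight, schedule."""

    model_config = ConfigDict(extra="forbid")

    window: int = Field(default=9, ge=3)
    smooth_lambda: float = Field(default=1.0, ge=0.0)
    epochs: int = Field(default=60, ge=1)
    lr_max: float = Field(default=3e-3, gt=0)
    weight_decay: float = Field(default=1e-5, ge=0)
    base_channels: int = Field(default=8, ge=2)
    depth: int = Field(default=2, ge=1)
    train_scale: float = Field(default=1.0, gt=0, le=1.0)
    # Gaussian smoothing (px, at full resolution) of the predicted flow:
    # suppresses noise-driven local warps that NCC cannot distinguish from
    # true deformation
    flow_smooth_px: float = Field(default=0.0, ge=0.0)
    # soft bound (px, full resolution) on the displacement magnitude via a
    # tanh squash: the deformable stage corrects section-mounting
    # deformation, which is a few pixels, not anatomical change between
    # sections; unbounded flows chase content differences down the chain.
    # Default: ~3x the RMS mounting deformation expected at this resolution.
    max_flow_px: float | None = Field(default=6.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _window_odd(self):
        if self.window % 2 == 0:
            raise ValueError("NCC window must be odd")
        return self


def _local_stats(a: np.ndarray, b: np.ndarray, w: int):
    """Local means/variances/covariance over w x w windows (full grid)."""
    mean = lambda x: ndimage.uniform_filter(x, size=w, mode="constant")
    ma, mb = mean(a), mean(b)
    cross = mean(a * b) - ma * mb
    va = mean(a * a) - ma * ma
    vb = mean(b * b) - mb * mb
    return ma, mb, cross, va, vb


def _valid_slice(shape: tuple[int, int], w: int) -> tuple[slice, slice]:
    h = w // 2
    return slice(h, shape[0] - h), slice(h, shape[1] - h)


def ncc_loss(warped: np.ndarray, fixed: np.ndarray, window: int = 9) -> float:
    """``1 - mean local NCC`` over all fully-interior windows; in [0, 2].

    Constant windows are handled by an epsilon-regularized variance, which
    drives their NCC toward 0 rather than producing a division blow-up.
    """
    a = np.asarray(warped, dtype=float)
    b = np.asarray(fixed, dtype=float)
    if a.shape != b.shape:
        raise ValueError("warped and fixed must have equal shapes")
    if min(a.shape) < window:
        raise ValueError(f"images smaller than the {window}-pixel NCC window")
    _, _, cross, va, vb = _local_stats(a, b, window)
    sl = _valid_slice(a.shape, window)
    ncc = cross[sl] / np.sqrt(va[sl] * vb[sl] + _EPS)
    return float(1.0 - ncc.mean())


def _ncc_loss_and_grad(warped: np.ndarray, fixed: np.ndarray, window: int) -> tuple[float, np.ndarray]:
    """NCC loss and its analytic gradient w.r.t. the warped image."""
    a, b = warped, fixed
    w = window
    ma, mb, cross, va, vb = _local_stats(a, b, w)
    sl = _valid_slice(a.shape, w)
    d = np.sqrt(va[sl] * vb[sl] + _EPS)
    ncc = cross[sl] / d
    loss = float(1.0 - ncc.mean())

    n_windows = ncc.size
    # window-level coefficient maps, embedded at valid positions
    A = np.zeros_like(a)
    B = np.zeros_like(a)
    A[sl] = 1.0 / d
    B[sl] = cross[sl] / ((va[sl] + _EPS) * d)
    # sum over all valid windows containing q  (adjoint of the box mean)
    boxsum = lambda x: ndimage.uniform_filter(x, size=w, mode="constant") * (w * w)
    term = b * boxsum(A) - boxsum(A * mb) - a * boxsum(B) + boxsum(B * ma)
    grad = -term / (w * w * n_windows)
    return loss, grad


def gradient_loss(flow: FlowField | np.ndarray) -> float:
    """Smoothness penalty: sum over axes of the mean squared forward
    difference of both displacement components along that axis.

    0 iff the flow is constant; a unit ramp (d_col = col) scores exactly 1.
    """
    disp = flow.displacement if isinstance(flow, FlowField) else np.asarray(flow, dtype=float)
    loss = 0.0
    for axis in (0, 1):
        d = np.diff(disp, axis=axis)
        loss += float(np.mean(d[..., 0] ** 2 + d[..., 1] ** 2))
    return loss


def _gradient_loss_and_grad(disp: np.ndarray) -> tuple[float, np.ndarray]:
    loss = 0.0
    grad = np.zeros_like(disp)
    for axis in (0, 1):
        d = np.diff(disp, axis=axis)
        n = d[..., 0].size
        loss += float(np.mean(d[..., 0] ** 2 + d[..., 1] ** 2))
        g = 2.0 * d / n
        pad_lo = [(0, 0)] * 3
        pad_hi = [(0, 0)] * 3
        pad_lo[axis] = (1, 0)
        pad_hi[axis] = (0, 1)
        grad += np.pad(g, pad_lo) - np.pad(g, pad_hi)
    return loss, grad


def _warp_and_grad(img: np.ndarray, disp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bilinear backward warp with analytic derivatives w.r.t. the flow.

    Returns (warped, d_warped/d_row_disp, d_warped/d_col_disp).
    """
    h, w = img.shape
    r, c = np.mgrid[0:h, 0:w].astype(float)
    rows = r + disp[..., 0]
    cols = c + disp[..., 1]
    r0 = np.floor(rows)
    c0 = np.floor(cols)
    fr = rows - r0
    fc = cols - c0
    r0i = r0.astype(int)
    c0i = c0.astype(int)

    def at(ri, ci):
        inside = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
        out = np.zeros_like(img, dtype=float)
        out[inside] = img[ri[inside], ci[inside]]
        return out

    i00 = at(r0i, c0i)
    i01 = at(r0i, c0i + 1)
    i10 = at(r0i + 1, c0i)
    i11 = at(r0i + 1, c0i + 1)
    warped = (1 - fr) * ((1 - fc) * i00 + fc * i01) + fr * ((1 - fc) * i10 + fc * i11)
    d_row = ((1 - fc) * i10 + fc * i11) - ((1 - fc) * i00 + fc * i01)
    d_col = ((1 - fr) * (i01 - i00)) + fr * (i11 - i10)
    return warped, d_row, d_col


def _pad_to_multiple(img: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img, (h, w)


class FlowModel:
    """A trained pairwise flow predictor (shared network for one stack)."""

    def __init__(self, config: FineConfig):
        self.config = config
        self.net = UNet(
            in_ch=2,
            out_ch=2,
            base=config.base_channels,
            depth=config.depth,
            seed=config.seed,
            final_zero=True,
        )

    def _prep(self, image: np.ndarray) -> np.ndarray:
        g = to_grayscale(image) / 255.0
        if self.config.train_scale < 1.0:
            g = ndimage.zoom(g, self.config.train_scale, order=1)
        return g

    def _cap_px(self) -> float | None:
        if self.config.max_flow_px is None:
            return None
        return self.config.max_flow_px * self.config.train_scale

    def _forward_flow(self, moving_g: np.ndarray, fixed_g: np.ndarray) -> np.ndarray:
        m = 2**self.config.depth
        mp, shape = _pad_to_multiple(moving_g, m)
        fp, _ = _pad_to_multiple(fixed_g, m)
        x = np.stack([mp, fp])[None]
        out = self.net.forward(x)[0]  # (2, H, W): d_row, d_col
        disp = out.transpose(1, 2, 0)[: shape[0], : shape[1]]
        a = self._cap_px()
        return disp if a is None else a * np.tanh(disp / a)

    def predict_flow(
        self, moving: np.ndarray, fixed: np.ndarray, moving_index: int = -1, fixed_index: int = -1
    ) -> FlowField:
        """Predict the forward flow warping ``moving`` onto ``fixed``."""
        h, w = to_grayscale(moving).shape
        disp = self._forward_flow(self._prep(moving), self._prep(fixed))
        s = self.config.train_scale
        if s < 1.0:
            disp = ndimage.zoom(disp, (h / disp.shape[0], w / disp.shape[1], 1), order=1) / s
        if self.config.flow_smooth_px > 0:
            disp = ndimage.gaussian_filter(disp, (self.config.flow_smooth_px, self.config.flow_smooth_px, 0))
        return FlowField(disp, moving_index=moving_index, fixed_index=fixed_index, direction="forward")


def train_fine_registration(
    images: SectionStack | list[np.ndarray], config: FineConfig | None = None
) -> FlowModel:
    """Train the shared flow network on every consecutive pair of a stack.

    Each step evaluates one pair bidirectionally: the forward flow warps the
    moving slice onto the fixed one and the backward flow does the reverse;
    both warps feed the NCC loss, both flows the smoothness penalty. AdamW
    with a one-cycle schedule; deterministic for a fixed config seed.

    Raises ``RuntimeError`` on a non-finite loss.
    """
    cfg = config or FineConfig()
    imgs = images.images if isinstance(images, SectionStack) else list(images)
    if len(imgs) < 2:
        raise ValueError("need at least 2 slices to train fine registration")
    model = FlowModel(cfg)
    grays = [model._prep(im) for im in imgs]
    m = 2**cfg.depth
    padded = [_pad_to_multiple(g, m) for g in grays]
    opt = AdamW(model.net.params(), lr=cfg.lr_max, weight_decay=cfg.weight_decay)
    n_pairs = len(imgs) - 1
    sched = OneCycleLR(cfg.lr_max, total_steps=cfg.epochs * n_pairs)
    step = 0
    for epoch in range(cfg.epochs):
        for i in range(n_pairs):
            (fg, fshape), (mg, _) = padded[i], padded[i + 1]
            loss = _train_step(model, opt, sched.lr(step), mg, fg, fshape, cfg)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"fine registration diverged (non-finite loss) at epoch {epoch}, pair {i}"
                )
            step += 1
    return model


def _train_step(
    model: FlowModel,
    opt: AdamW,
    lr: float,
    moving_p: np.ndarray,
    fixed_p: np.ndarray,
    shape: tuple[int, int],
    cfg: FineConfig,
) -> float:
    """One bidirectional step on a padded pair; returns the total loss."""
    net = model.net
    net.zero_grad()
    total = 0.0
    a = model._cap_px()
    for mv, fx in ((moving_p, fixed_p), (fixed_p, moving_p)):
        x = np.stack([mv, fx])[None]
        out = net.forward(x)  # (1, 2, H, W)
        raw = out[0].transpose(1, 2, 0)
        if a is None:
            disp, d_cap = raw, 1.0
        else:
            th = np.tanh(raw / a)
            disp, d_cap = a * th, 1.0 - th**2
        warped, d_row, d_col = _warp_and_grad(mv, disp)
        sl = (slice(0, shape[0]), slice(0, shape[1]))
        loss_ncc, g_warped_v = _ncc_loss_and_grad(warped[sl], fx[sl], cfg.window)
        g_warped = np.zeros_like(warped)
        g_warped[sl] = g_warped_v
        loss_sm, g_sm = _gradient_loss_and_grad(disp)
        total += loss_ncc + cfg.smooth_lambda * loss_sm
        g_disp = np.stack([g_warped * d_row, g_warped * d_col], axis=-1)
        g_disp += cfg.smooth_lambda * g_sm
        g_raw = g_disp * d_cap
        net.backward(g_raw.transpose(2, 0, 1)[None])
    opt.step(lr)
    return total


def register_stack_fine(
    images: SectionStack | list[np.ndarray],
    config: FineConfig | None = None,
    reference_index: int = 0,
    model: FlowModel | None = None,
) -> tuple[FlowModel, list[FlowField], list[FlowField]]:
    """Train (or reuse) a flow model on a coarsely aligned stack and build
    per-slice flows toward the reference.

    Pairwise forward flows are predicted for each consecutive pair in chain
    order toward the reference and composed by resampling, mirroring the
    affine chaining; the reference slice receives a zero flow. Returns
    ``(model, pairwise_flows, absolute_flows)``.
    """
    cfg = config or FineConfig()
    imgs = images.images if isinstance(images, SectionStack) else list(images)
    if model is None:
        model = train_fine_registration(imgs, cfg)
    n = len(imgs)
    if reference_index != 0:
        raise NotImplementedError("chaining is implemented toward reference slice 0")
    pairwise: list[FlowField] = []
    for i in range(1, n):
        pairwise.append(model.predict_flow(imgs[i], imgs[i - 1], moving_index=i, fixed_index=i - 1))
    h, w = to_grayscale(imgs[0]).shape
    absolute: list[FlowField] = [FlowField(np.zeros((h, w, 2)), 0, 0)]
    acc = None
    for i in range(1, n):
        f = pairwise[i - 1].displacement
        acc = f if acc is None else compose_flows(absolute[i - 1].displacement, f)
        absolute.append(FlowField(acc, moving_index=i, fixed_index=0))
    return model, pairwise, absolute
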