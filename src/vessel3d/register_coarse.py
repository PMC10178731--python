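"""Coarse pairwise affine registration by mutual-information maximization.

Consecutive sections are aligned with a 6-parameter affine (translation,
rotation, anisotropic scale, shear) that maximizes the mutual information of
the joint intensity histogram, optimized coarse-to-fine over a Gaussian image
pyramid with a bounded derivative-free (Powell) search on the Parzen-smoothed
negative MI. Pairwise transforms are then chained into the frame of a single
reference slice (slice 0 by default).
"""

from __future__ import annotations

import logging

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation
from skimage.transform import pyramid_reduce

from .metrics import to_grayscale
from .types import AffineTransform2D, SectionStack
from .warp import centered_grid, warp_affine

__all__ = [
    "PyramidConfig",
    "mutual_information",
    "register_pair_affine",
    "compose_to_reference",
    "register_stack_coarse",
    "warp_affine",
]

logger = logging.getLogger(__name__)


class PyramidConfig(BaseModel):
    """Settings of the hierarchical MI search.

    ``roi`` optionally restricts the objective to a rectangle
    (row0, row1, col0, col1) of the fixed frame before registration.
    """

    model_config = ConfigDict(extra="forbid")

    n_levels: int = Field(default=3, ge=1)
    bins: int = Field(default=48, ge=2)
    max_iter: int = Field(default=60, ge=1)
    tol: float = Field(default=1e-4, gt=0)
    parzen_sigma: float = Field(default=1.0, ge=0)
    min_coarse_size: int = Field(default=32, ge=8)
    roi: tuple[int, int, int, int] | None = None


def mutual_information(image_a: np.ndarray, image_b: np.ndarray, bins: int = 64) -> float:
    """Mutual information of the joint intensity histogram, in bits (>= 0).

    A constant image carries no information; MI is then 0 (logged).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    a = to_grayscale(image_a).ravel()
    b = to_grayscale(image_b).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have equal shapes")
    if a.max() == a.min() or b.max() == b.min():
        logger.info("constant image: mutual information is 0")
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def _mi_parzen(a: np.ndarray, b: np.ndarray, bins: int, sigma: float, a_range, b_range) -> float:
    joint, _, _ = np.histogram2d(a, b, bins=bins, range=(a_range, b_range))
    if sigma > 0:
        joint = ndimage.gaussian_filter(joint, sigma)
    return _mi_from_joint(joint)


# internal parameter scaling so one Powell unit moves the objective comparably
# for every degree of freedom (translations in px; rotation/scale/shear ~0.01)
_THETA_SCALE = np.array([1.0, 1.0, 0.01, 0.01, 0.01, 0.01])


def _params_to_matrix(theta: np.ndarray) -> np.ndarray:
    tx, ty, rot, log_sx, log_sy, shear = theta * _THETA_SCALE
    c, s = np.cos(rot), np.sin(rot)
    m = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    m = m @ np.array([[1.0, shear, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    m = m @ np.diag([np.exp(log_sx), np.exp(log_sy), 1.0])
    m[0, 2] = tx
    m[1, 2] = ty
    return m


def _warp_with_valid(image: np.ndarray, sampling: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Warp by a sampling matrix and return the in-bounds sample mask.

    Pixels that sample outside the moving frame carry no information about
    the alignment (they are filled with 0) and are excluded from the MI
    objective, which would otherwise bias the optimum toward shrinking the
    moving image into its own zero border.
    """
    h, w = image.shape
    x, y = centered_grid((h, w))
    xs = sampling[0, 0] * x + sampling[0, 1] * y + sampling[0, 2]
    ys = sampling[1, 0] * x + sampling[1, 1] * y + sampling[1, 2]
    rows = ys + (h - 1) / 2.0
    cols = xs + (w - 1) / 2.0
    warped = ndimage.map_coordinates(image, [rows, cols], order=1, mode="constant", cval=0.0)
    valid = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    return warped, valid


def _build_pyramid(img: np.ndarray, n_levels: int, min_size: int) -> list[np.ndarray]:
    levels = [img]
    for _ in range(n_levels - 1):
        nxt = pyramid_reduce(levels[-1], downscale=2, preserve_range=True)
        if min(nxt.shape) < min_size:
            break
        levels.append(nxt)
    return levels  # levels[0] is full resolution


def register_pair_affine(
    fixed: np.ndarray,
    moving: np.ndarray,
    config: PyramidConfig | None = None,
    moving_index: int = -1,
    fixed_index: int = -1,
) -> AffineTransform2D:
    """Find the affine aligning ``moving`` onto ``fixed`` by MI maximization.

    Returns the *active* transform (moving-frame points into the fixed frame);
    ``warp_affine(moving, T)`` then resamples the moving image into the fixed
    frame. If the optimized MI at full resolution is worse than the MI at
    identity, the identity is returned with ``converged=False``.
    """
    cfg = config or PyramidConfig()
    fx = to_grayscale(fixed)
    mv = to_grayscale(moving)
    if fx.shape != mv.shape:
        raise ValueError("fixed and moving must have equal shapes")
    if cfg.roi is not None:
        r0, r1, c0, c1 = cfg.roi
        roi_mask = np.zeros(fx.shape, dtype=bool)
        roi_mask[r0:r1, c0:c1] = True
    else:
        roi_mask = None

    pyr_f = _build_pyramid(fx, cfg.n_levels, cfg.min_coarse_size)
    pyr_m = _build_pyramid(mv, cfg.n_levels, cfg.min_coarse_size)
    theta = np.zeros(6)

    for level in range(len(pyr_f) - 1, -1, -1):
        f_l, m_l = pyr_f[level], pyr_m[level]
        f_range = (float(f_l.min()), float(f_l.max()) + 1e-9)
        m_range = (float(m_l.min()), float(m_l.max()) + 1e-9)
        roi_l = roi_mask if level == 0 else None
        f_flat = f_l.ravel()

        def neg_mi(th: np.ndarray) -> float:
            warped, valid = _warp_with_valid(m_l, _params_to_matrix(np.asarray(th)))
            if roi_l is not None:
                valid = valid & roi_l
            sel = valid.ravel()
            if not sel.any():
                return 0.0
            mi = _mi_parzen(f_flat[sel], warped.ravel()[sel], cfg.bins, cfg.parzen_sigma, f_range, m_range)
            # weight by the overlap fraction (total shared information):
            # plain per-pixel MI rises as the valid region shrinks, which
            # rewards absurd translations
            return -mi * (sel.sum() / sel.size)

        w_l = f_l.shape[1]
        if level == len(pyr_f) - 1:
            # global initialization at the coarsest level: MI has spurious
            # local basins, and a wrong rigid basin poisons every finer
            # level. Phase correlation over a fan of candidate rotations
            # finds the translation globally; MI arbitrates.
            best = (neg_mi(theta), theta)
            for rot_deg in np.arange(-20.0, 20.1, 4.0):
                rot_theta = np.zeros(6)
                rot_theta[2] = np.deg2rad(rot_deg) / _THETA_SCALE[2]
                rotated, _ = _warp_with_valid(m_l, _params_to_matrix(rot_theta))
                shift = phase_cross_correlation(
                    f_l, rotated, upsample_factor=2, normalization=None
                )[0]
                for sign in (1.0, -1.0):
                    cand = rot_theta.copy()
                    # rotation is applied about the centre, so the shift
                    # composes as a pure translation in the fixed frame
                    cand[0] = sign * shift[1]
                    cand[1] = sign * shift[0]
                    val = neg_mi(cand)
                    if val < best[0]:
                        best = (val, cand)
            # dense translation grid as a second candidate family: phase
            # correlation can lock onto repeating texture
            span = 0.25 * w_l
            for dx in np.linspace(-span, span, 7):
                for dy in np.linspace(-span, span, 7):
                    cand = theta.copy()
                    cand[0] += dx
                    cand[1] += dy
                    val = neg_mi(cand)
                    if val < best[0]:
                        best = (val, cand)
            theta = best[1]

        # consecutive sections carry two independent mounting errors, so the
        # relative translation can reach roughly twice the per-slice maximum
        bounds = [
            (theta[0] - 0.3 * w_l, theta[0] + 0.3 * w_l),
            (theta[1] - 0.3 * w_l, theta[1] + 0.3 * w_l),
            (-45.0, 45.0),
            (-20.0, 20.0),
            (-20.0, 20.0),
            (-20.0, 20.0),
        ]
        n_passes = 2 if level == 0 else 1  # restart at full resolution to
        for _ in range(n_passes):  # refresh Powell's direction set
            res = optimize.minimize(
                neg_mi,
                theta,
                method="Powell",
                bounds=bounds,
                options={"maxiter": cfg.max_iter, "xtol": cfg.tol, "ftol": cfg.tol},
            )
            theta = res.x
        if level > 0:
            theta = theta.copy()
            theta[0] *= 2.0  # translations double when moving down the pyramid
            theta[1] *= 2.0

        if level == 0:
            mi_solution = float(res.fun)
            mi_identity = float(neg_mi(np.zeros(6)))

    # the registration searched for the sampling transform; report the active one
    sampling = AffineTransform2D(_params_to_matrix(theta))
    if mi_solution > mi_identity:  # worse negative-MI than doing nothing
        logger.warning(
            "pair (%d -> %d): optimized MI %.4f below identity MI %.4f; keeping identity",
            moving_index,
            fixed_index,
            -mi_solution,
            -mi_identity,
        )
        return AffineTransform2D(
            np.eye(3),
            moving_index=moving_index,
            fixed_index=fixed_index,
            objective_at_identity=-mi_identity,
            objective_at_solution=-mi_identity,
            converged=False,
        )
    return AffineTransform2D(
        sampling.inverse().matrix,
        moving_index=moving_index,
        fixed_index=fixed_index,
        objective_at_identity=-mi_identity,
        objective_at_solution=-mi_solution,
        converged=bool(True),
    )


def compose_to_reference(
    pairwise: list[AffineTransform2D], reference_index: int = 0
) -> list[AffineTransform2D]:
    """Chain pairwise transforms into absolute transforms w.r.t. a reference.

    ``pairwise[i]`` must map slice ``i+1`` into the frame of slice ``i``
    (consecutive provenance). The absolute transform of slice ``j > ref`` is
    ``T[ref] · T[ref+1] · … · T[j-1]`` (matrix product, rightmost applied
    first); slices before the reference use inverses; the reference slice
    gets the identity.
    """
    n = len(pairwise) + 1
    if not 0 <= reference_index < n:
        raise ValueError("reference index out of range")
    for i, t in enumerate(pairwise):
        if t.moving_index >= 0 and (t.moving_index != i + 1 or t.fixed_index != i):
            raise ValueError(
                f"broken chain at position {i}: got provenance "
                f"({t.moving_index} -> {t.fixed_index}), expected ({i + 1} -> {i})"
            )
    absolute: list[AffineTransform2D] = [AffineTransform2D.identity(i, reference_index) for i in range(n)]
    # forward of the reference
    acc = np.eye(3)
    for j in range(reference_index + 1, n):
        acc = acc @ pairwise[j - 1].matrix
        absolute[j] = AffineTransform2D(acc.copy(), moving_index=j, fixed_index=reference_index)
    # behind the reference
    acc = np.eye(3)
    for j in range(reference_index - 1, -1, -1):
        acc = acc @ np.linalg.inv(pairwise[j].matrix)
        absolute[j] = AffineTransform2D(acc.copy(), moving_index=j, fixed_index=reference_index)
    return absolute


def register_stack_coarse(
    stack: SectionStack,
    config: PyramidConfig | None = None,
    reference_index: int = 0,
) -> tuple[list[AffineTransform2D], list[AffineTransform2D]]:
    """Register every consecutive pair and chain to the reference slice.

    Returns ``(pairwise, absolute)`` transforms; applying ``absolute[i]`` with
    :func:`warp_affine` brings slice ``i`` into the reference frame.
    """
    pairwise = [
        register_pair_affine(
            stack.images[i], stack.images[i + 1], config, moving_index=i + 1, fixed_index=i
        )
        for i in range(len(stack) - 1)
    ]
    return pairwise, compose_to_reference(pairwise, reference_index)
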