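"""Domain containers shared across the pipeline.

Coordinate conventions, stated once and used everywhere:

* 2D images are ``(row, col)`` arrays; row increases downward.
* 2D affine transforms are 3x3 homogeneous matrices acting on ``(x, y, 1)``
  column vectors where ``x = col - (W-1)/2`` and ``y = row - (H-1)/2``
  (i.e. about the image centre). The matrix is the *active* map taking
  moving-frame points into the fixed frame; warping resamples the moving
  image through the inverse.
* Flow fields are backward-sampling displacements: the warped image at pixel
  ``p`` is the moving image sampled at ``p + flow(p)``; ``flow[..., 0]`` is
  the row displacement, ``flow[..., 1]`` the column displacement, in pixels.
* 3D volumes are ``(z, row, col)`` with the first cut section at ``z = 0``;
  voxel spacing is ``(z, y, x)`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SectionStack",
    "MaskStack",
    "AffineTransform2D",
    "FlowField",
    "VesselVolume",
    "VesselPhantom",
    "PerturbationSpec",
    "GroundTruthRecord",
    "Skeleton",
    "BranchGraph",
]


@dataclass
class SectionStack:
    """An ordered stack of RGB section images with physical metadata.

    ``images`` follow physical cutting order; all share one shape.
    """

    images: list[np.ndarray]
    pixel_um: float
    thickness_um: float
    stain_style: str = "he"

    def __post_init__(self) -> None:
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if self.thickness_um <= 0:
            raise ValueError("thickness_um must be positive")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError(f"all section images must share one shape, got {shapes}")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class MaskStack:
    """Ordered binary vessel masks, paired 1:1 with a section stack."""

    masks: list[np.ndarray]
    pixel_um: float
    thickness_um: float

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks}
        if len(shapes) > 1:
            raise ValueError(f"all masks must share one shape, got {shapes}")
        self.masks = [np.asarray(m).astype(bool) for m in self.masks]

    def __len__(self) -> int:
        return len(self.masks)


@dataclass
class AffineTransform2D:
    """A 3x3 homogeneous affine acting on (x, y, 1) about the image centre.

    ``moving_index``/``fixed_index`` record provenance: the transform maps
    points of slice ``moving_index`` into the frame of slice ``fixed_index``.
    """

    matrix: np.ndarray
    moving_index: int = -1
    fixed_index: int = -1
    objective_at_identity: float = np.nan
    objective_at_solution: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("affine matrix must be 3x3")
        if not np.allclose(self.matrix[2], [0.0, 0.0, 1.0]):
            raise ValueError("bottom row of a homogeneous affine must be (0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:2, :2])) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls, moving_index: int = -1, fixed_index: int = -1) -> "AffineTransform2D":
        return cls(np.eye(3), moving_index, fixed_index)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return the transform that applies ``other`` first, then ``self``."""
        return AffineTransform2D(
            self.matrix @ other.matrix,
            moving_index=other.moving_index,
            fixed_index=self.fixed_index,
        )

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(
            np.linalg.inv(self.matrix),
            moving_index=self.fixed_index,
            fixed_index=self.moving_index,
        )


@dataclass
class FlowField:
    """Per-pixel 2D displacement ``(d_row, d_col)`` in pixels (backward sampling)."""

    displacement: np.ndarray  # (H, W, 2)
    moving_index: int = -1
    fixed_index: int = -1
    direction: str = "forward"

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 3 or self.displacement.shape[-1] != 2:
            raise ValueError("flow displacement must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("flow displacement must be finite")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacement.shape[:2]


@dataclass
class VesselVolume:
    """A reconstructed 3D binary vessel model with voxel spacing in µm."""

    voxels: np.ndarray  # (z, y, x) bool
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3D")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be strictly positive")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)

    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    def physical_volume_um3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_um3()


@dataclass
class VesselPhantom:
    """A synthetic 3D branching-tube phantom with analytic centerline truth.

    ``centerline`` is a graph whose nodes are voxel coordinates ``(z, y, x)``
    and whose edges are unit centerline steps, so endpoint/junction counts
    can be read off node degrees.
    """

    volume: np.ndarray  # (z, y, x) bool
    spacing_um: tuple[float, float, float]
    centerline: nx.Graph
    tube_radii_um: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume).astype(bool)

    def centerline_endpoints(self) -> list[tuple[int, int, int]]:
        return [n for n in self.centerline.nodes if self.centerline.degree(n) == 1]

    def centerline_junctions(self) -> list[tuple[int, int, int]]:
        return [n for n in self.centerline.nodes if self.centerline.degree(n) >= 3]

    def depth_um(self) -> float:
        return (self.volume.shape[0] - 1) * self.spacing_um[0]


@dataclass
class PerturbationSpec:
    """Magnitudes of the per-slice misalignment the registration must undo.

    All magnitudes are maxima of symmetric uniform draws; ``seed`` fixes every
    random draw. Elastic fields are Gaussian-smoothed white noise with RMS
    displacement ``elastic_amplitude_px`` and correlation length
    ``elastic_smoothness_px``.
    """

    max_rotation_deg: float = 10.0
    max_translation_frac: float = 0.05
    max_shear: float = 0.02
    max_scale_dev: float = 0.02
    elastic_amplitude_px: float = 2.0
    elastic_smoothness_px: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_rotation_deg",
            "max_translation_frac",
            "max_shear",
            "max_scale_dev",
            "elastic_amplitude_px",
            "elastic_smoothness_px",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def is_null(self) -> bool:
        return (
            self.max_rotation_deg == 0
            and self.max_translation_frac == 0
            and self.max_shear == 0
            and self.max_scale_dev == 0
            and self.elastic_amplitude_px == 0
        )


@dataclass
class GroundTruthRecord:
    """True per-slice transforms recorded by the perturbation generator."""

    affines: list[AffineTransform2D]
    flows: list[FlowField]
    masks: list[np.ndarray]


@dataclass
class Skeleton:
    """One-voxel-wide centerline voxels of a vessel volume."""

    voxels: np.ndarray  # (z, y, x) bool
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)


@dataclass
class BranchGraph:
    """Branch-level graph of a skeleton.

    ``graph`` is a :class:`networkx.MultiGraph` whose nodes are skeleton voxel
    coordinates ``(z, y, x)`` at endpoints (1 skeleton neighbour) or junctions
    (>= 3), and whose edges are traced branches carrying ``path`` (ordered
    voxel list) and ``length_um`` (sum of Euclidean steps scaled by spacing).
    ``component`` node/edge attributes give the 26-connected component id.
    """

    graph: nx.MultiGraph
    spacing_um: tuple[float, float, float]

    def n_components(self) -> int:
        ids = {d["component"] for _, d in self.graph.nodes(data=True)}
        return len(ids)

    def cycle_count(self) -> int:
        """Independent cycle rank: E - V + number of connected components."""
        g = self.graph
        if g.number_of_nodes() == 0:
            return 0
        return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)

    def total_length_um(self) -> float:
        return float(sum(d["length_um"] for *_, d in self.graph.edges(data=True)))
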