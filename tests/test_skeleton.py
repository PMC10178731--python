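"""Thinning topology, branch-graph construction and branch statistics."""

import networkx as nx
import numpy as np
import pytest
from itertools import combinations

from vessel3d.skeleton import (
    branch_statistics,
    build_branch_graph,
    euler_characteristic,
    independent_cycles,
    label_vessels,
    skeletonize_3d,
)
from vessel3d.types import Skeleton, VesselVolume


def ball(r=8):
    zz, yy, xx = np.mgrid[-r - 1 : r + 2, -r - 1 : r + 2, -r - 1 : r + 2]
    return zz**2 + yy**2 + xx**2 <= r**2


def cylinder(radius=3, length=100):
    zz, yy, xx = np.mgrid[0:length, -radius - 2 : radius + 3, -radius - 2 : radius + 3]
    return yy**2 + xx**2 <= radius**2


def torus(r_major=9, r_minor=3):
    m = r_major + r_minor + 2
    zz, yy, xx = np.mgrid[-r_minor - 1 : r_minor + 2, -m : m + 1, -m : m + 1]
    return (np.sqrt(yy**2 + xx**2) - r_major) ** 2 + zz**2 <= r_minor**2


def y_lines():
    """Analytic Y skeleton with arm lengths 40/30/20 µm at 1 µm spacing."""
    vox = np.zeros((50, 90, 90), bool)
    vox[25, 45, 5:46] = True
    vox[25, 15:46, 45] = True
    vox[5:26, 45, 45] = True
    return vox


def h_shape():
    vox = np.zeros((10, 40, 40), bool)
    vox[5, 5:35, 10] = True
    vox[5, 5:35, 30] = True
    vox[5, 20, 10:31] = True
    return vox


def brute_force_main_branch(graph):
    """Longest endpoint-to-endpoint path by exhaustive enumeration."""
    endpoints = [n for n, d in graph.degree() if d == 1]
    best = 0.0
    for a, b in combinations(endpoints, 2):
        for edge_path in nx.all_simple_edge_paths(graph, a, b):
            best = max(best, sum(graph.edges[e]["length_um"] for e in edge_path))
    return best


class TestSkeletonize:
    def test_ball_collapses_keeping_euler(self):
        b = ball()
        sk = skeletonize_3d(VesselVolume(b, (1, 1, 1)))
        assert euler_characteristic(b) == 1
        assert euler_characteristic(sk.voxels) == 1
        assert 0 < sk.voxels.sum() <= 30
        assert (sk.voxels & ~b).sum() == 0  # skeleton inside the source

    def test_cylinder_reduces_to_single_branch_within_5pct(self):
        sk = skeletonize_3d(VesselVolume(cylinder(), (1, 1, 1)))
        bg = build_branch_graph(sk)
        stats = branch_statistics(bg)
        assert len(stats.per_component) == 1
        assert stats.per_component.n_sub_branches.iloc[0] == 0
        assert stats.per_component.main_branch_um.iloc[0] == pytest.approx(100, rel=0.05)

    def test_torus_keeps_exactly_one_cycle(self):
        t = torus()
        sk = skeletonize_3d(VesselVolume(t, (1, 1, 1)))
        assert independent_cycles(t) == 1
        assert independent_cycles(sk.voxels) == 1
        assert build_branch_graph(sk).cycle_count() == 1

    @pytest.mark.parametrize(
        "vol",
        [ball(), cylinder(length=40), torus()],
        ids=["ball", "cylinder", "torus"],
    )
    def test_thinning_preserves_topology(self, vol):
        sk = skeletonize_3d(VesselVolume(vol, (1, 1, 1)))
        _, n_before = label_vessels(VesselVolume(vol, (1, 1, 1)))
        _, n_after = label_vessels(sk)
        assert n_before == n_after
        assert independent_cycles(vol) == independent_cycles(sk.voxels)

    def test_thinning_preserves_topology_y_and_h(self):
        from scipy import ndimage

        for lines in (y_lines(), h_shape()):
            vol = ndimage.distance_transform_edt(~lines) <= 2.5
            sk = skeletonize_3d(VesselVolume(vol, (1, 1, 1)))
            _, nb = ndimage.label(vol, structure=np.ones((3, 3, 3)))
            _, na = ndimage.label(sk.voxels, structure=np.ones((3, 3, 3)))
            assert nb == na
            assert independent_cycles(vol) == independent_cycles(sk.voxels)

    def test_empty_volume_gives_empty_skeleton(self):
        sk = skeletonize_3d(VesselVolume(np.zeros((4, 4, 4), bool), (1, 1, 1)))
        assert not sk.voxels.any()

    def test_agrees_with_reference_thinning_on_cylinder(self):
        """Cross-check against the scikit-image 3D thinning routine."""
        from skimage.morphology import skeletonize as sk_skel

        vol = cylinder(length=60)
        ours = skeletonize_3d(VesselVolume(vol, (1, 1, 1)))
        ref = Skeleton(sk_skel(vol).astype(bool), (1, 1, 1))
        len_ours = branch_statistics(build_branch_graph(ours)).per_component.main_branch_um.iloc[0]
        len_ref = branch_statistics(build_branch_graph(ref)).per_component.main_branch_um.iloc[0]
        assert len_ours == pytest.approx(len_ref, rel=0.1)


class TestBranchGraph:
    def test_straight_line_single_edge(self):
        vox = np.zeros((3, 3, 12), bool)
        vox[1, 1, 1:11] = True  # 10 voxels
        bg = build_branch_graph(Skeleton(vox, (1, 1, 1)))
        assert bg.graph.number_of_nodes() == 2
        assert bg.graph.number_of_edges() == 1
        (length,) = [d["length_um"] for *_, d in bg.graph.edges(data=True)]
        assert length == pytest.approx(9.0)

    def test_y_shape_nodes_and_edges(self):
        bg = build_branch_graph(Skeleton(y_lines(), (1, 1, 1)))
        kinds = [d["kind"] for _, d in bg.graph.nodes(data=True)]
        assert kinds.count("junction") == 1
        assert kinds.count("endpoint") == 3
        assert bg.graph.number_of_edges() == 3

    def test_single_voxel_is_isolated_node(self):
        vox = np.zeros((3, 3, 3), bool)
        vox[1, 1, 1] = True
        bg = build_branch_graph(Skeleton(vox, (1, 1, 1)))
        assert bg.graph.number_of_nodes() == 1
        assert bg.graph.number_of_edges() == 0

    def test_physical_spacing_scales_lengths(self):
        vox = np.zeros((3, 3, 12), bool)
        vox[1, 1, 1:11] = True
        bg = build_branch_graph(Skeleton(vox, (2.0, 2.0, 0.5)))
        (length,) = [d["length_um"] for *_, d in bg.graph.edges(data=True)]
        assert length == pytest.approx(9 * 0.5)


class TestLabelVessels:
    def test_two_tubes_two_labels(self):
        vox = np.zeros((5, 20, 20), bool)
        vox[2, 2:18, 3] = True
        vox[2, 2:18, 12] = True
        _, n = label_vessels(VesselVolume(vox, (1, 1, 1)))
        assert n == 2

    def test_empty_volume_no_labels(self):
        _, n = label_vessels(VesselVolume(np.zeros((3, 3, 3), bool), (1, 1, 1)))
        assert n == 0

    def test_labels_partition_foreground(self, rng):
        vox = rng.random((8, 16, 16)) < 0.2
        labels, n = label_vessels(VesselVolume(vox, (1, 1, 1)))
        assert (labels > 0).sum() == vox.sum()


class TestBranchStatistics:
    def test_y_main_branch_against_brute_force(self):
        bg = build_branch_graph(Skeleton(y_lines(), (1, 1, 1)))
        stats = branch_statistics(bg)
        row = stats.per_component.iloc[0]
        assert row.main_branch_um == pytest.approx(70.0)
        assert row.n_sub_branches == 1
        assert row.sub_branch_lengths_um == pytest.approx([20.0])
        assert row.main_branch_um == pytest.approx(brute_force_main_branch(bg.graph))

    def test_single_vessel_has_no_sub_branches(self):
        vox = np.zeros((3, 3, 20), bool)
        vox[1, 1, 2:18] = True
        stats = branch_statistics(build_branch_graph(Skeleton(vox, (1, 1, 1))))
        assert stats.per_component.n_sub_branches.iloc[0] == 0

    def test_two_components_reported_independently(self):
        vox = y_lines()
        vox2 = np.zeros_like(vox)
        vox2[40, 60, 10:30] = True  # far-away straight vessel
        stats = branch_statistics(build_branch_graph(Skeleton(vox | vox2, (1, 1, 1))))
        assert len(stats.per_component) == 2
        mains = sorted(stats.per_component.main_branch_um)
        assert mains == pytest.approx([19.0, 70.0])

    def test_single_node_component_scores_zero(self):
        vox = np.zeros((3, 3, 3), bool)
        vox[1, 1, 1] = True
        stats = branch_statistics(build_branch_graph(Skeleton(vox, (1, 1, 1))))
        assert stats.per_component.main_branch_um.iloc[0] == 0.0
        assert stats.per_component.n_sub_branches.iloc[0] == 0

    def test_main_branch_is_longest_per_component(self, phantom):
        """On a generated phantom skeleton the main branch dominates every sub-branch."""
        sk = skeletonize_3d(VesselVolume(phantom.volume, phantom.spacing_um))
        stats = branch_statistics(build_branch_graph(sk))
        for _, row in stats.per_component.iterrows():
            for sub in row.sub_branch_lengths_um:
                assert row.main_branch_um >= sub - 1e-9
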