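"""Centerline trees: topology, length/radius recovery, and invariants."""

import math

import numpy as np
import pytest

from mito3d import VoxelSpacing
from mito3d.skeleton import (
    build_centerline_tree,
    extract_skeleton,
    measure_segments,
    mitochondrion_volume,
    skeletonize_label_volume,
    summarize_morphometry,
)
from mito3d.synthetic import NetworkSpec, generate_network_phantom, generate_stage_cohort

from conftest import ISO10, analytic_capsule_volume


class TestExtractSkeleton:
    def test_straight_cylinder_skeleton_is_axial(self, cylinder_phantom, cylinder_tree):
        _, _, labels, _ = cylinder_phantom
        _, sk = cylinder_tree
        assert sk.skeleton.sum() > 0
        assert not np.any(sk.skeleton & ~labels.mask(1))  # containment
        zc, yc = np.argwhere(labels.mask(1)).mean(axis=0)[:2]
        coords = np.argwhere(sk.skeleton)
        # collinear within one voxel of the true axis
        assert np.all(np.abs(coords[:, 0] - zc) <= 1.0)
        assert np.all(np.abs(coords[:, 1] - yc) <= 1.0)

    def test_sphere_collapses_to_few_voxels(self, sphere_phantom):
        _, _, labels, _ = sphere_phantom
        sk = extract_skeleton(labels.mask(1), ISO10)
        assert sk.voxel_count <= 5

    def test_y_junction_has_one_branch_voxel_region(self, y_junction_phantom):
        _, _, labels, _ = y_junction_phantom
        sk = extract_skeleton(labels.mask(1), ISO10)
        tree = build_centerline_tree(sk, mito_label=1)
        assert tree.n_branch_nodes == 1

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            extract_skeleton(np.zeros((5, 5, 5), bool), ISO10)


class TestCenterlineTree:
    def test_cylinder_two_nodes_one_segment(self, cylinder_tree):
        tree, _ = cylinder_tree
        assert len(tree.nodes) == 2
        assert len(tree.segments) == 1
        assert not tree.has_cycle

    def test_y_junction_four_nodes_three_segments(self, y_junction_phantom):
        _, _, labels, _ = y_junction_phantom
        sk = extract_skeleton(labels.mask(1), ISO10)
        tree = build_centerline_tree(sk, mito_label=1)
        assert len(tree.nodes) == 4
        assert len(tree.segments) == 3
        degrees = sorted(n.degree for n in tree.nodes)
        assert degrees == [1, 1, 1, 3]

    def test_euler_relation_on_acyclic_trees(self, y_junction_phantom, cylinder_tree):
        tree, _ = cylinder_tree
        assert len(tree.segments) == len(tree.nodes) - 1
        _, _, labels, _ = y_junction_phantom
        sk = extract_skeleton(labels.mask(1), ISO10)
        ytree = build_centerline_tree(sk, mito_label=1)
        assert not ytree.has_cycle
        assert len(ytree.segments) == len(ytree.nodes) - 1

    def test_surface_bump_pruned_away(self):
        spec = NetworkSpec(nodes=[(0, 0, 0), (0, 0, 1500)], edges=[(0, 1, 80.0)])
        _, labels, _ = generate_network_phantom(spec, ISO10, seed=7)
        mask = labels.mask(1)
        # a one-voxel nub on the tube surface
        surface = np.argwhere(mask)
        mid = surface[np.abs(surface[:, 2] - surface[:, 2].mean()) < 2]
        top = mid[np.argmax(mid[:, 0])]
        mask[top[0] + 1, top[1], top[2]] = True
        sk = extract_skeleton(mask, ISO10)
        pruned = build_centerline_tree(sk, prune_min_length_factor=1.0)
        assert len(pruned.segments) == 1

    def test_polyline_points_inside_mask(self, y_junction_phantom):
        _, _, labels, _ = y_junction_phantom
        sk = extract_skeleton(labels.mask(1), ISO10)
        tree = build_centerline_tree(sk, mito_label=1)
        for s in tree.segments:
            idx = s.polyline_vox
            assert labels.mask(1)[idx[:, 0], idx[:, 1], idx[:, 2]].all()


class TestMeasurement:
    def test_cylinder_length_and_radius_recovery(self, cylinder_phantom, cylinder_tree):
        _, _, labels, _ = cylinder_phantom
        tree, _ = cylinder_tree
        tree = measure_segments(tree, labels.mask(1), ISO10)
        assert tree.total_length_nm == pytest.approx(2000.0, rel=0.05)
        assert tree.mean_radius_nm == pytest.approx(100.0, rel=0.10)

    def test_sphere_radius_recovery(self, sphere_phantom):
        _, _, labels, _ = sphere_phantom
        trees = skeletonize_label_volume(labels)
        recs = summarize_morphometry(labels, trees)
        assert recs[0].mean_radius_nm == pytest.approx(300.0, rel=0.15)
        assert recs[0].n_branch_nodes == 0

    def test_rotation_invariance_of_length_and_radius(self, cylinder_tree, cylinder_phantom):
        _, _, labels0, _ = cylinder_phantom
        tree0, _ = cylinder_tree
        c, s = math.cos(math.pi / 6), math.sin(math.pi / 6)
        spec = NetworkSpec(
            nodes=[(0, 0, 0), (0, 2000 * s, 2000 * c)], edges=[(0, 1, 100.0)]
        )
        _, labels, _ = generate_network_phantom(spec, ISO10, seed=4)
        sk = extract_skeleton(labels.mask(1), ISO10)
        tree = build_centerline_tree(sk, mito_label=1)
        assert tree.total_length_nm == pytest.approx(tree0.total_length_nm, rel=0.02)
        assert tree.mean_radius_nm == pytest.approx(tree0.mean_radius_nm, rel=0.02)

    def test_axis_permutation_leaves_length_invariant(self):
        spec = NetworkSpec(nodes=[(0, 0, 0), (0, 700, 1300)], edges=[(0, 1, 90.0)])
        _, labels, _ = generate_network_phantom(spec, ISO10, seed=6)
        lengths = []
        for perm in [(0, 1, 2), (2, 0, 1), (1, 2, 0)]:
            mask = np.transpose(labels.mask(1), perm)
            sk = extract_skeleton(mask, ISO10)
            tree = build_centerline_tree(sk)
            lengths.append(tree.total_length_nm)
        assert max(lengths) / min(lengths) - 1 < 0.02

    def test_radius_recovery_is_monotone(self):
        estimates = []
        for i, r in enumerate((50.0, 100.0, 150.0)):
            spec = NetworkSpec(nodes=[(0, 0, 0), (0, 0, 1200)], edges=[(0, 1, r)])
            _, labels, _ = generate_network_phantom(spec, ISO10, seed=10 + i)
            sk = extract_skeleton(labels.mask(1), ISO10)
            tree = build_centerline_tree(sk)
            estimates.append(tree.mean_radius_nm)
        assert estimates[0] < estimates[1] < estimates[2]

    def test_polyline_outside_mask_errors(self, cylinder_tree, cylinder_phantom):
        _, _, labels, _ = cylinder_phantom
        tree, _ = cylinder_tree
        wrong_mask = np.zeros_like(labels.mask(1))
        wrong_mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            measure_segments(tree, wrong_mask, ISO10)


class TestVolume:
    def test_cube_volume_arithmetic(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[1:11, 1:11, 1:11] = True
        assert mitochondrion_volume(mask, ISO10) == pytest.approx(1.0e6)

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[1:11, 1:11, 1:11] = True
        aniso = VoxelSpacing(200.0, 10.0, 10.0)
        assert mitochondrion_volume(mask, aniso) == pytest.approx(
            20 * mitochondrion_volume(mask, ISO10)
        )

    def test_cylinder_volume_within_five_percent(self, cylinder_phantom):
        _, _, labels, _ = cylinder_phantom
        assert mitochondrion_volume(labels.mask(1), ISO10) == pytest.approx(
            analytic_capsule_volume(100.0, 2000.0), rel=0.05
        )

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            mitochondrion_volume(np.zeros((4, 4, 4), bool), ISO10)


class TestSummaries:
    def test_branched_flag_and_totals(self, y_junction_phantom):
        _, _, labels, _ = y_junction_phantom
        trees = skeletonize_label_volume(labels)
        recs = summarize_morphometry(labels, trees)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.branched
        assert rec.total_length_nm == pytest.approx(
            sum(s.length_nm for s in trees[1].segments)
        )

    def test_volume_conservation_across_labels(self):
        spec = NetworkSpec(
            nodes=[(0, 0, 0), (0, 0, 600), (0, 900, 0), (0, 900, 600)],
            edges=[(0, 1, 50.0), (2, 3, 70.0)],
        )
        _, labels, _ = generate_network_phantom(spec, ISO10, seed=0)
        trees = skeletonize_label_volume(labels)
        recs = summarize_morphometry(labels, trees)
        total = sum(r.volume_nm3 for r in recs)
        assert total == pytest.approx(
            labels.foreground().sum() * ISO10.voxel_volume
        )

    def test_missing_tree_errors_with_label(self, y_junction_phantom):
        _, _, labels, _ = y_junction_phantom
        with pytest.raises(ValueError, match="label 1"):
            summarize_morphometry(labels, {})

    def test_stage_cohort_radius_ordering_recovered(self):
        from mito3d.synthetic import StageParams

        params = {
            "PF": StageParams(shape="network", radius_mean_nm=50.0, radius_sd_nm=5.0,
                              branching_prob=0.9, n_edges=3),
            "CL": StageParams(shape="tube", radius_mean_nm=120.0, radius_sd_nm=10.0,
                              n_edges=1, edge_length_mean_nm=600.0),
        }
        cohort = generate_stage_cohort(
            n_per_stage={"PF": 4, "CL": 4}, stage_params=params,
            spacing=VoxelSpacing(15, 15, 15), seed=2,
        )
        means = {}
        for stage in ("PF", "CL"):
            vals = []
            for m in cohort:
                if m.stage != stage:
                    continue
                trees = skeletonize_label_volume(m.labels)
                recs = summarize_morphometry(m.labels, trees)
                vals.append(recs[0].mean_radius_nm)
            means[stage] = np.mean(vals)
        assert means["PF"] < means["CL"]
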