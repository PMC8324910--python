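"""Phantom generators: analytic truth, containment, and determinism."""

import math

import numpy as np
import pytest

from mito3d import VoxelSpacing
from mito3d.synthetic import (
    DEFAULT_STAGE_PARAMS,
    NetworkSpec,
    PhantomSpecError,
    generate_cristae,
    generate_gold_image,
    generate_network_phantom,
    generate_p4_profile,
    generate_stage_cohort,
)

from conftest import ISO10, analytic_capsule_volume


class TestNetworkPhantom:
    def test_straight_tube_volume_matches_analytic_capsule(self, cylinder_phantom):
        _, _, labels, truth = cylinder_phantom
        analytic = analytic_capsule_volume(100.0, 2000.0)
        assert truth.mitochondria[0].volume_nm3 == pytest.approx(analytic)
        voxel_volume = labels.foreground().sum() * ISO10.voxel_volume
        assert voxel_volume == pytest.approx(analytic, rel=0.05)

    def test_zero_edges_gives_empty_volume_and_truth(self):
        spec = NetworkSpec(nodes=[], edges=[])
        _, labels, truth = generate_network_phantom(spec, ISO10, seed=0)
        assert labels.n_labels == 0
        assert truth.mitochondria == []

    def test_y_junction_truth_counts(self, y_junction_phantom):
        _, _, _, truth = y_junction_phantom
        m = truth.mitochondria[0]
        assert m.n_segments == 3
        assert m.n_branch_nodes == 1

    def test_sphere_truth_volume_exact(self, sphere_phantom):
        _, _, _, truth = sphere_phantom
        assert truth.mitochondria[0].volume_nm3 == pytest.approx(
            4.0 / 3.0 * math.pi * 300.0**3
        )

    def test_collinear_chain_volume_is_exact(self):
        # two collinear edges: cap double-counting cancels exactly
        spec = NetworkSpec(
            nodes=[(0, 0, 0), (0, 0, 800), (0, 0, 1600)],
            edges=[(0, 1, 80.0), (1, 2, 80.0)],
        )
        _, _, truth = generate_network_phantom(spec, ISO10, seed=0)
        assert truth.mitochondria[0].volume_nm3 == pytest.approx(
            analytic_capsule_volume(80.0, 1600.0)
        )

    def test_disconnected_tubes_get_separate_labels_and_truths(self):
        spec = NetworkSpec(
            nodes=[(0, 0, 0), (0, 0, 600), (0, 900, 0), (0, 900, 600)],
            edges=[(0, 1, 50.0), (2, 3, 70.0)],
        )
        _, labels, truth = generate_network_phantom(spec, ISO10, seed=0)
        assert labels.n_labels == 2
        assert sorted(m.label for m in truth.mitochondria) == [1, 2]

    def test_out_of_bounds_edge_rejected_naming_edge(self):
        spec = NetworkSpec(nodes=[(0, 0, 0), (0, 0, 5000)], edges=[(0, 1, 100.0)])
        with pytest.raises(PhantomSpecError, match="edge 0"):
            generate_network_phantom(spec, ISO10, seed=0, shape=(30, 30, 30))

    def test_bad_specs_rejected(self):
        with pytest.raises(PhantomSpecError):
            NetworkSpec(nodes=[(0, 0, 0)], edges=[(0, 5, 50.0)]).validate()
        with pytest.raises(PhantomSpecError):
            NetworkSpec(
                nodes=[(0, 0, 0), (0, 0, 100)], edges=[(0, 1, -5.0)]
            ).validate()
        with pytest.raises(PhantomSpecError):
            NetworkSpec(nodes=[], edges=[], cox_fraction=1.5).validate()

    def test_determinism_bit_identical(self):
        spec = NetworkSpec(nodes=[(0, 0, 0), (0, 0, 500)], edges=[(0, 1, 60.0)])
        d1, l1, _ = generate_network_phantom(spec, ISO10, noise_sd=0.2, seed=42)
        d2, l2, _ = generate_network_phantom(spec, ISO10, noise_sd=0.2, seed=42)
        assert np.array_equal(d1.voxels, d2.voxels)
        assert np.array_equal(l1.voxels, l2.voxels)


@pytest.fixture(scope="module")
def lamellar():
    spec = NetworkSpec(
        nodes=[(0, 0, 0), (0, 0, 1500)],
        edges=[(0, 1, 200.0)],
        cristae_style="lamellar",
        cristae_spacing=60.0,
        cox_fraction=1.0,
    )
    _, labels, _ = generate_network_phantom(spec, ISO10, seed=1)
    addition, ct = generate_cristae(labels, spec, ISO10, seed=2)
    return spec, labels, addition, ct


class TestCristae:
    def test_lamellar_volume_matches_slab_stack(self, lamellar):
        # slabs of thickness t at pitch p fill ~t/p of the eroded interior
        from scipy import ndimage

        spec, labels, _, ct = lamellar
        dt = ndimage.distance_transform_edt(labels.foreground(), sampling=ISO10.as_array())
        interior = (dt > 20.0).sum() * ISO10.voxel_volume
        assert ct.cristae_volume_nm3 == pytest.approx(interior * 20.0 / 60.0, rel=0.10)

    def test_containment_in_label(self, lamellar):
        _, labels, _, ct = lamellar
        assert not np.any(ct.cristae_mask & ~labels.foreground())
        assert not np.any(ct.cox_mask & ~ct.cristae_mask)

    def test_cox_fraction_extremes(self, lamellar):
        spec, labels, _, _ = lamellar
        spec0 = NetworkSpec(
            nodes=spec.nodes, edges=spec.edges, cristae_style="lamellar",
            cristae_spacing=60.0, cox_fraction=0.0,
        )
        addition0, ct0 = generate_cristae(labels, spec0, ISO10, seed=2)
        assert not addition0.any()
        assert not ct0.cox_mask.any()
        spec1 = NetworkSpec(
            nodes=spec.nodes, edges=spec.edges, cristae_style="lamellar",
            cristae_spacing=60.0, cox_fraction=1.0,
        )
        _, ct1 = generate_cristae(labels, spec1, ISO10, seed=2)
        assert np.array_equal(ct1.cox_mask, ct1.cristae_mask)

    def test_unresolvable_spacing_rejected(self, lamellar):
        spec, labels, _, _ = lamellar
        bad = NetworkSpec(
            nodes=spec.nodes, edges=spec.edges, cristae_style="lamellar",
            cristae_spacing=15.0,
        )
        with pytest.raises(PhantomSpecError, match="cristae_spacing"):
            generate_cristae(labels, bad, ISO10, seed=0)

    def test_tubular_style_produces_contained_tubules(self):
        spec = NetworkSpec(
            nodes=[(0, 0, 0), (0, 0, 1200)],
            edges=[(0, 1, 220.0)],
            cristae_style="tubular",
            cristae_spacing=70.0,
            cox_fraction=0.5,
        )
        _, labels, _ = generate_network_phantom(spec, ISO10, seed=4)
        _, ct = generate_cristae(labels, spec, ISO10, seed=5)
        assert ct.cristae_mask.any()
        assert not np.any(ct.cristae_mask & ~labels.foreground())
        frac = ct.cox_volume_nm3 / ct.cristae_volume_nm3
        assert 0.2 < frac < 0.8  # roughly half the tubule units carry COX


class TestGoldImage:
    def _rois(self):
        yy, xx = np.ogrid[:300, :300]
        roi1 = (yy - 80) ** 2 + (xx - 80) ** 2 <= 60**2
        roi2 = (yy - 210) ** 2 + (xx - 210) ** 2 <= 60**2
        return [roi1, roi2]

    def test_counts_by_construction(self):
        _, truth = generate_gold_image(self._rois(), [5, 0], 15.0, 2.0, seed=1)
        assert truth.counts == [5, 0]

    def test_diameter_in_pixels(self):
        _, truth = generate_gold_image(self._rois(), [3, 1], 15.0, 1.0, seed=1)
        assert truth.diameter_px == pytest.approx(15.0)

    def test_noise_free_image_is_bimodal(self):
        image, _ = generate_gold_image(
            self._rois(), [8, 4], 15.0, 2.0, noise_sd=0.0, seed=2,
            background=200.0, particle_depth=150.0,
        )
        assert set(np.unique(image)) == {50.0, 200.0}

    def test_centers_inside_their_roi(self):
        rois = self._rois()
        _, truth = generate_gold_image(rois, [10, 7], 15.0, 2.0, seed=3)
        for roi, centers in zip(rois, truth.centers_per_roi):
            for r, c in centers:
                assert roi[int(round(r)), int(round(c))]

    def test_too_small_roi_rejected(self):
        tiny = np.zeros((50, 50), bool)
        tiny[20:24, 20:24] = True
        with pytest.raises(PhantomSpecError, match="too small"):
            generate_gold_image([tiny], [5], 15.0, 2.0, seed=0)

    def test_subpixel_diameter_rejected(self):
        with pytest.raises(PhantomSpecError, match="2 pixels"):
            generate_gold_image(self._rois(), [1, 0], 15.0, 10.0, seed=0)


class TestP4Profile:
    def test_noise_free_nadirs_exactly_periodic(self):
        _, truth = generate_p4_profile(21, 4, 3, noise_sd=0.0, seed=0)
        assert np.allclose(np.diff(truth.nadir_days), 21.0)

    def test_cycle_length_23_recorded(self):
        _, truth = generate_p4_profile(23, 3, 3, seed=0)
        assert truth.period_days == 23.0

    def test_degenerate_constant_refused(self):
        with pytest.raises(ValueError, match="constant"):
            generate_p4_profile(21, 4, 3, seed=0, degenerate_constant=True)

    def test_too_few_cycles_refused(self):
        with pytest.raises(ValueError, match="n_cycles"):
            generate_p4_profile(21, 1, 3, seed=0)

    def test_sampling_cadence(self):
        series, _ = generate_p4_profile(21, 2, 3, seed=0)
        assert np.allclose(np.diff(series.days), 7.0 / 3.0)
        assert np.all(series.p4 >= 0)


class TestStageCohort:
    def test_default_cohort_sizes_match_study_design(self):
        cohort = generate_stage_cohort(seed=0, spacing=VoxelSpacing(30, 30, 30))
        sizes = {s: sum(1 for m in cohort if m.stage == s) for s in ("PF", "MF", "CH", "CL")}
        assert sizes == {"PF": 39, "MF": 22, "CH": 21, "CL": 24}

    def test_luteal_stages_have_no_branch_nodes(self):
        cohort = generate_stage_cohort(
            n_per_stage={"CH": 4, "CL": 4}, seed=1, spacing=VoxelSpacing(30, 30, 30)
        )
        assert all(m.truth.n_branch_nodes == 0 for m in cohort)

    def test_same_seed_bit_identical(self):
        kw = dict(
            n_per_stage={"PF": 2, "CL": 2}, seed=9, spacing=VoxelSpacing(30, 30, 30)
        )
        c1 = generate_stage_cohort(**kw)
        c2 = generate_stage_cohort(**kw)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.density.voxels, b.density.voxels)
            assert np.array_equal(a.labels.voxels, b.labels.voxels)

    def test_truth_radius_means_converge_to_configured(self):
        # 200 per stage at coarse spacing: truth radii are analytic, the
        # rasterization grid does not matter
        n = 200
        cohort = generate_stage_cohort(
            n_per_stage={"PF": n, "CH": n}, seed=3, spacing=VoxelSpacing(40, 40, 40)
        )
        for stage in ("PF", "CH"):
            cfg = DEFAULT_STAGE_PARAMS[stage]
            radii = np.array(
                [np.mean(m.truth.segment_radii_nm) for m in cohort if m.stage == stage]
            )
            se = cfg.radius_sd_nm / np.sqrt(n)
            assert abs(radii.mean() - cfg.radius_mean_nm) < 3.05 * se

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="statistics undefined"):
            generate_stage_cohort(n_per_stage={"PF": 1, "MF": 5})
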