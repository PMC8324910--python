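"""Labelling, exclusion rules, and COX thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mito3d import DensityVolume, LabelVolume
from mito3d.segmentation import (
    SegmentationParams,
    exclude_small,
    label_components,
    select_cox_abundant,
    threshold_cox,
)
from mito3d.synthetic import NetworkSpec, generate_cristae, generate_network_phantom

from conftest import ISO10, flood_fill_labels


class TestLabelComponents:
    def test_two_disjoint_cubes(self):
        m = np.zeros((12, 12, 12), bool)
        m[1:4, 1:4, 1:4] = True
        m[7:10, 7:10, 7:10] = True
        assert label_components(m).n_labels == 2

    def test_y_junction_is_single_component(self, y_junction_phantom):
        _, _, labels, _ = y_junction_phantom
        assert label_components(labels.foreground()).n_labels == 1

    def test_corner_touch_depends_on_connectivity(self):
        m = np.zeros((10, 10, 10), bool)
        m[2:5, 2:5, 2:5] = True
        m[5:8, 5:8, 5:8] = True  # touch only across the corner diagonal
        assert label_components(m, connectivity=26).n_labels == 1
        assert label_components(m, connectivity=6).n_labels == 2

    def test_empty_mask_is_valid_with_zero_labels(self):
        lv = label_components(np.zeros((5, 5, 5), bool))
        assert lv.n_labels == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16, 16)) < 0.25
        ours = label_components(mask, connectivity=connectivity).voxels
        oracle = flood_fill_labels(mask, connectivity)
        # same partition: component count and identical voxel groupings
        assert ours.max() == oracle.max()
        for lbl in range(1, int(oracle.max()) + 1):
            ours_here = np.unique(ours[oracle == lbl])
            assert len(ours_here) == 1 and ours_here[0] > 0

    def test_label_partition_invariant(self, y_junction_phantom):
        _, _, labels, _ = y_junction_phantom
        counts = sum((labels.voxels == l).sum() for l in labels.labels)
        assert counts == labels.foreground().sum()


class TestExcludeSmall:
    def _volume_with_speck(self):
        m = np.zeros((20, 30, 30), np.int32)
        m[2:18, 5:25, 5:25] = 1  # large block
        m[0, 28, 28] = 2  # single-voxel speck (1000 nm^3, z-span 1)
        return LabelVolume(m, ISO10)

    def test_speck_removed_and_survivor_reindexed(self):
        params = SegmentationParams(min_volume_nm3=1e6, min_z_span=2)
        kept, log = exclude_small(self._volume_with_speck(), params)
        assert kept.labels == [1]
        assert [rec.kept for rec in log] == [True, False]

    def test_zero_thresholds_are_identity(self):
        lv = self._volume_with_speck()
        params = SegmentationParams(min_volume_nm3=0, min_z_span=1)
        kept, log = exclude_small(lv, params)
        assert np.array_equal(kept.voxels, lv.voxels)

    def test_idempotent(self):
        params = SegmentationParams(min_volume_nm3=1e6, min_z_span=2)
        once, _ = exclude_small(self._volume_with_speck(), params)
        twice, _ = exclude_small(once, params)
        assert np.array_equal(once.voxels, twice.voxels)

    def test_injected_specks_removed_from_phantom(self):
        spec = NetworkSpec(nodes=[(0, 0, 0), (0, 0, 800)], edges=[(0, 1, 80.0)])
        _, labels, truth = generate_network_phantom(spec, ISO10, seed=5)
        vox = labels.voxels.copy()
        rng = np.random.default_rng(0)
        free = np.argwhere(vox == 0)
        for k in range(5):  # five sub-threshold specks
            z, y, x = free[rng.integers(len(free))]
            vox[z, y, x] = labels.n_labels + 1 + k
        noisy = LabelVolume(vox, ISO10)
        kept, _ = exclude_small(noisy, SegmentationParams())
        assert kept.n_labels == len(truth.mitochondria)


class TestThresholdCox:
    def test_fixed_threshold_recovers_truth_mask_noise_free(self):
        spec = NetworkSpec(
            nodes=[(0, 0, 0), (0, 0, 1000)], edges=[(0, 1, 150.0)],
            cristae_style="lamellar", cristae_spacing=60.0, cox_fraction=1.0,
        )
        density, labels, _ = generate_network_phantom(spec, ISO10, seed=1)
        addition, ct = generate_cristae(labels, spec, ISO10, seed=2)
        vol = DensityVolume(density.voxels + addition, ISO10)
        mask, thr = threshold_cox(
            vol, SegmentationParams(cox_threshold_value=2.6)
        )
        assert np.array_equal(mask, ct.cox_mask)

    def test_threshold_above_max_gives_empty_mask(self, cylinder_phantom):
        _, density, _, _ = cylinder_phantom
        mask, _ = threshold_cox(
            density, SegmentationParams(cox_threshold_value=1e9)
        )
        assert not mask.any()

    def test_otsu_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        data = np.concatenate(
            [rng.normal(0.5, 0.05, 4000), rng.normal(3.0, 0.05, 4000)]
        ).reshape(20, 20, 20)
        vol = DensityVolume(data, ISO10)
        _, thr = threshold_cox(vol, SegmentationParams(cox_threshold_method="otsu"))
        low_top = data[data < 1.5].max()
        high_bottom = data[data > 1.5].min()
        # strictly between the two modes (the variance plateau spans the gap)
        assert low_top < thr < high_bottom
        # oracle: exhaustive scan of between-class variance lands in the gap too
        flat = np.sort(data.ravel())
        candidates = np.linspace(flat[1], flat[-2], 512)
        best, best_t = -1.0, None
        for t in candidates:
            lo, hi = flat[flat <= t], flat[flat > t]
            if len(lo) == 0 or len(hi) == 0:
                continue
            w0, w1 = len(lo) / len(flat), len(hi) / len(flat)
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if v > best:
                best, best_t = v, t
        assert low_top < best_t < high_bottom

    def test_otsu_on_constant_volume_errors(self):
        vol = DensityVolume(np.ones((6, 6, 6)), ISO10)
        with pytest.raises(ValueError, match="constant"):
            threshold_cox(vol, SegmentationParams(cox_threshold_method="otsu"))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mask_monotone_nonincreasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        vol = DensityVolume(rng.random((8, 8, 8)), ISO10)
        t_low, t_high = sorted(rng.random(2))
        m_low, _ = threshold_cox(vol, SegmentationParams(cox_threshold_value=t_low))
        m_high, _ = threshold_cox(vol, SegmentationParams(cox_threshold_value=t_high))
        assert not np.any(m_high & ~m_low)


class TestSelectCoxAbundant:
    def _two_mito_phantom(self, cox_a: float, cox_b: float):
        nodes = [(0, 0, 0), (0, 0, 1000), (0, 900, 0), (0, 900, 1000)]
        edges = [(0, 1, 150.0), (2, 3, 150.0)]
        built = []
        spec_all = NetworkSpec(nodes=nodes, edges=edges)
        density, labels, _ = generate_network_phantom(spec_all, ISO10, seed=1)
        cox = np.zeros(labels.voxels.shape, bool)
        cristae = np.zeros(labels.voxels.shape, bool)
        for lbl, frac in ((1, cox_a), (2, cox_b)):
            spec = NetworkSpec(
                nodes=nodes, edges=[edges[lbl - 1]], cristae_style="lamellar",
                cristae_spacing=60.0, cox_fraction=frac,
            )
            single = LabelVolume(
                np.where(labels.voxels == lbl, lbl, 0).astype(np.int32), ISO10
            )
            _, ct = generate_cristae(single, spec, ISO10, seed=lbl)
            cox |= ct.cox_mask
            cristae |= ct.cristae_mask
        return labels, cox, cristae

    def test_full_vs_zero_cox_selection(self):
        labels, cox, cristae = self._two_mito_phantom(1.0, 0.0)
        params = SegmentationParams(cox_abundance_fraction=0.5)
        selected, fractions = select_cox_abundant(labels, cox, params, cristae)
        assert selected == [1]
        assert fractions[1] == pytest.approx(1.0)
        assert fractions[2] == pytest.approx(0.0)

    def test_zero_threshold_keeps_all(self):
        labels, cox, cristae = self._two_mito_phantom(1.0, 0.0)
        params = SegmentationParams(cox_abundance_fraction=0.0)
        selected, _ = select_cox_abundant(labels, cox, params, cristae)
        assert selected == labels.labels

    def test_cox_fraction_060_passes_050_threshold(self):
        labels, cox, cristae = self._two_mito_phantom(0.6, 0.6)
        params = SegmentationParams(cox_abundance_fraction=0.5)
        selected, fractions = select_cox_abundant(labels, cox, params, cristae)
        assert selected == labels.labels
        # oracle: direct voxel count of the measured region
        for lbl in labels.labels:
            assert fractions[lbl] == pytest.approx(0.6, abs=0.12)
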