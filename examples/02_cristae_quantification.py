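"""Quantify cristae from COX density inside the eroded outer membrane.

Paints lamellar cristae carrying a COX-like density into a tube phantom,
thresholds the density, and reports cristae volume ratio, surface area, and
the lamellar-vs-tubular shape score.
"""

from mito3d import DensityVolume, VoxelSpacing
from mito3d.cristae import quantify_cristae
from mito3d.segmentation import SegmentationParams, select_cox_abundant, threshold_cox
from mito3d.synthetic import NetworkSpec, generate_cristae, generate_network_phantom

spacing = VoxelSpacing(10.0, 10.0, 10.0)
spec = NetworkSpec(
    nodes=[(0, 0, 0), (0, 0, 1500)],
    edges=[(0, 1, 200.0)],
    cristae_style="lamellar",  # parallel membrane stacks, 60 nm apart
    cristae_spacing=60.0,
    cox_fraction=0.9,  # 90% of lamellae are COX-active
)
density, labels, _ = generate_network_phantom(spec, spacing, seed=1)
cox_addition, cristae_truth = generate_cristae(labels, spec, spacing, seed=2)

volume = DensityVolume(density.voxels + cox_addition, spacing)
params = SegmentationParams(cox_threshold_value=2.6, cox_abundance_fraction=0.5)
cox_mask, threshold = threshold_cox(volume, params)
selected, fractions = select_cox_abundant(
    labels, cox_mask, params, cristae_mask=cristae_truth.cristae_mask
)
print(f"COX threshold: {threshold}; COX-abundant labels: {selected} "
      f"(stained fraction {fractions[1]:.2f})")

metrics = quantify_cristae(labels, cox_mask, erosion_distance_nm=20.0,
                           selected_labels=selected)
m = metrics[0]
print(f"cristae volume ratio:   {m.volume_ratio:.3f}")
print(f"cristae surface area:   {m.surface_area_nm2:.3g} nm^2")
print(f"surface density (/mito volume): {m.surface_area_density_per_mito:.4f} nm^-1")
print(f"shape score: planarity {m.planarity:.2f} vs linearity {m.linearity:.2f}")
print()
print("Planarity > linearity identifies the lamellar (stacked-membrane)")
print("cristae of granulosa cells; tubular cristae reverse the ordering.")
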