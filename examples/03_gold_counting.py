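"""Count 15 nm immuno-gold particles inside mitochondrial ROIs.

Simulates a micrograph with two hand-drawn mitochondrial areas, detects the
dark gold particles automatically, and reports per-ROI densities.
"""

import numpy as np

from mito3d.gold import GoldROI, count_in_rois, detect_gold_particles
from mito3d.synthetic import generate_gold_image

pixel_size_nm = 2.0
yy, xx = np.ogrid[:400, :400]
roi_masks = [
    (yy - 100) ** 2 + (xx - 100) ** 2 <= 80**2,
    (yy - 280) ** 2 + (xx - 280) ** 2 <= 80**2,
]

image, truth = generate_gold_image(
    roi_masks, counts=[14, 4], particle_diameter_nm=15.0,
    pixel_size_nm=pixel_size_nm, noise_sd=30.0, seed=5,
)

points = detect_gold_particles(image, pixel_size_nm, diameter_nm=15.0)
rois = [GoldROI(i, m, stage=s) for i, (m, s) in enumerate(zip(roi_masks, ["MF", "CH"]))]
rois, stray = count_in_rois(points, rois, pixel_size_nm)

for roi, true_count in zip(rois, truth.counts):
    print(
        f"ROI {roi.roi_id} ({roi.stage}): {roi.particle_count} detected "
        f"(truth {true_count}) over {roi.area_um2:.3f} um^2 "
        f"-> {roi.density_per_um2:.1f} particles/um^2"
    )
print(f"particles outside every ROI: {len(stray)}")
print()
print("Particle density per mitochondrial area proxies ATP-synthase content;")
print("in the luteal lineage it is high in mature follicles and corpus luteum,")
print("low in primordial follicles and corpus hemorrhagicum.")
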