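# Methods

This note records the models, conventions, and numerical choices behind
`mito3d`, and what the synthetic validation does and does not demonstrate.

## Central-line trees

Each labelled mitochondrion is reduced to a one-voxel-wide medial line by 3D
topology-preserving iterative thinning (scikit-image's 3D skeletonization).
The skeleton voxel graph (26-connectivity) is converted to a tree: voxels
with one skeleton neighbour are endpoints, voxels with three or more are
junction voxels, and adjacent junction voxels are merged into a single node
placed at the member voxel nearest their centroid. Maximal junction-free
paths become segments with voxel polylines; cycles, when present, are kept
and flagged rather than broken silently.

**Twig pruning.** Thinning produces spurious short twigs where surface bumps
attract the medial axis. A leaf segment is removed when its length falls
below `prune_min_length_factor` (default 1.0) times the inscribed radius at
its junction; the skeleton is then re-derived, which also straightens the
junction back into a through-going segment. The default reflects the usual
medial-axis noise argument: a twig shorter than the local tube radius cannot
represent a resolved branch.

**Length.** Segment length is the arc length of the polyline in physical nm.
Raw voxel-step polylines overestimate oblique runs by up to ~8% (digital
staircase), so polyline coordinates are smoothed with a short Gaussian
(σ = 2 points, endpoints pinned) before summing; straight axis-aligned,
30°-rotated, and body-diagonal tubes then agree within ~2%.

**Radius.** The radius at a centerline point is the Euclidean distance to
the background computed with the anisotropic physical spacing — the
inscribed-sphere radius, which is the natural "mean radius" of a roughly
tubular organelle. A mitochondrion whose skeleton collapses to a point (a
sphere) reports the distance value at the collapse point; for an exact ball
this is the ball radius.

**Anisotropy.** Serial-section tomograms may arrive with dz ≫ dx (200 nm
sections vs ~10 nm in-plane). When anisotropy exceeds 2, the mask is
linearly resampled to the finest spacing before thinning (thinning assumes a
near-isotropic grid); distances and lengths are always computed in physical
units, so measurements are grid-independent. Radius estimates in the
resampled regime are accurate only to the section spacing — a limitation of
the data, not of the estimator, and the isotropic oracles in the tests do
not cover it.

Node coordinates are voxel centres in nm, 0-based, axis order (z, y, x) in
all outputs. Total length is summed per physically connected mitochondrion
(one label), matching the per-organelle colouring convention of connected
components; summing per cell would require cell segmentation the inputs do
not carry.

## Segmentation rules

"Small mitochondria without clearly defined volumes" is operationalized as a
pair of configurable thresholds applied together: minimum volume (default
10⁶ nm³) and minimum z-extent (default 2 sections). Connectivity for
"physical connection" defaults to 26 because manual segmentations routinely
produce diagonal voxel contacts. The COX threshold is a single scalar per
tomogram (fixed value, or Otsu on the tomogram's own histogram), and a
mitochondrion counts as COX-abundant when at least `cox_abundance_fraction`
(default 0.5, "most cristae") of its assessed cristae region is
COX-positive. Manual label volumes are trusted verbatim; the package never
re-segments them.

## Cristae quantification

COX reaction product marks active cristae but also rims the intermembrane
space, so the organelle mask is eroded by `erosion_nm` (default 20 nm —
roughly membrane thickness plus localization blur) before intersecting with
the COX mask. From the resulting cristae voxel set:

- **Volume ratio**: cristae volume / mitochondrion volume, both reported.
- **Surface area**: marching-cubes iso-surface at 0.5 of the binary field
  smoothed at a *physical* scale (default σ = 8 nm). The physical smoothing
  scale makes the estimate converge as voxel size decreases (the
  voxelization error it suppresses is O(voxel)); with the default the
  digital-ball error falls from ~6% at 20 nm voxels to ~0.1% at 5 nm.
  Voxel-face counting is kept as a cross-check; it overestimates smooth
  surfaces by ~1.5×, so the weighted variant applies the classical 2/3
  isotropic-orientation correction.
- **Surface density**: the denominator convention is ambiguous in common
  usage, so both surface/mito-volume and surface/cristae-volume are emitted.
- **Shape score**: per-voxel second-moment (PCA) tensors of the surrounding
  cristae mass in a Gaussian window (default 40 nm, spanning a cristae
  thickness but not the organelle), eigenvalues λ₁≥λ₂≥λ₃, averaged scores
  planarity = (λ₂−λ₃)/λ₁ and linearity = (λ₁−λ₂)/λ₁. Lamellae score
  planar, tubules linear. Voxels near the cristae boundary see a truncated
  window and bias planarity upward, so "isotropic" objects score ~0.2, not
  0; scores need ≥30 voxels to be reported at all. Scores are invariant to
  axis permutation within ±0.05 on isotropic grids.

## Immuno-gold counting

The reference procedure is manual: particles counted inside hand-drawn
mitochondrial areas. The package ingests manual point lists verbatim and
provides an automatic detector for synthetic validation: intensity
inversion, multiscale Laplacian-of-Gaussian with scales bracketing the known
15 nm diameter, a ±50% equivalent-diameter gate, and intensity-weighted
sub-pixel centroid refinement. A point belongs to a ROI iff the ROI mask is
true at the centroid's pixel (boundary pixels count as inside); overlapping
ROIs require an explicit precedence order. Densities are reported per µm²
(the only place the nm-based units are converted).

## Cycle prediction

Serum P4 is smoothed with a centred moving median over a day-based window
(default 7 days — robust to single-sample EIA noise at three draws per
week), and nadirs are strict interior minima separated by at least
`min_separation` (default 14 days, safely below a 21-day cycle). Nadirs are
reported at sample resolution; the blood-draw cadence does not support
sub-interval precision, which is also why per-cycle lengths quantize to the
sampling interval. The cycle length is the median inter-nadir interval, and
an estimate is "consistent" when the per-cycle spread is ≤ 2 days
(configurable — at 3 draws/week a tolerance of one sampling interval,
2.33 days, is the finest meaningful setting). Scheduling predicts the next
Day 0 as last nadir + median length and emits MF: [−5, −2], CH: [0, 4],
CL: [4, 12] days relative to it; inconsistent estimates refuse to schedule.

## Statistics

Morphometry distributions are skewed mixtures, so the default inference path
is distribution-free: Kruskal–Wallis on midranks with the tie correction,
p from the χ² approximation (df = k−1), then Dunn's z on rank means with the
pooled tie term and two-sided normal p-values. The family-wise adjustment
default is Bonferroni over all k(k−1)/2 pairs (classical Dunn); Holm is
available and is uniformly no larger. For two groups the Dunn z reduces
algebraically to the tie-corrected normal-approximation rank-sum z, which
the tests verify to 1e-10. Classical one-way ANOVA is provided for
completeness but is not the default path. Mitochondria are treated as
independent units; per-animal nesting (mixed models) is a known limitation,
not implemented.

## Synthetic phantoms and what they show

Tube networks are unions of capsules (cylinder + hemispherical caps); a
voxel is foreground iff its centre lies inside the continuous shape. Truth
is analytic, never voxel-derived: volume uses the convention

    V = Σ_edges [πr²L + (4/3)πr³] − Σ_{nodes, deg≥2} Σ_{incident k} (2/3)πr_k³

which is exact for collinear chains and ~3% high at equal-radius Y
junctions (tests budget 5%). Spheres are exact (4/3)πr³. Cristae are
parallel slabs perpendicular to the local tube axis (lamellar) or thin
cylinders on a square lattice (tubular), clipped to the interior, with a
configurable fraction of units carrying the COX density; truth masks are
voxel-exact. Gold particles are hard disks placed uniformly without overlap
inside their ROI. P4 profiles are piecewise-linear rise/plateau/fall
templates — only nadir timing matters downstream.

The default cohort encodes the study design: group sizes 39/22/21/24
(PF/MF/CH/CL); PF and MF as branched 3-arm networks (tube radii
50 ± 8 / 70 ± 10 nm, arms ~500–550 nm, branching probability 0.9); CH as
spheres (210 ± 20 nm); CL as single fat tubes (240 ± 25 nm × ~600 nm). The
radii/volumes are the package's own choice — bar-chart sources print no
numbers — selected once to realize the qualitative pattern (radius and
volume increasing PF→CL, branching collapsing after ovulation) and not
revisited. Gold densities default to 6/30/8/28 particles per µm²
(MF, CL ≫ PF, CH). Phantom noise is Gaussian (σ = 0.1 on a matrix signal of
1.0 over background 0.5); COX adds +2.0, and the default fixed threshold of
2.6 sits between the membrane shell (2.0) and the COX level (3.5).

Passing the recovery tests shows the estimators are correct on clean,
well-resolved geometry with known truth. It does **not** demonstrate
robustness to missing-wedge artefacts, section-joining seams, membrane
segmentation errors, or staining heterogeneity — real-tomogram effects the
generator deliberately does not model (no tilt-series simulation, no CTF).

## Problem sizes and determinism

The validation cohort runs the full 106-mitochondrion design at 15 nm
isotropic voxels (each phantom in its own auto-sized volume, margin twice
the maximal radius) — chosen as the coarsest grid at which the smallest
tubes are still ~7 voxels across. Oracle phantoms use 10 nm voxels. The
statistical calibrations use 2000 null replicates (type-I error) and 200
effect replicates (Dunn power) at the study's group sizes, and cycle
recovery uses 100 simulated animals. All randomness flows from explicit
integer seeds through per-call `numpy` generators; a pipeline run writes a
manifest (config hash + seed) and reproduces its CSVs byte-for-byte.
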