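"""Cristae quantification from COX density inside the eroded OMM mask.

The COX enzyme-histochemistry product is electron dense on active cristae
(and the intermembrane space), so the COX-positive voxel set, clipped to the
organelle interior after eroding away the outer-membrane rim, is taken as
the cristae estimate.  From it this module derives cristae volume, the
cristae/mitochondrion volume ratio, cristae membrane surface area (marching
cubes by default, corrected voxel-face counting as a cross-check), and a
lamellar-versus-tubular shape score from local second-moment eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .types import LabelVolume, VoxelSpacing

__all__ = [
    "CristaeMetrics",
    "erode_omm",
    "cristae_mask",
    "cristae_volume_ratio",
    "cristae_surface_area",
    "cristae_shape_score",
    "quantify_cristae",
]

# plain voxel-face counting overestimates smooth-surface area; 2/3 is the
# classical average correction for isotropically oriented surfaces
FACE_AREA_CORRECTION = 2.0 / 3.0

MIN_SHAPE_SCORE_VOXELS = 30


@dataclass
class CristaeMetrics:
    """Per-mitochondrion cristae readouts.

    Two surface-area-density conventions are reported because the
    denominator ("density" per what?) is a modelling choice: per
    mitochondrion volume and per cristae volume.
    """

    mito_label: int
    stage: str
    cristae_volume_nm3: float
    mito_volume_nm3: float
    volume_ratio: float
    surface_area_nm2: float
    surface_area_density_per_mito: float  # nm^2 / nm^3 of mitochondrion
    surface_area_density_per_cristae: float  # nm^2 / nm^3 of cristae
    planarity: float
    linearity: float
    shape_score_defined: bool


def erode_omm(
    mito_mask: np.ndarray, spacing: VoxelSpacing, erosion_distance_nm: float = 20.0
) -> tuple[np.ndarray, bool]:
    """Shrink a mitochondrion mask inward by a physical distance.

    Removes every voxel within ``erosion_distance_nm`` of the background so
    the outer-membrane / intermembrane rim signal is excluded.  Returns
    (eroded mask, warning flag); the flag is set when erosion exhausted the
    mask.
    """
    if erosion_distance_nm < 0:
        raise ValueError("erosion_distance_nm must be >= 0")
    mask = np.asarray(mito_mask).astype(bool)
    if erosion_distance_nm == 0:
        return mask.copy(), False
    dt = ndimage.distance_transform_edt(mask, sampling=spacing.as_array())
    eroded = dt > erosion_distance_nm
    return eroded, bool(mask.any() and not eroded.any())


def cristae_mask(cox_mask: np.ndarray, eroded_omm_mask: np.ndarray) -> np.ndarray:
    """Cristae voxels = COX-positive voxels inside the eroded OMM."""
    cox_mask = np.asarray(cox_mask).astype(bool)
    eroded_omm_mask = np.asarray(eroded_omm_mask).astype(bool)
    if cox_mask.shape != eroded_omm_mask.shape:
        raise ValueError("cox_mask and eroded_omm_mask shapes differ")
    return cox_mask & eroded_omm_mask


def cristae_volume_ratio(
    cristae: np.ndarray, mito_mask: np.ndarray, spacing: VoxelSpacing
) -> tuple[float, float, float]:
    """Cristae/mitochondrion volume ratio plus both volumes in nm^3.

    Returns (ratio, cristae_volume_nm3, mito_volume_nm3); requires
    cristae to be a subset of the mitochondrion mask.
    """
    cristae = np.asarray(cristae).astype(bool)
    mito_mask = np.asarray(mito_mask).astype(bool)
    if not mito_mask.any():
        raise ValueError("empty mitochondrion mask")
    if np.any(cristae & ~mito_mask):
        raise ValueError("cristae voxels outside the mitochondrion mask")
    vv = spacing.voxel_volume
    cv = float(cristae.sum()) * vv
    mv = float(mito_mask.sum()) * vv
    return cv / mv, cv, mv


def cristae_surface_area(
    cristae: np.ndarray,
    spacing: VoxelSpacing,
    method: str = "mesh",
    smoothing_sigma_nm: float = 8.0,
) -> float:
    """Boundary surface area of a cristae voxel set, in nm^2.

    ``mesh``: marching-cubes iso-surface at 0.5 of the lightly smoothed
    binary field (default).  The smoothing scale is *physical* (default
    8 nm, about half a membrane thickness), so the voxelization error it
    suppresses shrinks as the grid is refined and the estimate converges
    with decreasing voxel size.
    ``weighted_faces``: exposed voxel faces weighted by their physical area
    and the isotropic-orientation correction of 2/3 — a fast cross-check
    that would otherwise overestimate by ~1.5x.
    ``raw_faces``: uncorrected face counting (diagnostics only).
    """
    cristae = np.asarray(cristae).astype(bool)
    if not cristae.any():
        return 0.0
    sp = spacing.as_array()
    if method == "mesh":
        padded = np.pad(cristae, 1).astype(np.float32)
        if smoothing_sigma_nm > 0:
            padded = ndimage.gaussian_filter(padded, smoothing_sigma_nm / sp)
        if padded.max() <= 0.5:  # tiny object smoothed below the iso level
            padded = np.pad(cristae, 1).astype(np.float32)
        verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5, spacing=tuple(sp))
        return float(skmeasure.mesh_surface_area(verts, faces))
    if method in ("weighted_faces", "raw_faces"):
        area = 0.0
        face_areas = {0: sp[1] * sp[2], 1: sp[0] * sp[2], 2: sp[0] * sp[1]}
        for axis in range(3):
            p = np.pad(
                cristae,
                [(1, 1) if a == axis else (0, 0) for a in range(3)],
            )
            diff = np.diff(p.astype(np.int8), axis=axis)
            area += float(np.abs(diff).sum()) * face_areas[axis]
        if method == "weighted_faces":
            area *= FACE_AREA_CORRECTION
        return area
    raise ValueError(f"unknown surface-area method {method!r}")


def cristae_shape_score(
    cristae: np.ndarray,
    spacing: VoxelSpacing,
    neighborhood_radius_nm: float = 40.0,
) -> tuple[float, float, bool]:
    """Lamellar-vs-tubular score from local shape-tensor eigenvalues.

    For each cristae voxel, the second-moment (covariance) tensor of the
    surrounding cristae mass inside a Gaussian window of scale
    ``neighborhood_radius_nm`` is computed; with eigenvalues
    l1 >= l2 >= l3:

    * ``linearity  = (l1 - l2) / l1`` — large for tubules (one long axis);
    * ``planarity  = (l2 - l3) / l1`` — large for lamellae (two long axes).

    Both lie in [0, 1] and sum to at most 1.  Scores are averaged over the
    cristae voxels.  Returns (planarity, linearity, defined); ``defined``
    is False when fewer than 30 cristae voxels exist.
    """
    cristae = np.asarray(cristae).astype(bool)
    n = int(cristae.sum())
    if n < MIN_SHAPE_SCORE_VOXELS:
        return float("nan"), float("nan"), False
    sp = spacing.as_array()
    sigmas = neighborhood_radius_nm / sp  # in voxels, per axis

    f = cristae.astype(np.float64)
    # centred physical coordinates: shifts leave the covariance unchanged and
    # keep the moment accumulators well-conditioned
    coords = [
        (np.arange(s, dtype=np.float64) - s / 2.0) * sp[a]
        for a, s in enumerate(cristae.shape)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    axes_nm = (zz, yy, xx)

    w = ndimage.gaussian_filter(f, sigmas)
    first = [ndimage.gaussian_filter(f * axes_nm[a], sigmas) for a in range(3)]
    second = {}
    for a in range(3):
        for b in range(a, 3):
            second[(a, b)] = ndimage.gaussian_filter(f * axes_nm[a] * axes_nm[b], sigmas)

    sel = cristae & (w > 1e-8)
    wsel = w[sel]
    mu = [first[a][sel] / wsel for a in range(3)]
    cov = np.empty((int(sel.sum()), 3, 3), dtype=np.float64)
    for a in range(3):
        for b in range(a, 3):
            c = second[(a, b)][sel] / wsel - mu[a] * mu[b]
            cov[:, a, b] = c
            cov[:, b, a] = c
    evals = np.linalg.eigvalsh(cov)  # ascending: l3, l2, l1
    evals = np.clip(evals, 0.0, None)
    l3, l2, l1 = evals[:, 0], evals[:, 1], evals[:, 2]
    valid = l1 > 1e-12
    planarity = float(np.mean((l2[valid] - l3[valid]) / l1[valid]))
    linearity = float(np.mean((l1[valid] - l2[valid]) / l1[valid]))
    return planarity, linearity, True


def quantify_cristae(
    labels: LabelVolume,
    cox_mask: np.ndarray,
    erosion_distance_nm: float = 20.0,
    surface_method: str = "mesh",
    neighborhood_radius_nm: float = 40.0,
    selected_labels: list[int] | None = None,
) -> list[CristaeMetrics]:
    """Full cristae quantification for each (selected) mitochondrion."""
    spacing = labels.spacing
    out: list[CristaeMetrics] = []
    for lbl in selected_labels if selected_labels is not None else labels.labels:
        mito = labels.mask(lbl)
        eroded, _warn = erode_omm(mito, spacing, erosion_distance_nm)
        cr = cristae_mask(cox_mask, eroded)
        ratio, cv, mv = cristae_volume_ratio(cr, mito, spacing)
        area = cristae_surface_area(cr, spacing, method=surface_method)
        planarity, linearity, defined = cristae_shape_score(
            cr, spacing, neighborhood_radius_nm
        )
        out.append(
            CristaeMetrics(
                mito_label=lbl,
                stage=labels.label_table.get(lbl, ""),
                cristae_volume_nm3=cv,
                mito_volume_nm3=mv,
                volume_ratio=ratio,
                surface_area_nm2=area,
                surface_area_density_per_mito=area / mv if mv else float("nan"),
                surface_area_density_per_cristae=area / cv if cv else float("nan"),
                planarity=planarity,
                linearity=linearity,
                shape_score_defined=defined,
            )
        )
    return out
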