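"""Labelling and inclusion/exclusion rules for mitochondrial volumes.

Manual masks (the study's OMM definitions) are trusted verbatim when imported
as label volumes; these operations cover the automatic parts of the workflow:
connected-component labelling of binary masks, exclusion of small mitochondria
without clearly defined volumes, per-tomogram COX density thresholding, and
selection of COX-abundant mitochondria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .types import DensityVolume, LabelVolume, VoxelSpacing

__all__ = [
    "SegmentationParams",
    "label_components",
    "exclude_small",
    "threshold_cox",
    "select_cox_abundant",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SegmentationParams:
    """Thresholds behind the inclusion/exclusion and COX rules.

    ``min_volume_nm3``/``min_z_span`` operationalize "small mitochondria
    without clearly defined volumes": an object must reach both to be kept.
    The COX threshold is per tomogram — one scalar for the whole volume —
    either fixed or Otsu-derived; ``cox_abundance_fraction`` is the minimum
    COX-positive fraction of a mitochondrion's eroded interior for it to
    count as COX-abundant ("most cristae stained" -> 0.5).
    """

    connectivity: int = 26
    min_volume_nm3: float = 1.0e6
    min_z_span: int = 2
    cox_threshold_method: str = "fixed"  # fixed | otsu
    cox_threshold_value: float = 1.0
    cox_abundance_fraction: float = 0.5
    interior_erosion_nm: float = 20.0

    def __post_init__(self) -> None:
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.min_volume_nm3 < 0:
            raise ValueError("min_volume_nm3 must be >= 0")
        if not 0.0 <= self.cox_abundance_fraction <= 1.0:
            raise ValueError("cox_abundance_fraction must lie in [0, 1]")


def label_components(
    mask: np.ndarray,
    connectivity: int = 26,
    spacing: VoxelSpacing | None = None,
) -> LabelVolume:
    """Label physically connected foreground components.

    Mitochondria without physical connections get different labels;
    background stays 0.  An empty mask yields a valid zero-label volume.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    if spacing is None:
        spacing = VoxelSpacing(1.0, 1.0, 1.0)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, _n = ndimage.label(mask, structure=structure)
    return LabelVolume(labels.astype(np.int32), spacing)


@dataclass
class ExclusionRecord:
    label: int
    voxel_count: int
    volume_nm3: float
    z_span: int
    kept: bool
    new_label: int | None


def exclude_small(
    labels: LabelVolume, params: SegmentationParams
) -> tuple[LabelVolume, list[ExclusionRecord]]:
    """Drop labels below the volume or z-span thresholds; re-index survivors.

    Returns the filtered volume (labels renumbered consecutively from 1 in
    ascending original order) and a removal log.  Idempotent: running it
    twice removes nothing new.
    """
    vox = labels.voxels
    voxel_volume = labels.spacing.voxel_volume
    log: list[ExclusionRecord] = []
    mapping = np.zeros(int(vox.max()) + 1, dtype=np.int32)
    next_label = 1
    for lbl in labels.labels:
        where = vox == lbl
        count = int(where.sum())
        z_present = np.nonzero(where.any(axis=(1, 2)))[0]
        z_span = int(z_present[-1] - z_present[0] + 1) if len(z_present) else 0
        volume = count * voxel_volume
        kept = volume >= params.min_volume_nm3 and z_span >= params.min_z_span
        new = next_label if kept else None
        if kept:
            mapping[lbl] = next_label
            next_label += 1
        log.append(ExclusionRecord(lbl, count, volume, z_span, kept, new))
    out = mapping[vox]
    table = {
        rec.new_label: labels.label_table.get(rec.label, "")
        for rec in log
        if rec.kept and rec.new_label is not None
    }
    return LabelVolume(out.astype(np.int32), labels.spacing, table), log


def threshold_cox(
    volume: DensityVolume, params: SegmentationParams
) -> tuple[np.ndarray, float]:
    """Binarize COX density with one scalar threshold per tomogram.

    Positive signal is *strictly above* the threshold.  With
    ``method='otsu'`` the threshold is derived from the volume's own
    histogram; a constant-valued volume then has no defined threshold and is
    an error.  Returns (mask, threshold used).
    """
    data = volume.voxels
    if params.cox_threshold_method == "fixed":
        thr = float(params.cox_threshold_value)
    elif params.cox_threshold_method == "otsu":
        if float(data.max()) == float(data.min()):
            raise ValueError("Otsu threshold undefined on a constant-valued volume")
        thr = float(threshold_otsu(np.asarray(data, dtype=np.float64)))
    else:
        raise ValueError(f"unknown cox_threshold_method {params.cox_threshold_method!r}")
    return data > thr, thr


def select_cox_abundant(
    labels: LabelVolume,
    cox_mask: np.ndarray,
    params: SegmentationParams,
    cristae_mask: np.ndarray | None = None,
) -> tuple[list[int], dict[int, float]]:
    """Keep mitochondria where most cristae carry COX signal.

    The assessed region is the label's eroded interior (erosion by
    ``params.interior_erosion_nm`` physical distance strips the membrane rim
    where intermembrane-space signal sits), intersected with
    ``cristae_mask`` when a cristae truth or estimate is available.  A label
    is kept when the COX-positive fraction of that region reaches
    ``params.cox_abundance_fraction`` ("most cristae stained" -> 0.5);
    labels whose assessed region is empty are excluded with a NaN fraction.

    Returns (selected label ids, per-label COX fraction).
    """
    if cox_mask.shape != labels.voxels.shape:
        raise ValueError("cox_mask and labels must share a shape")
    sp = labels.spacing.as_array()
    fractions: dict[int, float] = {}
    selected: list[int] = []
    for lbl in labels.labels:
        mask = labels.voxels == lbl
        if params.interior_erosion_nm > 0:
            interior = ndimage.distance_transform_edt(mask, sampling=sp) > params.interior_erosion_nm
        else:
            interior = mask
        if cristae_mask is not None:
            interior = interior & np.asarray(cristae_mask, dtype=bool)
        n_int = int(interior.sum())
        if n_int == 0:
            fractions[lbl] = float("nan")
            continue
        frac = float((cox_mask & interior).sum()) / n_int
        fractions[lbl] = frac
        if frac >= params.cox_abundance_fraction:
            selected.append(lbl)
    return selected, fractions
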