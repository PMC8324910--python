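"""Immuno-gold particle counting on 2D TEM micrographs.

ATP synthase (ATP5A) is detected with 15 nm gold conjugates; particle density
per mitochondrial area proxies respiratory-enzyme content.  The study counted
particles manually inside hand-drawn mitochondrial ROIs, so two paths are
offered: ingesting an annotated point list verbatim, and an automatic
dark-blob detector (Laplacian-of-Gaussian with a diameter prior) for
validation on synthetic micrographs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import blob_log

__all__ = ["GoldROI", "detect_gold_particles", "count_in_rois", "read_points_csv"]

NM2_PER_UM2 = 1.0e6


@dataclass
class GoldROI:
    """One manually delimited mitochondrial area on a micrograph."""

    roi_id: int
    mask: np.ndarray  # 2D bool
    stage: str = ""
    area_nm2: float = 0.0
    particle_count: int = 0

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / NM2_PER_UM2

    @property
    def density_per_um2(self) -> float:
        if self.area_nm2 <= 0:
            return float("nan")
        return self.particle_count / self.area_um2


def detect_gold_particles(
    image: np.ndarray,
    pixel_size_nm: float,
    diameter_nm: float = 15.0,
    threshold_rel: float = 0.3,
    diameter_tolerance: float = 0.5,
) -> np.ndarray:
    """Detect dark disk-shaped particles of a known physical diameter.

    The image is inverted (gold is electron dense, i.e. dark) and scanned
    with a multiscale Laplacian-of-Gaussian blob detector centred on the
    expected particle scale; blobs whose equivalent diameter falls outside
    ``(1 +/- diameter_tolerance)`` of the prior are discarded.  Centroids are
    refined to sub-pixel precision by intensity-weighted averaging inside
    the particle footprint.  Returns an (n, 2) array of (row, col) centers.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    diameter_px = diameter_nm / pixel_size_nm
    if diameter_px < 2:
        raise ValueError("particles below 2 px cannot be detected")
    img = np.asarray(image, dtype=np.float64)
    inverted = img.max() - img
    span = inverted.max() - inverted.min()
    if span <= 0:
        return np.empty((0, 2))
    inverted /= span

    sigma0 = diameter_px / (2.0 * np.sqrt(2.0))  # LoG scale of a disk
    blobs = blob_log(
        inverted,
        min_sigma=sigma0 * (1 - diameter_tolerance * 0.8),
        max_sigma=sigma0 * (1 + diameter_tolerance * 0.8),
        num_sigma=7,
        threshold=threshold_rel * 0.5,
        overlap=0.3,
    )
    centers = []
    radius_px = diameter_px / 2.0
    rows = np.arange(img.shape[0])[:, None]
    cols = np.arange(img.shape[1])[None, :]
    for r, c, sigma in blobs:
        eq_diameter = 2.0 * np.sqrt(2.0) * sigma
        if not (1 - diameter_tolerance) * diameter_px <= eq_diameter <= (
            1 + diameter_tolerance
        ) * diameter_px:
            continue
        # sub-pixel refinement on the inverted intensity
        rr = slice(max(0, int(r - radius_px)), int(r + radius_px) + 2)
        cc = slice(max(0, int(c - radius_px)), int(c + radius_px) + 2)
        patch = inverted[rr, cc]
        if patch.sum() <= 0:
            centers.append((float(r), float(c)))
            continue
        pr = rows[rr, :].astype(float)
        pc = cols[:, cc].astype(float)
        w = patch - patch.min()
        if w.sum() <= 0:
            centers.append((float(r), float(c)))
            continue
        centers.append(
            (
                float((w * pr).sum() / w.sum()),
                float((w * pc).sum() / w.sum()),
            )
        )
    return np.array(centers, dtype=float).reshape(-1, 2)


def count_in_rois(
    points: np.ndarray,
    rois: list[GoldROI],
    pixel_size_nm: float,
    precedence: list[int] | None = None,
) -> tuple[list[GoldROI], np.ndarray]:
    """Assign particle centers to ROIs and fill counts and densities.

    A point belongs to a ROI iff the ROI mask is True at the pixel containing
    its centroid (boundary pixels count as inside).  Overlapping ROIs are an
    error unless ``precedence`` (an ordering of roi_ids, first wins) is
    given.  Returns (filled ROIs, points assigned to no ROI).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if not rois:
        return [], points
    shape = rois[0].mask.shape
    overlap_free = np.zeros(shape, dtype=np.int32)
    for roi in rois:
        if roi.mask.shape != shape:
            raise ValueError("ROI masks must share the image frame")
        overlap_free += roi.mask.astype(np.int32)
    if (overlap_free > 1).any() and precedence is None:
        raise ValueError(
            "ROIs overlap; supply a precedence order (list of roi_ids) to resolve"
        )
    order = (
        sorted(rois, key=lambda r: precedence.index(r.roi_id))
        if precedence is not None
        else list(rois)
    )
    claimed = np.full(shape, -1, dtype=np.int64)
    for roi in reversed(order):  # first in precedence claims last -> wins
        claimed[roi.mask.astype(bool)] = roi.roi_id

    counts: dict[int, int] = {r.roi_id: 0 for r in rois}
    unassigned = []
    for p in points:
        rr, cc = int(round(p[0])), int(round(p[1]))
        if 0 <= rr < shape[0] and 0 <= cc < shape[1] and claimed[rr, cc] >= 0:
            counts[int(claimed[rr, cc])] += 1
        else:
            unassigned.append(p)
    px_area_nm2 = pixel_size_nm**2
    for roi in rois:
        roi.particle_count = counts[roi.roi_id]
        roi.area_nm2 = float(roi.mask.sum()) * px_area_nm2
    return rois, np.array(unassigned, dtype=float).reshape(-1, 2)


def read_points_csv(path) -> np.ndarray:
    """Read a manually annotated particle list (columns row, col)."""
    df = pd.read_csv(path)
    if not {"row", "col"} <= set(df.columns):
        raise ValueError("points CSV needs 'row' and 'col' columns")
    return df[["row", "col"]].to_numpy(float)


def rois_to_frame(rois: list[GoldROI]) -> pd.DataFrame:
    """Per-ROI result table (id, stage, area, count, density)."""
    return pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in rois],
            "stage": [r.stage for r in rois],
            "area_um2": [r.area_um2 for r in rois],
            "count": [r.particle_count for r in rois],
            "density_per_um2": [r.density_per_um2 for r in rois],
        }
    )
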