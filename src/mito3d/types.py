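"""Core containers shared across the pipeline.

All voxel grids use axis order ``(z, y, x)`` with 0-based indexing; physical
coordinates are in nanometres throughout, with voxel ``(k, j, i)`` centred at
``(k*dz, j*dy, i*dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelSpacing", "DensityVolume", "LabelVolume"]


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel edge lengths in nm along (z, y, x).

    ``dz`` may exceed ``dx``/``dy`` — serial-section tomograms are commonly
    reconstructed from 200 nm sections with ~1-10 nm in-plane sampling.
    """

    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        if not (self.dz > 0 and self.dy > 0 and self.dx > 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self}")

    def as_array(self) -> np.ndarray:
        """Spacing as an array ordered like the volume axes (z, y, x)."""
        return np.array([self.dz, self.dy, self.dx], dtype=float)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in nm^3."""
        return self.dz * self.dy * self.dx

    @property
    def anisotropy(self) -> float:
        """Ratio of the largest to the smallest spacing (1.0 = isotropic)."""
        a = self.as_array()
        return float(a.max() / a.min())


@dataclass
class DensityVolume:
    """A 3D scalar voxel grid (tomogram density or synthetic phantom)."""

    voxels: np.ndarray
    spacing: VoxelSpacing
    provenance: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("DensityVolume requires a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("DensityVolume voxels must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """Integer-labelled voxel grid: 0 = background, one label per physically
    connected mitochondrion.

    ``label_table`` maps label id -> stage tag (free text, e.g. "PF", "CL");
    labels absent from the table are untagged.
    """

    voxels: np.ndarray
    spacing: VoxelSpacing
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("LabelVolume requires a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("LabelVolume voxels must be integer-typed")
        if self.voxels.min() < 0:
            raise ValueError("LabelVolume voxels must be non-negative")

    @property
    def labels(self) -> list[int]:
        """Sorted list of positive labels present in the volume."""
        vals = np.unique(self.voxels)
        return [int(v) for v in vals if v > 0]

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of one mitochondrion."""
        return self.voxels == label

    def foreground(self) -> np.ndarray:
        return self.voxels > 0
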