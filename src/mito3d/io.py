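"""Volume I/O: MRC2014 and multipage TIFF with a JSON spacing sidecar.

The MRC2014 header stores the cell dimensions in Angstrom; spacing is
converted to/from nm on the way through (1 nm = 10 A). TIFF carries no
trustworthy 3D spacing, so TIFF volumes require a ``<path>.json`` sidecar
with ``{"spacing_nm": [dz, dy, dx]}`` — a missing sidecar is an error, never
a silent default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .types import DensityVolume, LabelVolume, VoxelSpacing

__all__ = ["read_volume", "write_volume", "read_mrc", "write_mrc"]

_MRC_HEADER_BYTES = 1024
# MRC mode -> dtype for the modes this package reads/writes
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def _build_mrc_header(data: np.ndarray, spacing: VoxelSpacing, mode: int) -> bytes:
    nz, ny, nx = data.shape
    h = np.zeros(256, dtype=np.int32)
    h[0:3] = (nx, ny, nz)
    h[3] = mode
    h[7:10] = (nx, ny, nz)  # mx, my, mz: sampling grid = full cell
    cella = np.array(
        [nx * spacing.dx * 10.0, ny * spacing.dy * 10.0, nz * spacing.dz * 10.0],
        dtype=np.float32,
    )
    h.view(np.float32)[10:13] = cella
    h.view(np.float32)[13:16] = 90.0  # cell angles
    h[16:19] = (1, 2, 3)  # mapc, mapr, maps: columns=x, rows=y, sections=z
    stats = h.view(np.float32)
    stats[19] = float(data.min())
    stats[20] = float(data.max())
    stats[21] = float(data.mean())
    h[27] = 20140  # NVERSION: MRC2014 format, version 0
    raw = bytearray(h.tobytes())
    raw[208:212] = b"MAP "
    raw[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian machine stamp
    return bytes(raw)


def write_mrc(data: np.ndarray, spacing: VoxelSpacing, path: str | Path) -> None:
    """Write a (z, y, x) array as MRC2014.

    Float data is stored as float32 (mode 2); integer labels as int16
    (mode 1) when they fit, else uint16 (mode 6).
    """
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("MRC writer expects a 3D array")
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.int64)
        if data.max() <= np.iinfo(np.int16).max and data.min() >= 0:
            out, mode = data.astype(np.int16), 1
        elif data.max() <= np.iinfo(np.uint16).max and data.min() >= 0:
            out, mode = data.astype(np.uint16), 6
        else:
            raise ValueError("integer labels exceed 16-bit MRC modes")
    else:
        out, mode = data.astype(np.float32), 2
    with open(path, "wb") as fh:
        fh.write(_build_mrc_header(out, spacing, mode))
        # MRC stores x fastest, then y, then z: C-order (z, y, x) matches.
        fh.write(np.ascontiguousarray(out).tobytes())


def read_mrc(path: str | Path) -> tuple[np.ndarray, VoxelSpacing]:
    """Read an MRC2014 file, returning ((z, y, x) array, spacing in nm)."""
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise ValueError(f"{path}: truncated MRC header")
    h = np.frombuffer(raw[:_MRC_HEADER_BYTES], dtype=np.int32)
    nx, ny, nz, mode = (int(v) for v in h[0:4])
    if mode not in _MODE_DTYPES:
        raise ValueError(f"{path}: unsupported MRC mode {mode}")
    mx, my, mz = (int(v) for v in h[7:10])
    cella = h.view(np.float32)[10:13]
    if min(mx, my, mz) <= 0 or min(cella) <= 0:
        raise ValueError(f"{path}: MRC header lacks voxel-size information")
    # cell is in Angstrom; /10 converts to nm
    spacing = VoxelSpacing(
        dz=float(cella[2]) / mz / 10.0,
        dy=float(cella[1]) / my / 10.0,
        dx=float(cella[0]) / mx / 10.0,
    )
    nsymbt = int(h[23])
    dtype = _MODE_DTYPES[mode]
    count = nx * ny * nz
    data = np.frombuffer(
        raw, dtype=dtype, count=count, offset=_MRC_HEADER_BYTES + nsymbt
    ).reshape(nz, ny, nx)
    return data.copy(), spacing


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: DensityVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as MRC2014 (.mrc/.rec) or multipage TIFF (.tif/.tiff).

    TIFF output gains a JSON sidecar carrying the nm spacing (and the label
    table for :class:`LabelVolume`).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".rec"):
        write_mrc(volume.voxels, volume.spacing, path)
        if isinstance(volume, LabelVolume) and volume.label_table:
            meta = {"label_table": {str(k): v for k, v in volume.label_table.items()}}
            _sidecar_path(path).write_text(json.dumps(meta))
    elif suffix in (".tif", ".tiff"):
        data = volume.voxels
        if data.dtype == bool:
            data = data.astype(np.uint8)
        tifffile.imwrite(path, data, photometric="minisblack")
        meta: dict = {"spacing_nm": list(volume.spacing.as_array())}
        if isinstance(volume, LabelVolume):
            meta["label_table"] = {str(k): v for k, v in volume.label_table.items()}
        _sidecar_path(path).write_text(json.dumps(meta))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(path: str | Path, kind: str = "auto") -> DensityVolume | LabelVolume:
    """Read MRC2014 or TIFF(+sidecar) into a volume container.

    ``kind``: "density", "label", or "auto" (integer data -> LabelVolume).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    label_table: dict[int, str] = {}
    if suffix in (".mrc", ".rec"):
        data, spacing = read_mrc(path)
        sc = _sidecar_path(path)
        if sc.exists():
            meta = json.loads(sc.read_text())
            label_table = {int(k): v for k, v in meta.get("label_table", {}).items()}
    elif suffix in (".tif", ".tiff"):
        sc = _sidecar_path(path)
        if not sc.exists():
            raise ValueError(
                f"{path}: TIFF volumes need a '{sc.name}' sidecar with spacing_nm "
                "[dz, dy, dx]; none found"
            )
        meta = json.loads(sc.read_text())
        if "spacing_nm" not in meta:
            raise ValueError(f"{sc}: sidecar lacks 'spacing_nm'")
        dz, dy, dx = (float(v) for v in meta["spacing_nm"])
        spacing = VoxelSpacing(dz=dz, dy=dy, dx=dx)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        label_table = {int(k): v for k, v in meta.get("label_table", {}).items()}
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")

    is_int = np.issubdtype(data.dtype, np.integer)
    if kind == "label" or (kind == "auto" and is_int):
        return LabelVolume(data.astype(np.int32), spacing, label_table)
    return DensityVolume(np.asarray(data, dtype=np.float32), spacing, provenance=str(path))
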