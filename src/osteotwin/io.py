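"""Image I/O for voxel grids: multipage TIFF and MHD+RAW pairs.

Both formats round-trip the tissue labels and the mineral-density channel
losslessly.

TIFF
    A single multipage file with two stacked channels: the first ``nz``
    pages are the uint8 tissue labels, the next ``nz`` pages the float32
    mineral fraction.  Grid metadata (voxel size, shape, maximum mineral
    density) is stored as JSON in the ImageDescription tag.

MHD+RAW
    Uncompressed little-endian MetaImage pairs: ``<stem>.mhd``/``.raw``
    hold the tissue labels, ``<stem>_density.mhd``/``.raw`` the mineral
    fraction.  Spacing must be isotropic.

An 8-bit binary mask (single-channel TIFF, or MHD without a density
companion) is read as MARROW/BONE with the mineral fraction initialized to
``default_mineral`` everywhere in bone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .grid import BONE, MARROW, VoxelGrid

_MHD_DTYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MHD_NAMES = {np.dtype(np.uint8): "MET_UCHAR", np.dtype(np.float32): "MET_FLOAT"}


def write_image(path: str | Path, grid: VoxelGrid) -> None:
    """Write a grid to ``path`` (.tif/.tiff or .mhd inferred from suffix)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        _write_tiff(path, grid)
    elif suffix == ".mhd":
        _write_mhd(path, grid)
    else:
        raise ValueError(f"unsupported image format: {suffix!r}")


def read_image(path: str | Path, default_mineral: float = 1.0) -> VoxelGrid:
    """Read a grid written by :func:`write_image` or a plain binary mask."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _read_tiff(path, default_mineral)
    if suffix == ".mhd":
        return _read_mhd(path, default_mineral)
    raise ValueError(f"unsupported image format: {suffix!r}")


# ----------------------------------------------------------------------
# TIFF
# ----------------------------------------------------------------------

def _write_tiff(path: Path, grid: VoxelGrid) -> None:
    nz = grid.shape[0]
    meta = {
        "osteotwin": 1,
        "voxel_size_mm": grid.voxel_size,
        "nz": nz,
        "max_mineral_density": grid.max_mineral_density,
    }
    with tifffile.TiffWriter(path) as tw:
        tw.write(grid.tissue, description=json.dumps(meta), photometric="minisblack")
        tw.write(grid.mineral.astype(np.float32), photometric="minisblack")


def _read_tiff(path: Path, default_mineral: float) -> VoxelGrid:
    with tifffile.TiffFile(path) as tf:
        desc = tf.series[0].pages[0].description or ""
        data = [s.asarray() for s in tf.series]
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if meta.get("osteotwin"):
        if "voxel_size_mm" not in meta:
            raise ValueError("missing spacing metadata: voxel_size_mm")
        tissue = np.asarray(data[0], dtype=np.uint8)
        if len(data) < 2:
            raise ValueError("missing mineral-density channel")
        mineral = np.asarray(data[1], dtype=np.float64)
        return VoxelGrid(
            tissue=tissue,
            voxel_size=float(meta["voxel_size_mm"]),
            mineral=mineral,
            max_mineral_density=float(
                meta.get("max_mineral_density", VoxelGrid.max_mineral_density)
            ),
        )
    # plain 8-bit mask: nonzero -> BONE at default mineral
    raise ValueError(
        "missing spacing metadata: voxel_size_mm (use read_mask for plain masks)"
    )


def read_mask(
    path: str | Path, voxel_size: float, default_mineral: float = 1.0
) -> VoxelGrid:
    """Read an 8-bit binary mask (TIFF) as MARROW/BONE with given spacing."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    tissue = np.where(arr != 0, BONE, MARROW).astype(np.uint8)
    mineral = np.where(tissue != MARROW, float(default_mineral), 0.0)
    return VoxelGrid(tissue=tissue, voxel_size=voxel_size, mineral=mineral)


# ----------------------------------------------------------------------
# MHD + RAW
# ----------------------------------------------------------------------

def _write_mhd_pair(path: Path, array: np.ndarray, voxel_size: float, extra: dict) -> None:
    raw = path.with_suffix(".raw")
    dtype = np.dtype(array.dtype)
    header = {
        "ObjectType": "Image",
        "NDims": 3,
        "BinaryData": "True",
        "BinaryDataByteOrderMSB": "False",
        "DimSize": f"{array.shape[2]} {array.shape[1]} {array.shape[0]}",
        "ElementSpacing": f"{voxel_size} {voxel_size} {voxel_size}",
        "ElementType": _MHD_NAMES[dtype],
        "ElementDataFile": raw.name,
    }
    header.update(extra)
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"{k} = {v}\n")
    array.astype(dtype.newbyteorder("<")).tofile(raw)


def _write_mhd(path: Path, grid: VoxelGrid) -> None:
    _write_mhd_pair(
        path,
        grid.tissue,
        grid.voxel_size,
        {"OsteotwinMaxMineralDensity": grid.max_mineral_density},
    )
    dpath = path.with_name(path.stem + "_density.mhd")
    _write_mhd_pair(dpath, grid.mineral.astype(np.float32), grid.voxel_size, {})


def _parse_mhd(path: Path) -> tuple[np.ndarray, float, dict]:
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                header[k.strip()] = v.strip()
    for required in ("DimSize", "ElementType", "ElementDataFile"):
        if required not in header:
            raise ValueError(f"malformed MHD header: missing {required}")
    if "ElementSpacing" not in header:
        raise ValueError("missing spacing metadata: ElementSpacing")
    spacing = [float(s) for s in header["ElementSpacing"].split()]
    if len(set(spacing)) != 1:
        raise ValueError(f"non-isotropic spacing: {spacing}")
    nx, ny, nz = (int(s) for s in header["DimSize"].split())
    dtype = _MHD_DTYPES.get(header["ElementType"])
    if dtype is None:
        raise ValueError(f"malformed MHD header: ElementType {header['ElementType']}")
    raw = path.parent / header["ElementDataFile"]
    arr = np.fromfile(raw, dtype=np.dtype(dtype).newbyteorder("<")).reshape(nz, ny, nx)
    return arr, spacing[0], header


def _read_mhd(path: Path, default_mineral: float) -> VoxelGrid:
    tissue_arr, voxel_size, header = _parse_mhd(path)
    dpath = path.with_name(path.stem + "_density.mhd")
    if dpath.exists():
        mineral_arr, dsp, _ = _parse_mhd(dpath)
        if abs(dsp - voxel_size) > 1e-12:
            raise ValueError("tissue/density spacing mismatch")
        mineral = np.asarray(mineral_arr, dtype=np.float64)
        tissue = np.asarray(tissue_arr, dtype=np.uint8)
    else:
        tissue = np.where(tissue_arr != 0, BONE, MARROW).astype(np.uint8)
        mineral = np.where(tissue != MARROW, float(default_mineral), 0.0)
    max_density = float(
        header.get("OsteotwinMaxMineralDensity", VoxelGrid.max_mineral_density)
    )
    return VoxelGrid(
        tissue=tissue,
        voxel_size=voxel_size,
        mineral=mineral,
        max_mineral_density=max_density,
    )
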