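"""Readers and writers for point clouds, rasters, tree tables and configs.

Point clouds: plain XYZ text (whitespace or comma delimited, optional
header) and uncompressed LAS. The LAS support is deliberately minimal:
x, y, z and the classification byte are the only attributes guaranteed,
which is all the segmentation pipeline consumes. LAZ is not supported.

Rasters: ESRI ASCII grid and single-band GeoTIFF (via tifffile, with
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import PointCloud, RasterGrid

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_tree_table",
    "write_tree_table",
    "read_raster",
    "write_raster",
    "write_labels_csv",
    "read_config",
    "write_config",
]

GROUND_CLASS = 2  # ASPRS standard ground classification code


class FormatError(ValueError):
    """Raised when a file cannot be parsed under its declared format."""


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def read_point_cloud(path, fmt: str | None = None) -> PointCloud:
    """Read a point cloud from LAS or delimited XYZ text.

    Parameters
    ----------
    path : path-like
    fmt : {"las", "laz", "xyz"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".") or "xyz"
    fmt = fmt.lower()
    if fmt == "laz":
        raise FormatError("LAZ (compressed LAS) is not supported; decompress to LAS first")
    if fmt == "las":
        return _read_las(path)
    if fmt in ("xyz", "txt", "csv", "pts"):
        return _read_xyz(path)
    raise FormatError(f"unknown point-cloud format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".") or "xyz"
    fmt = fmt.lower()
    if fmt == "las":
        _write_las(cloud, path)
    elif fmt in ("xyz", "txt", "csv", "pts"):
        _write_xyz(cloud, path, delimiter="," if fmt == "csv" else " ")
    else:
        raise FormatError(f"unknown point-cloud format {fmt!r}")


def _read_xyz(path: Path) -> PointCloud:
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: no points in file")
    delim = "," if "," in lines[0] else None
    start = 0
    first = lines[0].replace(",", " ").split()
    try:
        float(first[0])
    except ValueError:
        start = 1  # header row detected by non-numeric first token
    if start >= len(lines):
        raise FormatError(f"{path}: no points in file")
    rows = []
    for ln in lines[start:]:
        parts = ln.split(delim) if delim else ln.split()
        if len(parts) < 3:
            raise FormatError(f"{path}: expected at least 3 columns, got {ln!r}")
        rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
    arr = np.asarray(rows, dtype=np.float64)
    return PointCloud(arr[:, 0], arr[:, 1], arr[:, 2])


def _write_xyz(cloud: PointCloud, path: Path, delimiter: str = " ") -> None:
    arr = cloud.xyz
    np.savetxt(path, arr, fmt="%.6f", delimiter=delimiter)


# -- LAS ------------------------------------------------------------------
# Minimal uncompressed LAS support. Read: versions 1.2-1.4, point record
# formats 0-10 (x, y, z, classification only). Write: LAS 1.2, format 0.

_CLASSIFICATION_OFFSET = {0: 15, 1: 15, 2: 15, 3: 15, 4: 15, 5: 15,
                          6: 16, 7: 16, 8: 16, 9: 16, 10: 16}


def _read_las(path: Path) -> PointCloud:
    data = path.read_bytes()
    if data[:4] != b"LASF":
        raise FormatError(f"{path}: not a LAS file (bad signature)")
    ver_major, ver_minor = data[24], data[25]
    point_offset = struct.unpack_from("<I", data, 96)[0]
    fmt_id = data[104]
    if fmt_id >= 128:
        raise FormatError(f"{path}: LAZ-compressed points are not supported")
    rec_len = struct.unpack_from("<H", data, 105)[0]
    count = struct.unpack_from("<I", data, 107)[0]
    if count == 0 and ver_major == 1 and ver_minor >= 4 and len(data) >= 255:
        count = struct.unpack_from("<Q", data, 247)[0]
    sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", data, 131)
    if count == 0:
        raise FormatError(f"{path}: LAS file contains zero points")
    if fmt_id not in _CLASSIFICATION_OFFSET:
        raise FormatError(f"{path}: unsupported LAS point format {fmt_id}")
    raw = np.frombuffer(
        data, dtype=np.uint8, count=count * rec_len, offset=point_offset
    ).reshape(count, rec_len)
    xyz_int = raw[:, :12].copy().view("<i4").reshape(count, 3)
    x = xyz_int[:, 0] * sx + ox
    y = xyz_int[:, 1] * sy + oy
    z = xyz_int[:, 2] * sz + oz
    cls = raw[:, _CLASSIFICATION_OFFSET[fmt_id]]
    if fmt_id <= 5:
        cls = cls & 0x1F  # classification is the low 5 bits in legacy formats
    ground = cls == GROUND_CLASS
    return PointCloud(x, y, z, ground=ground if ground.any() else None)


def _write_las(cloud: PointCloud, path: Path) -> None:
    n = cloud.n
    scale = 0.001
    ox, oy, oz = float(cloud.x.min()), float(cloud.y.min()), float(cloud.z.min())
    header = bytearray(227)
    header[0:4] = b"LASF"
    header[24] = 1
    header[25] = 2  # LAS 1.2
    struct.pack_into("<H", header, 94, 227)  # header size
    struct.pack_into("<I", header, 96, 227)  # offset to point data
    header[104] = 0  # point data record format 0
    struct.pack_into("<H", header, 105, 20)  # record length
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<6d", header, 131, scale, scale, scale, ox, oy, oz)
    struct.pack_into(
        "<6d", header, 179,
        float(cloud.x.max()), float(cloud.x.min()),
        float(cloud.y.max()), float(cloud.y.min()),
        float(cloud.z.max()), float(cloud.z.min()),
    )
    rec = np.zeros((n, 20), dtype=np.uint8)
    xyz_int = np.empty((n, 3), dtype="<i4")
    xyz_int[:, 0] = np.round((cloud.x - ox) / scale)
    xyz_int[:, 1] = np.round((cloud.y - oy) / scale)
    xyz_int[:, 2] = np.round((cloud.z - oz) / scale)
    rec[:, :12] = xyz_int.view(np.uint8).reshape(n, 12)
    if cloud.ground is not None:
        rec[:, 15] = np.where(cloud.ground, GROUND_CLASS, 1)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# tree tables
# ---------------------------------------------------------------------------

def read_tree_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["tree_id", "x", "y", "height"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"tree table missing columns: {missing}")
    if df["tree_id"].duplicated().any():
        raise FormatError("tree table has duplicate tree_id values")
    if len(df) and (df["height"] <= 0).any():
        raise FormatError("tree heights must be positive")
    return df[required]


def write_tree_table(trees: pd.DataFrame, path) -> None:
    cols = ["tree_id", "x", "y", "height"]
    df = trees[cols] if len(trees) else pd.DataFrame(columns=cols)
    df.to_csv(path, index=False)


def write_labels_csv(labels: np.ndarray, path) -> None:
    """Write per-point labels as (point_index, tree_id) CSV."""
    df = pd.DataFrame({"point_index": np.arange(labels.size), "tree_id": labels})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def read_raster(path) -> RasterGrid:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt", ".grd"):
        return _read_esri_ascii(path)
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path)
    raise FormatError(f"unknown raster format {suffix!r}")


def write_raster(grid: RasterGrid, path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt", ".grd"):
        _write_esri_ascii(grid, path)
    elif suffix in (".tif", ".tiff"):
        _write_geotiff(grid, path)
    else:
        raise FormatError(f"unknown raster format {suffix!r}")


def _read_esri_ascii(path: Path) -> RasterGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    try:
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        cell = header["cellsize"]
    except KeyError as exc:
        raise FormatError(f"{path}: missing ESRI ASCII header field {exc}") from exc
    if "xllcorner" in header:
        x0, y0 = header["xllcorner"], header["yllcorner"]
    else:  # cell-center registration
        x0 = header["xllcenter"] - cell / 2
        y0 = header["yllcenter"] - cell / 2
    nodata = header.get("nodata_value", -9999.0)
    if values.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: grid shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    return RasterGrid(x0, y0, cell, values, nodata=nodata)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _write_esri_ascii(grid: RasterGrid, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
        np.savetxt(fh, vals, fmt="%.8g")


_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _write_geotiff(grid: RasterGrid, path: Path) -> None:
    import tifffile

    top_y = grid.origin_y + grid.n_rows * grid.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, top_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    tifffile.imwrite(path, vals.astype(np.float64), extratags=extratags)


def _read_geotiff(path: Path) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(np.float64)
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise FormatError(f"{path}: TIFF lacks georeferencing tags") from exc
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    cell = float(scale[0])
    if abs(float(scale[1]) - cell) > 1e-12:
        raise FormatError(f"{path}: non-square pixels are not supported")
    origin_x = float(tiepoint[3])
    top_y = float(tiepoint[4])
    origin_y = top_y - values.shape[0] * cell
    return RasterGrid(origin_x, origin_y, cell, values, nodata=nodata)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
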