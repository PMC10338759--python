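"""Ground classification, DTM interpolation, normalization, pit-free CHM.

The canopy height model (CHM) is built "pit-free": the normalized cloud
is sliced at increasing height thresholds (0, 2, 5, 10, 15 m by default),
a partial CHM is TIN-interpolated from each slice's per-cell highest
points, and the final CHM is the cell-wise maximum of the partial CHMs.
This removes the spurious low cells (pits) that a naive highest-point
CHM inherits from laser pulses that penetrated a crown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .containers import PointCloud, RasterGrid

__all__ = [
    "PitFreeConfig",
    "classify_ground",
    "build_dtm",
    "normalize_heights",
    "pitfree_chm",
    "naive_chm",
    "default_resolution",
]

log = logging.getLogger(__name__)


class TerrainError(ValueError):
    """Raised when terrain interpolation is impossible (e.g. <3 ground points)."""


@dataclass
class PitFreeConfig:
    """Parameters of pit-free CHM generation.

    layer_thresholds : strictly increasing heights (m), starting at 0,
        at which the normalized cloud is sliced.
    resolution : CHM cell size (m).
    max_edge_factor : triangles whose longest edge exceeds this multiple
        of the cell size are dropped in layers above 2 m, so that sparse
        high slices do not bridge between crowns. ``None`` disables it.
    """

    layer_thresholds: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 15.0)
    resolution: float = 0.1
    max_edge_factor: float | None = 3.0

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.layer_thresholds)
        if not t or t[0] != 0.0:
            raise ValueError("layer thresholds must start at 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("layer thresholds must be strictly increasing")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        self.layer_thresholds = t


def default_resolution(point_density: float) -> float:
    """0.1 m for dense (>= 100 pts/m2, ULS-like) clouds, else 0.2 m."""
    return 0.1 if point_density >= 100.0 else 0.2


def classify_ground(cloud: PointCloud, grid_size: float = 1.0, tol: float = 0.2) -> PointCloud:
    """Flag ground points.

    Pre-classified clouds (``cloud.ground`` present) pass through
    unchanged. Otherwise a minimum-grid fallback runs: the lowest point
    of each ``grid_size`` cell defines a minimum surface (TIN) and every
    point within ``tol`` meters above it is classified as ground. This is
    a stand-in contract, not a cloth-simulation filter; pre-classified
    input is preferred for production terrain.
    """
    if cloud.ground is not None:
        return cloud
    out = cloud.copy()
    if cloud.n == 1:
        out.ground = np.array([True])
        return out
    x0, y0 = cloud.x.min(), cloud.y.min()
    col = np.floor((cloud.x - x0) / grid_size).astype(np.int64)
    row = np.floor((cloud.y - y0) / grid_size).astype(np.int64)
    key = row * (col.max() + 1) + col
    order = np.lexsort((cloud.z, key))
    sorted_key = key[order]
    first = np.ones(cloud.n, dtype=bool)
    first[1:] = sorted_key[1:] != sorted_key[:-1]
    min_idx = order[first]  # lowest point per occupied cell
    gx, gy, gz = cloud.x[min_idx], cloud.y[min_idx], cloud.z[min_idx]
    if min_idx.size >= 3:
        try:
            interp = LinearNDInterpolator(np.c_[gx, gy], gz)
            surf = interp(cloud.x, cloud.y)
            nn = NearestNDInterpolator(np.c_[gx, gy], gz)
            bad = ~np.isfinite(surf)
            if bad.any():
                surf[bad] = nn(cloud.x[bad], cloud.y[bad])
        except QhullError:
            surf = np.full(cloud.n, gz.min())
    else:
        surf = np.full(cloud.n, gz.min())
    out.ground = cloud.z <= surf + tol
    n_ground = int(out.ground.sum())
    relief = float(cloud.z.max() - cloud.z.min())
    if (n_ground == 0 or n_ground == cloud.n) and relief > tol:
        log.warning(
            "ground classification degenerate: %d/%d points flagged ground",
            n_ground, cloud.n,
        )
    return out


def _tin_sample(px, py, pz, xq, yq, max_edge: float | None = None) -> np.ndarray:
    """Linear TIN interpolation of scattered (px,py,pz) at query points.

    Returns NaN outside the convex hull and inside dropped (long-edge)
    triangles. Query arrays may be any broadcastable shape.
    """
    pts = np.c_[px, py]
    tri = Delaunay(pts)
    q = np.c_[np.ravel(xq), np.ravel(yq)]
    simplex = tri.find_simplex(q)
    out = np.full(q.shape[0], np.nan)
    ok = simplex >= 0
    if max_edge is not None:
        verts = tri.simplices
        a, b, c = pts[verts[:, 0]], pts[verts[:, 1]], pts[verts[:, 2]]
        longest = np.maximum(
            np.linalg.norm(a - b, axis=1),
            np.maximum(np.linalg.norm(b - c, axis=1), np.linalg.norm(c - a, axis=1)),
        )
        ok &= np.where(simplex >= 0, longest[simplex] <= max_edge, False)
    if ok.any():
        s = simplex[ok]
        bary_t = tri.transform[s]
        delta = q[ok] - bary_t[:, 2]
        bc = np.einsum("ijk,ik->ij", bary_t[:, :2], delta)
        w = np.c_[bc, 1 - bc.sum(axis=1)]
        out[ok] = np.einsum("ij,ij->i", w, np.asarray(pz)[tri.simplices[s]])
    return out.reshape(np.shape(xq))


def build_dtm(cloud: PointCloud, resolution: float, origin: tuple[float, float] | None = None,
              shape: tuple[int, int] | None = None) -> RasterGrid:
    """Interpolate a DTM from ground-classified points by linear TIN.

    Cells outside the ground-point convex hull are filled by nearest
    neighbor. Raises :class:`TerrainError` with fewer than 3 ground
    points (or all collinear). The default lattice is registered so the
    first cell center sits exactly at the data minimum: every sample
    inside the data extent then interpolates between in-hull centers.
    """
    if cloud.ground is None:
        raise TerrainError("cloud has no ground classification; run classify_ground first")
    g = cloud.ground
    if int(g.sum()) < 3:
        raise TerrainError("DTM interpolation needs at least 3 ground points")
    gx, gy, gz = cloud.x[g], cloud.y[g], cloud.z[g]
    if origin is None:
        origin = (float(cloud.x.min()) - resolution / 2.0,
                  float(cloud.y.min()) - resolution / 2.0)
    if shape is None:
        n_cols = int(np.floor((cloud.x.max() - origin[0]) / resolution)) + 1
        n_rows = int(np.floor((cloud.y.max() - origin[1]) / resolution)) + 1
    else:
        n_rows, n_cols = shape
    grid = RasterGrid(origin[0], origin[1], resolution, np.zeros((n_rows, n_cols)))
    xq, yq = np.meshgrid(grid.x_centers, grid.y_centers)
    try:
        vals = _tin_sample(gx, gy, gz, xq, yq)
    except QhullError as exc:
        raise TerrainError(f"ground points are degenerate (collinear?): {exc}") from exc
    bad = ~np.isfinite(vals)
    if bad.any():
        nn = NearestNDInterpolator(np.c_[gx, gy], gz)
        vals[bad] = nn(xq[bad], yq[bad])
    grid.values = vals
    return grid


def normalize_heights(cloud: PointCloud, dtm: RasterGrid) -> PointCloud:
    """Replace z by height above terrain (bilinear DTM sample, clamped at 0).

    Points outside the DTM extent use the nearest-edge value; their count
    is logged as a warning.
    """
    terrain, inside = dtm.sample_bilinear(cloud.x, cloud.y)
    n_outside = int((~inside).sum())
    if n_outside:
        log.warning("%d points outside DTM extent; nearest-cell terrain used", n_outside)
    out = cloud.copy()
    out.z = np.maximum(cloud.z - terrain, 0.0)
    return out


def _per_cell_highest(cloud_x, cloud_y, cloud_z, grid: RasterGrid):
    """Indices of the highest point of each occupied cell."""
    row, col, inside = grid.cell_index(cloud_x, cloud_y)
    key = row * grid.n_cols + col
    key = key[inside]
    idx_all = np.flatnonzero(inside)
    order = np.lexsort((cloud_z[idx_all], key))
    sorted_key = key[order]
    last = np.ones(sorted_key.size, dtype=bool)
    last[:-1] = sorted_key[1:] != sorted_key[:-1]
    return idx_all[order[last]]


def naive_chm(cloud: PointCloud, resolution: float, origin=None, shape=None) -> RasterGrid:
    """Single-layer highest-point CHM (no interpolation; empty cells = 0)."""
    if origin is None:
        origin = (float(cloud.x.min()), float(cloud.y.min()))
    if shape is None:
        n_cols = int(np.floor((cloud.x.max() - origin[0]) / resolution)) + 1
        n_rows = int(np.floor((cloud.y.max() - origin[1]) / resolution)) + 1
    else:
        n_rows, n_cols = shape
    grid = RasterGrid(origin[0], origin[1], resolution, np.zeros((n_rows, n_cols)))
    row, col, inside = grid.cell_index(cloud.x, cloud.y)
    np.maximum.at(grid.values, (row[inside], col[inside]), cloud.z[inside])
    return grid


def pitfree_chm(cloud: PointCloud, config: PitFreeConfig,
                origin=None, shape=None) -> RasterGrid:
    """Pit-free CHM: cell-wise max of per-layer TIN CHMs.

    Each layer keeps only points at or above its threshold, reduces them
    to per-cell highest points, triangulates, and samples cell centers.
    The result is clamped below by the naive highest-point CHM so no
    cell ever falls under the evidence its own points provide, and empty
    cells are 0.
    """
    if cloud.z.min() < -1e-9:
        raise TerrainError("pitfree_chm expects a normalized cloud (min z >= 0)")
    if origin is None:
        origin = (float(cloud.x.min()), float(cloud.y.min()))
    base = naive_chm(cloud, config.resolution, origin=origin, shape=shape)
    if shape is None:
        shape = (base.n_rows, base.n_cols)
    t0 = config.layer_thresholds[0]
    if not (cloud.z >= t0).any():
        raise TerrainError("no points at or above the first CHM layer threshold")
    xq, yq = np.meshgrid(base.x_centers, base.y_centers)
    chm = base.values.copy()  # pit-free CHM >= naive CHM, cell-wise
    for t in config.layer_thresholds:
        sel = cloud.z >= t
        if int(sel.sum()) < 3:
            continue
        sx, sy, sz = cloud.x[sel], cloud.y[sel], cloud.z[sel]
        hi = _per_cell_highest(sx, sy, sz, base)
        if hi.size < 3:
            continue
        max_edge = None
        if config.max_edge_factor is not None and t >= 2.0:
            max_edge = config.max_edge_factor * config.resolution
        try:
            layer = _tin_sample(sx[hi], sy[hi], sz[hi], xq, yq, max_edge=max_edge)
        except QhullError:
            continue
        np.fmax(chm, layer, out=chm, where=np.isfinite(layer))
    return RasterGrid(origin[0], origin[1], config.resolution, chm)
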