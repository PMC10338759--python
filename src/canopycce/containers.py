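"""Core in-memory containers shared by every stage of the pipeline.

Coordinates are meters in a projected CRS. Rasters follow the usual
north-up convention: ``values[0, :]`` is the northernmost row, while
``origin_x``/``origin_y`` name the lower-left corner of the lower-left
cell so that ESRI ASCII export is a direct dump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointCloud",
    "RasterGrid",
    "SuperPointSet",
    "TreeRecord",
    "records_to_table",
]


@dataclass
class PointCloud:
    """A LiDAR point cloud with optional ground flags and tree labels.

    Parameters
    ----------
    x, y, z : ndarray of float64, shape (n,)
        Point coordinates in meters.
    ground : ndarray of bool, shape (n,), optional
        True for ground-classified points (LAS class 2).
    labels : ndarray of int, shape (n,), optional
        Per-point tree label; 0 means unassigned/background.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    ground: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).ravel()
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.z = np.asarray(self.z, dtype=np.float64).ravel()
        n = self.x.size
        if n == 0:
            raise ValueError("point cloud must contain at least one point")
        if self.y.size != n or self.z.size != n:
            raise ValueError("x, y, z must have equal length")
        if not (
            np.isfinite(self.x).all()
            and np.isfinite(self.y).all()
            and np.isfinite(self.z).all()
        ):
            raise ValueError("coordinates must be finite")
        if self.ground is not None:
            self.ground = np.asarray(self.ground, dtype=bool).ravel()
            if self.ground.size != n:
                raise ValueError("ground flags must match point count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
            if self.labels.size != n:
                raise ValueError("labels must match point count")
            if (self.labels < 0).any():
                raise ValueError("labels must be non-negative")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def xyz(self) -> np.ndarray:
        """Points stacked as an (n, 3) array."""
        return np.column_stack([self.x, self.y, self.z])

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.x.copy(),
            self.y.copy(),
            self.z.copy(),
            None if self.ground is None else self.ground.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def subset(self, idx: np.ndarray) -> "PointCloud":
        """Return a new cloud restricted to the given point indices."""
        return PointCloud(
            self.x[idx],
            self.y[idx],
            self.z[idx],
            None if self.ground is None else self.ground[idx],
            None if self.labels is None else self.labels[idx],
        )


@dataclass
class RasterGrid:
    """A georeferenced single-band height grid (DTM or CHM).

    ``values`` has shape (n_rows, n_cols) with row 0 at the north edge.
    ``origin_x``/``origin_y`` are the lower-left corner of the grid.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        """y coordinate of each row center, row 0 = northernmost."""
        return self.origin_y + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size

    def is_nodata(self) -> np.ndarray:
        vals = self.values
        mask = vals == self.nodata
        return mask | ~np.isfinite(vals)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) under half-open cell intervals.

        Returns (row, col, inside) where ``inside`` marks points that fall
        within the grid extent. Out-of-extent indices are clamped.
        """
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        row_from_bottom = np.floor((y - self.origin_y) / self.cell_size).astype(np.int64)
        row = self.n_rows - 1 - row_from_bottom
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col, inside

    def sample_bilinear(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear sample at (x, y); edges are clamped (nearest behavior).

        Returns (values, inside) where ``inside`` is False for points
        outside the grid extent (their value comes from the clamped edge).
        Nodata cells are treated as NaN and propagate.
        """
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        vals = np.where(self.is_nodata(), np.nan, self.values)
        # fractional cell coordinates relative to cell-center lattice
        fx = (x - self.origin_x) / self.cell_size - 0.5
        fy_bottom = (y - self.origin_y) / self.cell_size - 0.5
        fr = (self.n_rows - 1) - fy_bottom  # row coordinate, 0 = north
        inside = (
            (x >= self.origin_x)
            & (x < self.origin_x + self.n_cols * self.cell_size)
            & (y >= self.origin_y)
            & (y < self.origin_y + self.n_rows * self.cell_size)
        )
        fx = np.clip(fx, 0.0, self.n_cols - 1.0)
        fr = np.clip(fr, 0.0, self.n_rows - 1.0)
        c0 = np.floor(fx).astype(np.int64)
        r0 = np.floor(fr).astype(np.int64)
        c1 = np.minimum(c0 + 1, self.n_cols - 1)
        r1 = np.minimum(r0 + 1, self.n_rows - 1)
        tx = fx - c0
        tr = fr - r0
        v00 = vals[r0, c0]
        v01 = vals[r0, c1]
        v10 = vals[r1, c0]
        v11 = vals[r1, c1]
        out = (
            v00 * (1 - tr) * (1 - tx)
            + v01 * (1 - tr) * tx
            + v10 * tr * (1 - tx)
            + v11 * tr * tx
        )
        return out, inside


@dataclass
class SuperPointSet:
    """Voxelized (mean-shift merged) representation of a point set.

    ``centers[i]`` is the weighted centroid of the original points mapped
    to super-point i, ``weights[i]`` their count, and ``member_map[j]``
    the super-point index of original point j. Mass is conserved:
    ``weights.sum() == member_map.size``.
    """

    centers: np.ndarray
    weights: np.ndarray
    member_map: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.int64)
        self.member_map = np.asarray(self.member_map, dtype=np.int64)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must be (m, 3)")
        if self.weights.size != self.centers.shape[0]:
            raise ValueError("weights must match centers")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")
        if int(self.weights.sum()) != self.member_map.size:
            raise ValueError("sum of weights must equal number of original points")

    @property
    def m(self) -> int:
        return self.centers.shape[0]


@dataclass
class TreeRecord:
    """Attributes of one detected tree."""

    tree_id: int
    top_x: float
    top_y: float
    height: float
    crown_x: float
    crown_y: float
    members: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)
        if self.members.size == 0:
            raise ValueError("tree record needs at least one member point")
        if self.height <= 0:
            raise ValueError("tree height must be positive")


def records_to_table(records: list[TreeRecord]):
    """Convert TreeRecords to a tree-table DataFrame (tree_id, x, y, height)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "tree_id": [r.tree_id for r in records],
            "x": [r.top_x for r in records],
            "y": [r.top_y for r in records],
            "height": [r.height for r in records],
        }
    )
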