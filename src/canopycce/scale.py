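"""Optimal-scale selection by tri-planar crown-shape constraints.

A clustering scale is a candidate only if every one of its clusters
looks like a plausible tree crown when projected onto the X-Y, X-Z and
Y-Z planes:

* the larger of the two crown widths is less than three times the
  smaller, |CrownX - CrownY| < (CrownX + CrownY) / 2;
* the highest point lies away from the crown edge in both axes,
  Xmin + f*CrownX < XmaxZ < Xmax - f*CrownX (and likewise in y), with
  edge fraction f = 1/8 by default (for f = 1/8 the bounds are exactly
  (7*Xmin + Xmax)/8 and (7*Xmax + Xmin)/8).

Among candidate scales, the cluster count backed by the most scales
wins (ties to the smaller count), and inside that group the clustering
with the lowest normalized cut is returned. If no scale qualifies the
segment is kept whole — one tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ProjectionStats", "projection_stats", "shape_ok", "select_scale"]


@dataclass
class ProjectionStats:
    crown_x: float
    crown_y: float
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    x_max_z: float  # x of the highest point
    y_max_z: float  # y of the highest point


def projection_stats(points: np.ndarray) -> ProjectionStats:
    """Extremes and highest-point coordinates of a cluster's points."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, 3) array")
    top = int(np.argmax(pts[:, 2]))
    x_min, x_max = float(pts[:, 0].min()), float(pts[:, 0].max())
    y_min, y_max = float(pts[:, 1].min()), float(pts[:, 1].max())
    return ProjectionStats(
        crown_x=x_max - x_min,
        crown_y=y_max - y_min,
        x_min=x_min,
        x_max=x_max,
        y_min=y_min,
        y_max=y_max,
        x_max_z=float(pts[top, 0]),
        y_max_z=float(pts[top, 1]),
    )


def shape_ok(ps: ProjectionStats, edge_fraction: float = 0.125) -> bool:
    """All three crown-shape inequalities, strict as printed.

    Degenerate clusters (zero width in either axis) fail.
    """
    cx, cy = ps.crown_x, ps.crown_y
    if cx <= 0 or cy <= 0:
        return False
    if not abs(cx - cy) < (cx + cy) / 2.0:
        return False
    f = edge_fraction
    if not (ps.x_min + f * cx < ps.x_max_z < ps.x_max - f * cx):
        return False
    if not (ps.y_min + f * cy < ps.y_max_z < ps.y_max - f * cy):
        return False
    return True


def select_scale(results, points: np.ndarray, member_map: np.ndarray,
                 edge_fraction: float = 0.125):
    """Pick the best clustering of a segment across the k-sweep.

    Parameters
    ----------
    results : list of ClusterResult over the segment's super-points.
    points : (n, 3) original points of the segment.
    member_map : (n,) super-point index per original point.

    Returns
    -------
    labels : (n,) cluster id (0-based) per original point.
    chosen : the selected ClusterResult, or None when no scale passed
        the shape constraints (then all points share label 0).
    """
    points = np.asarray(points, dtype=np.float64)
    member_map = np.asarray(member_map, dtype=np.int64)
    n = points.shape[0]
    candidates = []
    for res in results:
        point_labels = res.assignment[member_map]
        ok = True
        for lab in range(res.m):
            member_pts = points[point_labels == lab]
            if member_pts.shape[0] == 0 or not shape_ok(
                projection_stats(member_pts), edge_fraction
            ):
                ok = False
                break
        if ok:
            candidates.append((res, point_labels))
    if not candidates:
        return np.zeros(n, dtype=np.int64), None
    counts: dict[int, int] = {}
    for res, _ in candidates:
        counts[res.m] = counts.get(res.m, 0) + 1
    best_m = min(counts, key=lambda m: (-counts[m], m))  # mode, ties to smaller m
    group = [(res, lab) for res, lab in candidates if res.m == best_m]
    chosen, labels = min(group, key=lambda rl: rl[0].ncut)
    return labels.astype(np.int64), chosen
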