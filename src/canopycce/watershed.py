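"""Initial crown segmentation of the CHM by a tolerance-merging watershed.

Seeds are local maxima of the CHM inside a (2*ext+1)^2 window. Regions
grow from the seeds by a deterministic highest-frontier-first flood
(8-connectivity). Afterwards, any object whose drop from its seed to its
highest contact (saddle) with a neighboring object is smaller than
``tolerance`` is merged into its highest neighbor, iteratively, until
stable. ``tolerance`` is in CHM units (m); ``ext`` in pixels.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import PointCloud, RasterGrid

__all__ = ["WatershedParams", "SegmentMap", "detect_seeds", "watershed_segment", "label_points"]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class WatershedParams:
    tolerance: float = 1.0   # min seed-to-saddle drop (m) to survive merging
    ext: int = 2             # local-max neighborhood radius (pixels)
    min_height: float = 2.0  # CHM cells below this are background (m)

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if int(self.ext) < 1 or self.ext != int(self.ext):
            raise ValueError("ext must be a positive integer")
        self.ext = int(self.ext)


@dataclass
class SegmentMap:
    """Pixel labels aligned with the CHM (0 = background, ids 1..K)."""

    labels: np.ndarray
    grid: RasterGrid
    seeds: list[tuple[int, int]]

    @property
    def n_segments(self) -> int:
        return len(self.seeds)


def detect_seeds(chm: RasterGrid, params: WatershedParams) -> list[tuple[int, int]]:
    """Local maxima of the CHM above ``min_height``.

    A cell is a seed if it attains the maximum of its (2*ext+1)^2
    neighborhood. Flat-topped maxima (plateaus) yield one seed, the
    plateau cell with the smallest (row, col).
    """
    vals = np.where(chm.is_nodata(), -np.inf, chm.values)
    size = 2 * params.ext + 1
    local_max = ndimage.maximum_filter(vals, size=size, mode="constant", cval=-np.inf)
    is_max = (vals >= local_max) & (vals >= params.min_height)
    if not is_max.any():
        return []
    # collapse plateau components to their smallest (row, col) cell
    comp, n_comp = ndimage.label(is_max, structure=np.ones((3, 3), dtype=int))
    seeds = []
    rows, cols = np.nonzero(is_max)
    order = np.lexsort((cols, rows))  # row-major: first cell per component wins
    seen: set[int] = set()
    for i in order:
        c = comp[rows[i], cols[i]]
        if c not in seen:
            seen.add(c)
            seeds.append((int(rows[i]), int(cols[i])))
    seeds.sort()
    return seeds


def _flood(vals: np.ndarray, seeds: list[tuple[int, int]], min_height: float) -> np.ndarray:
    """Seeded highest-frontier-first flood, 8-connected, deterministic.

    At every step the unlabeled masked cell with the greatest height among
    those adjacent to a labeled cell is labeled next; it takes the label of
    its highest labeled neighbor (ties: smaller label). Priority ties break
    on (row, col).
    """
    n_rows, n_cols = vals.shape
    labels = np.zeros(vals.shape, dtype=np.int64)
    mask = np.isfinite(vals) & (vals >= min_height)
    expanded = np.zeros(vals.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for lab, (r, c) in enumerate(seeds, start=1):
        labels[r, c] = lab
        heapq.heappush(heap, (-vals[r, c], r, c))
    while heap:
        _, r, c = heapq.heappop(heap)
        if expanded[r, c]:
            continue
        expanded[r, c] = True
        if labels[r, c] == 0:
            # label from the highest labeled neighbor (ties: smaller label)
            best_h, best_lab = -np.inf, 0
            for er, ec in _NEIGHBORS:
                nr, nc = r + er, c + ec
                if 0 <= nr < n_rows and 0 <= nc < n_cols and labels[nr, nc] > 0:
                    h = vals[nr, nc]
                    if h > best_h or (h == best_h and labels[nr, nc] < best_lab):
                        best_h, best_lab = h, labels[nr, nc]
            labels[r, c] = best_lab
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and mask[rr, cc] and labels[rr, cc] == 0:
                heapq.heappush(heap, (-vals[rr, cc], rr, cc))
    return labels


def _saddles(labels: np.ndarray, vals: np.ndarray, n_lab: int) -> np.ndarray:
    """(n+1, n+1) matrix of saddle heights between adjacent objects.

    saddle[a, b] = max over 8-adjacent pixel pairs (p in a, q in b) of
    min(vals[p], vals[q]); -inf where the objects do not touch.
    """
    saddle = np.full((n_lab + 1, n_lab + 1), -np.inf)
    n_rows, n_cols = labels.shape

    def _pair_slices(d, n):
        # source rows/cols i and shifted i+d, both in range
        return slice(max(0, -d), n - max(0, d)), slice(max(0, d), n + min(0, d))

    for dr, dc in _NEIGHBORS[:4]:  # each unordered pair once
        ra, rb = _pair_slices(dr, n_rows)
        ca, cb = _pair_slices(dc, n_cols)
        a, b = labels[ra, ca], labels[rb, cb]
        va, vb = vals[ra, ca], vals[rb, cb]
        touching = (a > 0) & (b > 0) & (a != b)
        if touching.any():
            lo = np.minimum(va[touching], vb[touching])
            np.maximum.at(saddle, (a[touching], b[touching]), lo)
            np.maximum.at(saddle, (b[touching], a[touching]), lo)
    return saddle


def watershed_segment(chm: RasterGrid, params: WatershedParams) -> SegmentMap:
    """Seeded watershed with tolerance-based object merging.

    After flooding, objects are processed in ascending seed height; an
    object whose seed rises less than ``tolerance`` above its highest
    saddle is merged into its highest-seeded neighbor. One merge per
    pass, repeated until stable, so results are order-independent and
    bit-reproducible.
    """
    vals = np.where(chm.is_nodata(), -np.inf, chm.values)
    seeds = detect_seeds(chm, params)
    if not seeds:
        return SegmentMap(np.zeros(vals.shape, dtype=np.int64), chm, [])
    labels = _flood(vals, seeds, params.min_height)
    seed_of = {lab: rc for lab, rc in enumerate(seeds, start=1)}
    seed_h = {lab: float(vals[rc]) for lab, rc in seed_of.items()}
    alive = sorted(seed_of)
    while True:
        n_lab = max(alive)
        saddle = _saddles(labels, vals, n_lab)
        merged = False
        # ascending seed height, then label, for a deterministic order
        for lab in sorted(alive, key=lambda l: (seed_h[l], l)):
            row = saddle[lab, : n_lab + 1]
            contact = float(row.max())
            if not np.isfinite(contact):
                continue
            if seed_h[lab] - contact < params.tolerance:
                neighbors = [b for b in alive if b != lab and np.isfinite(saddle[lab, b])]
                target = max(neighbors, key=lambda b: (seed_h[b], -b))
                labels[labels == lab] = target
                alive.remove(lab)
                del seed_h[lab], seed_of[lab]
                merged = True
                break
        if not merged:
            break
    # relabel contiguously 1..K, ordered by original label
    remap = np.zeros(max(alive) + 1, dtype=np.int64)
    final_seeds = []
    for new, lab in enumerate(sorted(alive), start=1):
        remap[lab] = new
        final_seeds.append(seed_of[lab])
    labels = remap[labels]
    return SegmentMap(labels, chm, final_seeds)


def label_points(cloud: PointCloud, seg: SegmentMap, min_height: float = 2.0) -> PointCloud:
    """Project pixel labels onto normalized points.

    Points with z >= min_height take the label of their containing cell
    (half-open intervals); everything else gets label 0.
    """
    row, col, inside = seg.grid.cell_index(cloud.x, cloud.y)
    labels = np.zeros(cloud.n, dtype=np.int64)
    take = inside & (cloud.z >= min_height)
    labels[take] = seg.labels[row[take], col[take]]
    out = cloud.copy()
    out.labels = labels
    return out
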