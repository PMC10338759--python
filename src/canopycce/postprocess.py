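"""Per-tree attribute extraction and plantation merge rule.

The merge rule targets spuriously split crowns (e.g. bifurcated larch
trunks): two detected trees are merged when their tops are closer than
the plot's average crown diameter and their heights differ by less than
``height_gap_max``. Merging is greedy by increasing top-to-top distance
and re-evaluates after every merge, which makes it idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import PointCloud, TreeRecord

__all__ = ["MergeParams", "extract_tree_attributes", "merge_close_trees"]


@dataclass
class MergeParams:
    enabled: bool = True
    height_gap_max: float = 10.0      # max |height difference| to merge (m)
    crown_diameter: float | None = None  # None = plot mean crown width, re-derived

    def __post_init__(self) -> None:
        if self.height_gap_max <= 0:
            raise ValueError("height_gap_max must be > 0")


def extract_tree_attributes(cloud: PointCloud) -> list[TreeRecord]:
    """One TreeRecord per label >= 1: top = highest member point."""
    if cloud.labels is None:
        raise ValueError("cloud has no tree labels")
    records = []
    for lab in np.unique(cloud.labels):
        if lab == 0:
            continue
        members = np.flatnonzero(cloud.labels == lab)
        records.append(_record_from_members(int(lab), cloud, members))
    return records


def _record_from_members(tree_id: int, cloud: PointCloud, members: np.ndarray) -> TreeRecord:
    z = cloud.z[members]
    top = members[int(np.argmax(z))]
    x, y = cloud.x[members], cloud.y[members]
    return TreeRecord(
        tree_id=tree_id,
        top_x=float(cloud.x[top]),
        top_y=float(cloud.y[top]),
        height=float(cloud.z[top]),
        crown_x=float(x.max() - x.min()),
        crown_y=float(y.max() - y.min()),
        members=members,
    )


def merge_close_trees(trees: list[TreeRecord], cloud: PointCloud,
                      params: MergeParams | None = None) -> list[TreeRecord]:
    """Merge adjacent similar-height trees closer than the crown diameter.

    The qualifying pair with the smallest horizontal top-to-top distance
    merges first (union of members, attributes re-extracted); the
    process repeats until no pair qualifies. The automatic crown
    diameter is the plot mean crown width of the records at entry — it
    is not re-derived from merged crowns, which would cascade.
    """
    params = params or MergeParams()
    if not params.enabled or len(trees) < 2:
        return list(trees)
    records = list(trees)
    if params.crown_diameter is not None:
        diameter = params.crown_diameter
    else:
        diameter = float(np.mean([(r.crown_x + r.crown_y) / 2.0 for r in records]))
    while True:
        best = None
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                a, b = records[i], records[j]
                dist = float(np.hypot(a.top_x - b.top_x, a.top_y - b.top_y))
                if dist < diameter and abs(a.height - b.height) < params.height_gap_max:
                    key = (dist, a.tree_id, b.tree_id)
                    if best is None or key < best[0]:
                        best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = records[i], records[j]
        members = np.sort(np.concatenate([a.members, b.members]))
        merged = _record_from_members(min(a.tree_id, b.tree_id), cloud, members)
        records = [r for idx, r in enumerate(records) if idx not in (i, j)]
        records.append(merged)
        records.sort(key=lambda r: r.tree_id)
    # renumber contiguously, keeping the deterministic id order
    for new_id, rec in enumerate(sorted(records, key=lambda r: r.tree_id), start=1):
        rec.tree_id = new_id
    return sorted(records, key=lambda r: r.tree_id)
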