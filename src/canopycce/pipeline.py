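"""End-to-end individual tree segmentation.

Stage order: ground classification (or pass-through) -> DTM -> height
normalization -> pit-free CHM -> tolerance watershed (initial segments)
-> per-segment mean-shift voxelization -> CCE scale sweep -> crown-shape
scale selection -> plantation merge -> per-tree attributes.

:class:`TreeSegmenter` exposes the whole chain as a scikit-learn style
estimator; :func:`segment_trees` is the functional entry point.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .cce import CCEConfig, cce_sweep
from .containers import PointCloud, records_to_table
from .postprocess import MergeParams, extract_tree_attributes, merge_close_trees
from .scale import select_scale
from .terrain import (PitFreeConfig, build_dtm, classify_ground,
                      default_resolution, normalize_heights, pitfree_chm)
from .voxelize import default_bandwidth, meanshift_voxelize
from .watershed import WatershedParams, label_points, watershed_segment

__all__ = ["TreeSegmenter", "RunConfig", "segment_trees"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is attached to the message."""


@dataclass
class RunConfig:
    """Validated run configuration mirroring the estimator parameters.

    ``from_dict`` accepts the nested YAML layout::

        resolution: 0.1
        layers: [0, 2, 5, 10, 15]
        watershed: {tolerance: 1.0, ext: 2, min_height: 2.0}
        voxel: {bandwidth: 0.3, tol: 1.0e-3, max_iter: 100}
        cce: {vr: 0.1667, sigma: 30.0, max_power: 1048576, weight_mode: printed}
        scale: {edge_fraction: 0.125}
        merge: {enabled: true, height_gap_max: 10.0, crown_diameter: null}
    """

    resolution: float | None = None
    layers: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 15.0)
    tolerance: float = 1.0
    ext: int = 2
    min_height: float = 2.0
    bandwidth: float | None = None
    voxel_tol: float = 1e-3
    voxel_max_iter: int = 100
    vr: float = 1.0 / 6.0
    sigma: float = 30.0
    max_power: int = 2 ** 20
    weight_mode: str = "printed"
    edge_fraction: float = 0.125
    merge: bool = True
    height_gap_max: float = 10.0
    crown_diameter: float | None = None
    use_cce: bool = True
    min_segment_superpoints: int = 10
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        # delegate range checks to the stage parameter classes
        WatershedParams(self.tolerance, self.ext, self.min_height)
        CCEConfig(self.vr, self.sigma, self.max_power, self.weight_mode)
        MergeParams(self.merge, self.height_gap_max, self.crown_diameter)
        if self.edge_fraction < 0:
            raise ValueError("edge_fraction must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        flat: dict = {}
        nested_map = {
            "watershed": {"tolerance": "tolerance", "ext": "ext", "min_height": "min_height"},
            "voxel": {"bandwidth": "bandwidth", "tol": "voxel_tol", "max_iter": "voxel_max_iter"},
            "cce": {"vr": "vr", "sigma": "sigma", "max_power": "max_power",
                    "weight_mode": "weight_mode"},
            "scale": {"edge_fraction": "edge_fraction"},
            "merge": {"enabled": "merge", "height_gap_max": "height_gap_max",
                      "crown_diameter": "crown_diameter"},
        }
        for key, value in (data or {}).items():
            if key in nested_map and isinstance(value, dict):
                for sub, subval in value.items():
                    if sub not in nested_map[key]:
                        raise ValueError(f"unknown config key {key}.{sub}")
                    flat[nested_map[key][sub]] = subval
            else:
                flat[key] = value
        if "layers" in flat and flat["layers"] is not None:
            flat["layers"] = tuple(float(v) for v in flat["layers"])
        return cls(**flat)

    def to_dict(self) -> dict:
        return asdict(self)


class TreeSegmenter(BaseEstimator, ClusterMixin):
    """Individual tree segmentation of a normalized-or-raw LiDAR cloud.

    ``fit(X)`` accepts an (n, 3) coordinate array or a
    :class:`~canopycce.containers.PointCloud` (ground flags, when
    present, are passed through to terrain modelling). Resolution and
    voxel bandwidth default by point density (0.1 m / 0.4 m for
    >= 100 pts/m2, else 0.2 m / 0.6 m).

    Attributes
    ----------
    labels_ : final tree label per input point (0 = background).
    records_ : list of TreeRecord.
    trees_ : tree table DataFrame (tree_id, x, y, height).
    n_trees_ : number of detected trees.
    chm_, dtm_ : the rasters used; segment_map_ : initial watershed map.
    timings_ : per-stage wall times (s).
    """

    def __init__(self, resolution=None, layers=(0.0, 2.0, 5.0, 10.0, 15.0),
                 tolerance=1.0, ext=2, min_height=2.0, bandwidth=None,
                 voxel_tol=1e-3, voxel_max_iter=100, vr=1.0 / 6.0, sigma=30.0,
                 max_power=2 ** 20, weight_mode="printed", edge_fraction=0.125,
                 merge=True, height_gap_max=10.0, crown_diameter=None,
                 use_cce=True, min_segment_superpoints=10):
        self.resolution = resolution
        self.layers = layers
        self.tolerance = tolerance
        self.ext = ext
        self.min_height = min_height
        self.bandwidth = bandwidth
        self.voxel_tol = voxel_tol
        self.voxel_max_iter = voxel_max_iter
        self.vr = vr
        self.sigma = sigma
        self.max_power = max_power
        self.weight_mode = weight_mode
        self.edge_fraction = edge_fraction
        self.merge = merge
        self.height_gap_max = height_gap_max
        self.crown_diameter = crown_diameter
        self.use_cce = use_cce
        self.min_segment_superpoints = min_segment_superpoints

    # -- stages ----------------------------------------------------------

    def fit(self, X, y=None):
        cloud = X if isinstance(X, PointCloud) else PointCloud(
            np.asarray(X, dtype=np.float64)[:, 0],
            np.asarray(X, dtype=np.float64)[:, 1],
            np.asarray(X, dtype=np.float64)[:, 2],
        )
        self.timings_ = {}
        area = max(
            (cloud.x.max() - cloud.x.min()) * (cloud.y.max() - cloud.y.min()), 1e-9
        )
        density = cloud.n / area
        resolution = self.resolution or default_resolution(density)
        bandwidth = self.bandwidth or default_bandwidth(density)

        norm = self._stage("terrain", self._terrain, cloud, resolution)
        chm, seg, labeled = self._stage("watershed", self._watershed, norm, resolution)
        if self.use_cce:
            labeled = self._stage("cce", self._cce, labeled, seg, bandwidth)
        records = self._stage("attributes", self._attributes, labeled)
        self.labels_ = labeled.labels
        self.cloud_ = labeled
        self.records_ = records
        self.trees_ = records_to_table(records)
        self.n_trees_ = len(records)
        return self

    def _stage(self, name, func, *args):
        t0 = time.perf_counter()
        try:
            out = func(*args)
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        self.timings_[name] = time.perf_counter() - t0
        log.info("stage %-10s %.2f s", name, self.timings_[name])
        return out

    def _terrain(self, cloud, resolution):
        flagged = classify_ground(cloud)
        self.dtm_ = build_dtm(flagged, resolution)
        return normalize_heights(flagged, self.dtm_)

    def _watershed(self, norm, resolution):
        nonground = norm if norm.ground is None else norm.subset(~norm.ground)
        cfg = PitFreeConfig(layer_thresholds=tuple(self.layers), resolution=resolution)
        origin = (float(norm.x.min()), float(norm.y.min()))
        n_cols = int(np.floor((norm.x.max() - origin[0]) / resolution)) + 1
        n_rows = int(np.floor((norm.y.max() - origin[1]) / resolution)) + 1
        self.chm_ = pitfree_chm(nonground, cfg, origin=origin, shape=(n_rows, n_cols))
        params = WatershedParams(self.tolerance, self.ext, self.min_height)
        self.segment_map_ = watershed_segment(self.chm_, params)
        labeled = label_points(norm, self.segment_map_, self.min_height)
        log.info("watershed: %d initial segments", self.segment_map_.n_segments)
        return self.chm_, self.segment_map_, labeled

    def _cce(self, labeled, seg, bandwidth):
        config = CCEConfig(self.vr, self.sigma, self.max_power, self.weight_mode)
        out_labels = np.zeros(labeled.n, dtype=np.int64)
        next_label = 1
        for seg_id in range(1, seg.n_segments + 1):
            idx = np.flatnonzero(labeled.labels == seg_id)
            if idx.size == 0:
                continue
            pts = labeled.xyz[idx]
            split = None
            if idx.size >= 3:
                sp = meanshift_voxelize(pts, bandwidth, vr=self.vr,
                                        tol=self.voxel_tol, max_iter=self.voxel_max_iter)
                if sp.m >= self.min_segment_superpoints:
                    results = cce_sweep(sp, config)
                    sub_labels, chosen = select_scale(
                        results, pts, sp.member_map, edge_fraction=self.edge_fraction
                    )
                    if chosen is not None and chosen.m > 1:
                        split = sub_labels
            if split is None:
                out_labels[idx] = next_label
                next_label += 1
            else:
                for lab in range(int(split.max()) + 1):
                    out_labels[idx[split == lab]] = next_label
                    next_label += 1
        out = labeled.copy()
        out.labels = out_labels
        return out

    def _attributes(self, labeled):
        records = extract_tree_attributes(labeled)
        params = MergeParams(self.merge, self.height_gap_max, self.crown_diameter)
        records = merge_close_trees(records, labeled, params)
        # rewrite labels to the merged, renumbered records
        labels = np.zeros(labeled.n, dtype=np.int64)
        for rec in records:
            labels[rec.members] = rec.tree_id
        labeled.labels = labels
        return records

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def segment_trees(cloud: PointCloud, config: RunConfig | None = None):
    """Run the full pipeline; returns (labeled cloud, tree records)."""
    config = config or RunConfig()
    est = TreeSegmenter(
        resolution=config.resolution, layers=config.layers,
        tolerance=config.tolerance, ext=config.ext, min_height=config.min_height,
        bandwidth=config.bandwidth, voxel_tol=config.voxel_tol,
        voxel_max_iter=config.voxel_max_iter, vr=config.vr, sigma=config.sigma,
        max_power=config.max_power, weight_mode=config.weight_mode,
        edge_fraction=config.edge_fraction, merge=config.merge,
        height_gap_max=config.height_gap_max, crown_diameter=config.crown_diameter,
        use_cce=config.use_cce, min_segment_superpoints=config.min_segment_superpoints,
    )
    est.fit(cloud)
    return est.cloud_, est.records_
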