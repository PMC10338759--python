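"""Deterministic synthetic ULS/ALS forest plots with ground truth.

The generator emulates the plot conditions of small inventoried stands:
a sloped terrain plane with smooth low-amplitude undulation, stems on a
jittered grid honoring a minimum spacing, conifer (cone) or broadleaf
(ellipsoid) crowns sampled at a target point density, and exponential
vertical thinning that mimics canopy occlusion (retention
exp(-occlusion_decay * depth_below_apex)). Each tree's apex point is
always retained so the ground-truth top is well defined. All randomness
flows from one seeded generator in a fixed draw order, so outputs are
bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PointCloud

__all__ = ["ForestSpec", "generate_forest", "generate_bifurcated_tree", "terrain_height"]

CROWN_LENGTH_RATIO = 0.5  # crown occupies the top half of the stem height


class SpecError(ValueError):
    pass


@dataclass
class ForestSpec:
    """Study-plot conditions for the generator.

    Defaults follow typical dense ULS plots: 0.10 trees/m2 stem density,
    300 pts/m2, tree heights 12-22 m, crown radii 1-2.5 m, 5 deg slope.
    """

    plot_size: tuple[float, float] = (30.0, 30.0)   # m x m
    stem_density: float = 0.10                      # trees/m2
    crown_shape: str = "cone"                       # cone | ellipsoid | mixed
    height_range: tuple[float, float] = (12.0, 22.0)  # m
    crown_radius_range: tuple[float, float] = (1.0, 2.5)  # m
    slope_deg: float = 5.0
    point_density: float = 300.0                    # pts/m2
    occlusion_decay: float = 0.15                   # 1/m below apex
    min_spacing: float = 2.0                        # m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_density <= 0 or self.point_density <= 0:
            raise SpecError("densities must be positive")
        if self.min_spacing < 0:
            raise SpecError("min_spacing must be >= 0")
        if not (0 < self.height_range[0] <= self.height_range[1]):
            raise SpecError("height_range must be positive and ordered")
        if self.crown_shape not in ("cone", "ellipsoid", "mixed"):
            raise SpecError("crown_shape must be cone, ellipsoid or mixed")

    @property
    def area(self) -> float:
        return self.plot_size[0] * self.plot_size[1]

    @property
    def n_trees(self) -> int:
        return int(round(self.stem_density * self.area))


def terrain_height(spec: ForestSpec, x, y) -> np.ndarray:
    """Ground elevation: inclined plane plus smooth 0.3 m undulation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    slope = np.tan(np.radians(spec.slope_deg))
    sx, sy = spec.plot_size
    wobble = 0.3 * (
        np.sin(2 * np.pi * x / max(sx, 1.0) + 0.37 * spec.seed)
        * np.cos(2 * np.pi * y / max(sy, 1.0) + 0.11 * spec.seed)
    )
    return slope * x + wobble


def _place_stems(spec: ForestSpec, rng: np.random.Generator, margin: float):
    n = spec.n_trees
    if n < 1:
        raise SpecError("spec yields zero trees (density * area rounds to 0)")
    sx, sy = spec.plot_size
    ux, uy = sx - 2 * margin, sy - 2 * margin
    if ux <= 0 or uy <= 0:
        raise SpecError("plot too small for the crown margin")
    nx = max(1, int(np.ceil(np.sqrt(n * ux / uy))))
    ny = max(1, int(np.ceil(n / nx)))
    while nx * ny < n:
        ny += 1
    gx, gy = ux / nx, uy / ny
    if min(gx, gy) < spec.min_spacing:
        raise SpecError(
            f"cannot place {n} stems with min_spacing={spec.min_spacing} m "
            f"in {sx:g}x{sy:g} m (grid pitch {min(gx, gy):.2f} m)"
        )
    cells = np.arange(nx * ny)
    chosen = np.sort(rng.choice(cells, size=n, replace=False))
    ix, iy = chosen % nx, chosen // nx
    jx = (gx - spec.min_spacing) / 2.0
    jy = (gy - spec.min_spacing) / 2.0
    x = margin + (ix + 0.5) * gx + rng.uniform(-jx, jx, size=n)
    y = margin + (iy + 0.5) * gy + rng.uniform(-jy, jy, size=n)
    return x, y


def _sample_crown(rng: np.random.Generator, shape: str, apex_xy, apex_z: float,
                  radius: float, height: float, point_density: float,
                  occlusion_decay: float) -> np.ndarray:
    """Sample one crown; returns (n, 3) including the apex as first row."""
    crown_len = CROWN_LENGTH_RATIO * height
    n_target = max(1, int(round(point_density * np.pi * radius ** 2)))
    # depth pdf proportional to the crown cross-section r(d)^2: uniform
    # density per volume, so the thin apex is not artificially dense
    if shape == "cone":
        depth = crown_len * np.cbrt(rng.uniform(size=n_target))
        r_at = radius * depth / crown_len
    else:  # ellipsoid: rejection sampling against the cross-section profile
        half = crown_len / 2.0
        depth = np.empty(n_target)
        filled = 0
        while filled < n_target:
            cand = rng.uniform(0.0, crown_len, size=2 * (n_target - filled))
            acc = rng.uniform(size=cand.size) < 1.0 - ((cand - half) / half) ** 2
            take = cand[acc][: n_target - filled]
            depth[filled: filled + take.size] = take
            filled += take.size
        r_at = radius * np.sqrt(np.clip(1.0 - ((depth - half) / half) ** 2, 0.0, 1.0))
    azimuth = rng.uniform(0.0, 2 * np.pi, size=n_target)
    rad = r_at * np.sqrt(rng.uniform(0.0, 1.0, size=n_target))
    keep = rng.uniform(size=n_target) < np.exp(-occlusion_decay * depth)
    x = apex_xy[0] + rad[keep] * np.cos(azimuth[keep])
    y = apex_xy[1] + rad[keep] * np.sin(azimuth[keep])
    z = apex_z - depth[keep]
    apex = np.array([[apex_xy[0], apex_xy[1], apex_z]])
    return np.vstack([apex, np.column_stack([x, y, z])])


def generate_forest(spec: ForestSpec) -> tuple[PointCloud, pd.DataFrame]:
    """Generate a plot; returns (cloud with ground flags, truth table).

    The truth table has columns tree_id, x, y, height where (x, y) is
    the stem/apex position and height the normalized apex height.
    """
    rng = np.random.default_rng(spec.seed)
    # stems keep a small edge margin; crowns may overhang the plot edge
    margin = min(1.0, spec.crown_radius_range[1])
    sx_stem, sy_stem = _place_stems(spec, rng, margin)
    n = spec.n_trees
    heights = rng.uniform(*spec.height_range, size=n)
    radii = rng.uniform(*spec.crown_radius_range, size=n)
    if spec.crown_shape == "mixed":
        shapes = np.where(rng.uniform(size=n) < 0.5, "cone", "ellipsoid")
    else:
        shapes = np.full(n, spec.crown_shape)
    chunks = []
    for i in range(n):
        ground_z = float(terrain_height(spec, sx_stem[i], sy_stem[i]))
        chunks.append(
            _sample_crown(
                rng, shapes[i], (sx_stem[i], sy_stem[i]), ground_z + heights[i],
                radii[i], heights[i], spec.point_density, spec.occlusion_decay,
            )
        )
    crown_pts = np.vstack(chunks)
    sx, sy = spec.plot_size
    n_ground = max(3, int(round(spec.point_density / 10.0 * spec.area)))
    gx = rng.uniform(0.0, sx, size=n_ground)
    gy = rng.uniform(0.0, sy, size=n_ground)
    gz = terrain_height(spec, gx, gy)
    x = np.concatenate([crown_pts[:, 0], gx])
    y = np.concatenate([crown_pts[:, 1], gy])
    z = np.concatenate([crown_pts[:, 2], gz])
    ground = np.zeros(x.size, dtype=bool)
    ground[crown_pts.shape[0]:] = True
    cloud = PointCloud(x, y, z, ground=ground)
    truth = pd.DataFrame(
        {
            "tree_id": np.arange(1, n + 1),
            "x": sx_stem,
            "y": sy_stem,
            "height": heights,
        }
    )
    return cloud, truth


def generate_bifurcated_tree(spec: ForestSpec | None = None) -> tuple[PointCloud, pd.DataFrame]:
    """One tree whose crown carries two apices less than a crown radius apart.

    Ground truth is a single reference tree at the taller apex; without
    the plantation merge rule a pipeline typically reports two trees
    (one false positive), with it one.
    """
    spec = spec or ForestSpec(plot_size=(12.0, 12.0), stem_density=1.0 / 144.0,
                              slope_deg=0.0)
    rng = np.random.default_rng(spec.seed)
    cx, cy = spec.plot_size[0] / 2.0, spec.plot_size[1] / 2.0
    radius = float(np.mean(spec.crown_radius_range))
    height = float(np.mean(spec.height_range))
    ground_z = float(terrain_height(spec, cx, cy))
    offset = 0.8 * radius  # second apex < 1 crown radius away
    second_h = height - 1.5
    main = _sample_crown(rng, "cone", (cx, cy), ground_z + height, radius, height,
                         spec.point_density, spec.occlusion_decay)
    side = _sample_crown(rng, "cone", (cx + offset, cy), ground_z + second_h, radius,
                         second_h, spec.point_density, spec.occlusion_decay)
    sx, sy = spec.plot_size
    n_ground = max(3, int(round(spec.point_density / 10.0 * spec.area)))
    gx = rng.uniform(0.0, sx, size=n_ground)
    gy = rng.uniform(0.0, sy, size=n_ground)
    gz = terrain_height(spec, gx, gy)
    crown_pts = np.vstack([main, side])
    x = np.concatenate([crown_pts[:, 0], gx])
    y = np.concatenate([crown_pts[:, 1], gy])
    z = np.concatenate([crown_pts[:, 2], gz])
    ground = np.zeros(x.size, dtype=bool)
    ground[crown_pts.shape[0]:] = True
    cloud = PointCloud(x, y, z, ground=ground)
    truth = pd.DataFrame({"tree_id": [1], "x": [cx], "y": [cy], "height": [height]})
    return cloud, truth
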