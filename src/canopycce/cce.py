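"""Connection-center-evolution (CCE) clustering on weighted super-points.

The algorithm builds a weighted pairwise distance

    d_ij = n_i * n_j * sqrt(dx^2 + dy^2 + vr * dz^2)

(n_i are super-point weights, vr in (0, 1] down-weights vertical offsets
to compensate occlusion-thinned lower crowns), converts it to a Gaussian
similarity s~_ij = exp(-d_ij^2 / sigma^2), normalizes symmetrically by
degrees, S = D^(-1/2) S~ D^(-1/2), and then raises S to increasing powers
k. The entry S^k[i, j] is the k-order connectivity between points i and
j. A point whose k-order self-connectivity dominates its row is a
cluster center at scale k; every other point joins the center with the
greatest relative connectivity rcon_k(c, j) = S^k[c, j] / S^k[c, c].
Small k gives micro clusters (k = 1: every point a center), large k the
Perron-Frobenius limit of a single center per connected component. The
normalized cut of each partition ranks clusterings of equal size.

Because Eqs. for centers, assignment and Ncut are invariant to positive
scaling of S^k, the sweep renormalizes the matrix by its maximum after
every squaring; otherwise S^k (spectral radius <= 1) underflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import SuperPointSet

__all__ = [
    "CCEConfig",
    "ClusterResult",
    "build_distance_matrix",
    "gaussian_similarity",
    "normalize_similarity",
    "connectivity_power",
    "find_centers",
    "assign_points",
    "normalized_cut",
    "cce_sweep",
    "ConnectionCenterClustering",
]


@dataclass
class CCEConfig:
    """Tunable parameters of the CCE stage.

    vr : vertical distance correction factor in (0, 1]; default 1/6.
    sigma : Gaussian kernel scale in the (weighted) distance units; default 30.
    max_power : largest matrix power visited by the sweep (powers of two).
    weight_mode : "printed" multiplies distances by n_i*n_j; "none" ignores
        super-point weights (sensitivity switch).
    """

    vr: float = 1.0 / 6.0
    sigma: float = 30.0
    max_power: int = 2 ** 20
    weight_mode: str = "printed"

    def __post_init__(self) -> None:
        if not (0 < self.vr <= 1):
            raise ValueError("vr must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.max_power < 1:
            raise ValueError("max_power must be >= 1")
        if self.weight_mode not in ("printed", "none"):
            raise ValueError("weight_mode must be 'printed' or 'none'")

    @property
    def k_schedule(self) -> list[int]:
        ks, k = [], 1
        while k <= self.max_power:
            ks.append(k)
            k *= 2
        return ks


@dataclass
class ClusterResult:
    """Clustering of one segment's super-points at one scale k."""

    k: int
    centers: np.ndarray          # super-point indices, ascending
    assignment: np.ndarray       # index into `centers` per super-point
    ncut: float = np.nan

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.int64)
        self.assignment = np.asarray(self.assignment, dtype=np.int64)

    @property
    def m(self) -> int:
        return self.centers.size

    @property
    def labels(self) -> np.ndarray:
        """Cluster id (0..m-1) per super-point."""
        return self.assignment


def build_distance_matrix(sp, vr: float, weight_mode: str = "printed") -> np.ndarray:
    """Weighted anisotropic distance matrix D with zero diagonal."""
    if isinstance(sp, SuperPointSet):
        xyz, w = sp.centers, sp.weights.astype(np.float64)
    else:
        xyz = np.asarray(sp, dtype=np.float64)
        w = np.ones(xyz.shape[0])
    if not (0 < vr <= 1):
        raise ValueError("vr must be in (0, 1]")
    dx = xyz[:, 0][:, None] - xyz[:, 0][None, :]
    dy = xyz[:, 1][:, None] - xyz[:, 1][None, :]
    dz = xyz[:, 2][:, None] - xyz[:, 2][None, :]
    D = np.sqrt(dx * dx + dy * dy + vr * dz * dz)
    if weight_mode == "printed":
        D *= w[:, None] * w[None, :]
    np.fill_diagonal(D, 0.0)
    return D


def gaussian_similarity(D: np.ndarray, sigma: float) -> np.ndarray:
    """S~ = exp(-D^2 / sigma^2); unit diagonal, entries in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    S = np.exp(-(D * D) / (sigma * sigma))
    np.fill_diagonal(S, 1.0)
    return S


def normalize_similarity(S_tilde: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric degree normalization S = D^(-1/2) S~ D^(-1/2).

    Returns (S, degrees) with degrees d_i = sum_j s~_ij.
    """
    degrees = S_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(degrees)
    S = S_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    return S, degrees


def connectivity_power(S: np.ndarray, k: int) -> np.ndarray:
    """Exact k-th matrix power of S (k >= 1 integer)."""
    if k < 1 or k != int(k):
        raise ValueError("k must be a positive integer")
    return np.linalg.matrix_power(S, int(k))


def find_centers(S_k: np.ndarray) -> np.ndarray:
    """Indices whose diagonal entry dominates their row.

    Strict dominance is required; an exact off-diagonal tie is resolved
    in favor of the lower index (the lower-index point keeps center
    status, the higher-index one loses it), so degenerate symmetric
    configurations still yield a deterministic center set.
    """
    diag = np.diag(S_k)
    n = S_k.shape[0]
    off = S_k - np.diag(diag)
    greater = off > diag[:, None]
    ties = (off == diag[:, None]) & ~np.eye(n, dtype=bool)
    # a tie with a lower-index point disqualifies; with a higher index it doesn't
    lower = np.tril(np.ones((n, n), dtype=bool), k=-1)
    bad = greater.any(axis=1) | (ties & lower).any(axis=1)
    return np.flatnonzero(~bad)


def assign_points(S_k: np.ndarray, centers: np.ndarray) -> ClusterResult:
    """Assign every point to the center of greatest relative connectivity.

    rcon_k(c, j) = S^k[c, j] / S^k[c, c]; ties go to the lowest center
    index. Centers assign to themselves (rcon = 1 is their row maximum).
    """
    centers = np.asarray(centers, dtype=np.int64)
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    rcon = S_k[centers, :] / np.diag(S_k)[centers][:, None]
    assignment = np.argmax(rcon, axis=0)  # first (lowest center) wins ties
    return ClusterResult(k=0, centers=centers, assignment=assignment)


def normalized_cut(S_k: np.ndarray, assignment: np.ndarray) -> float:
    """Ncut = sum_l cut(P_l, ~P_l) / Vol(P_l) over the partition."""
    assignment = np.asarray(assignment)
    parts = np.unique(assignment)
    total = 0.0
    for lab in parts:
        in_l = assignment == lab
        if not in_l.any():
            raise ValueError("empty partition part")
        vol = S_k[in_l, :].sum()
        cut = vol - S_k[np.ix_(in_l, in_l)].sum()
        total += cut / vol
    return float(total)


def cce_sweep(sp, config: CCEConfig | None = None) -> list[ClusterResult]:
    """Run the k-sweep (powers of two, repeated squaring with max-renorm).

    Returns one ClusterResult per visited k that produced a non-empty
    center set; stops early once a single cluster persists for two
    consecutive schedule entries.
    """
    config = config or CCEConfig()
    if isinstance(sp, SuperPointSet):
        n = sp.m
    else:
        n = np.asarray(sp).shape[0]
    D = build_distance_matrix(sp, config.vr, config.weight_mode)
    S_tilde = gaussian_similarity(D, config.sigma)
    S, _ = normalize_similarity(S_tilde)
    results: list[ClusterResult] = []
    M = S.copy()
    k = 1
    ones_run = 0
    while k <= config.max_power:
        centers = find_centers(M)
        if centers.size:
            res = assign_points(M, centers)
            res.k = k
            res.ncut = normalized_cut(M, res.assignment)
            results.append(res)
            ones_run = ones_run + 1 if res.m == 1 else 0
            if ones_run >= 2 or (res.m == 1 and n == 1):
                break
        k *= 2
        if k <= config.max_power:
            M = M @ M
            M = (M + M.T) / 2.0  # enforce symmetry against rounding
            mx = M.max()
            if mx > 0:
                M /= mx
    return results


class ConnectionCenterClustering(BaseEstimator, ClusterMixin):
    """Scale-swept CCE clusterer with crown-shape scale selection.

    ``fit(X, sample_weight=...)`` sweeps the connectivity scales on the
    (optionally weighted) points and chooses the scale whose clusters
    all look like plausible crowns (shape constraints on the tri-planar
    projections of the member points); among candidate scales the most
    frequent cluster count wins, then the lowest normalized cut.

    Attributes
    ----------
    labels_ : cluster id per input point.
    n_clusters_ : number of clusters of the selected scale.
    result_ : the selected :class:`ClusterResult` (None if no scale
        passed the shape constraints and the data were kept whole).
    results_ : every ClusterResult of the sweep.
    """

    def __init__(self, vr: float = 1.0 / 6.0, sigma: float = 30.0,
                 max_power: int = 2 ** 20, edge_fraction: float = 0.125,
                 weight_mode: str = "printed"):
        self.vr = vr
        self.sigma = sigma
        self.max_power = max_power
        self.edge_fraction = edge_fraction
        self.weight_mode = weight_mode

    def fit(self, X, y=None, sample_weight=None):
        from .scale import select_scale

        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be an (n, 3) coordinate array")
        n = X.shape[0]
        if sample_weight is None:
            sp = SuperPointSet(X, np.ones(n, dtype=np.int64), np.arange(n))
        else:
            w = np.asarray(sample_weight)
            sp = SuperPointSet(X, w, np.repeat(np.arange(n), w))
        config = CCEConfig(vr=self.vr, sigma=self.sigma, max_power=self.max_power,
                           weight_mode=self.weight_mode)
        self.results_ = cce_sweep(sp, config)
        member_map = np.arange(n)
        labels, chosen = select_scale(self.results_, X, member_map,
                                      edge_fraction=self.edge_fraction)
        self.labels_ = labels
        self.result_ = chosen
        self.n_clusters_ = int(labels.max()) + 1 if labels.size else 0
        return self
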