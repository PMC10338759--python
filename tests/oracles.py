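"""Independent brute-force oracles used to validate the implementation.

Everything here is written as plainly as possible (nested loops,
repeated scans, exhaustive enumeration) and shares no code with the
package's own algorithms.
"""

from __future__ import annotations

import itertools

import numpy as np

NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# -- watershed --------------------------------------------------------------

def naive_local_maxima(vals: np.ndarray, ext: int, min_height: float):
    """Window-scan local maxima; plateau keeps smallest (row, col) of its
    8-connected equal-height component."""
    n_rows, n_cols = vals.shape
    is_max = np.zeros(vals.shape, dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            v = vals[r, c]
            if not np.isfinite(v) or v < min_height:
                continue
            window = vals[max(0, r - ext): r + ext + 1, max(0, c - ext): c + ext + 1]
            if v >= np.nanmax(window[np.isfinite(window)]):
                is_max[r, c] = True
    seeds = []
    claimed = np.zeros(vals.shape, dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            if is_max[r, c] and not claimed[r, c]:
                # flood the equal-max component
                stack, comp = [(r, c)], []
                claimed[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr, dc in NEIGHBORS8:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < n_rows and 0 <= nc < n_cols
                                and is_max[nr, nc] and not claimed[nr, nc]):
                            claimed[nr, nc] = True
                            stack.append((nr, nc))
                seeds.append(min(comp))
    return sorted(seeds)


def naive_watershed(vals: np.ndarray, seeds, min_height: float, tolerance: float):
    """Repeated-scan flood + tolerance merging, all O(n^2) loops."""
    n_rows, n_cols = vals.shape
    labels = np.zeros(vals.shape, dtype=np.int64)
    for lab, (r, c) in enumerate(seeds, start=1):
        labels[r, c] = lab
    mask = np.isfinite(vals) & (vals >= min_height)
    while True:
        best = None  # (-h, r, c)
        for r in range(n_rows):
            for c in range(n_cols):
                if labels[r, c] != 0 or not mask[r, c]:
                    continue
                touches = any(
                    0 <= r + dr < n_rows and 0 <= c + dc < n_cols
                    and labels[r + dr, c + dc] > 0
                    for dr, dc in NEIGHBORS8
                )
                if touches:
                    key = (-vals[r, c], r, c)
                    if best is None or key < best:
                        best = key
        if best is None:
            break
        _, r, c = best
        nb_h, nb_lab = -np.inf, 0
        for dr, dc in NEIGHBORS8:
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols and labels[nr, nc] > 0:
                h = vals[nr, nc]
                if h > nb_h or (h == nb_h and labels[nr, nc] < nb_lab):
                    nb_h, nb_lab = h, labels[nr, nc]
        labels[r, c] = nb_lab
    # tolerance merging, one merge per pass, ascending seed height
    seed_of = {lab: rc for lab, rc in enumerate(seeds, start=1)}
    seed_h = {lab: vals[rc] for lab, rc in seed_of.items()}
    alive = sorted(seed_of)
    while True:
        merged = False
        for lab in sorted(alive, key=lambda l: (seed_h[l], l)):
            contact = -np.inf
            neighbor_saddle: dict[int, float] = {}
            for r in range(n_rows):
                for c in range(n_cols):
                    if labels[r, c] != lab:
                        continue
                    for dr, dc in NEIGHBORS8:
                        nr, nc = r + dr, c + dc
                        if (0 <= nr < n_rows and 0 <= nc < n_cols
                                and labels[nr, nc] > 0 and labels[nr, nc] != lab):
                            s = min(vals[r, c], vals[nr, nc])
                            other = labels[nr, nc]
                            contact = max(contact, s)
                            neighbor_saddle[other] = max(
                                neighbor_saddle.get(other, -np.inf), s)
            if not np.isfinite(contact):
                continue
            if seed_h[lab] - contact < tolerance:
                target = max(neighbor_saddle, key=lambda b: (seed_h[b], -b))
                labels[labels == lab] = target
                alive.remove(lab)
                del seed_h[lab], seed_of[lab]
                merged = True
                break
        if not merged:
            break
    remap = {lab: i for i, lab in enumerate(sorted(alive), start=1)}
    out = np.zeros_like(labels)
    for lab, new in remap.items():
        out[labels == lab] = new
    return out, [seed_of[lab] for lab in sorted(alive)]


def two_bump_chm(rng: np.random.Generator, n: int = 30):
    """Random CHM with two Gaussian bumps and mild noise, values >= 0."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c1 = rng.uniform(n * 0.2, n * 0.45, size=2)
    c2 = rng.uniform(n * 0.55, n * 0.8, size=2)
    h1, h2 = rng.uniform(8.0, 20.0, size=2)
    s1, s2 = rng.uniform(2.0, 4.5, size=2)
    vals = (
        h1 * np.exp(-(((xx - c1[0]) ** 2 + (yy - c1[1]) ** 2) / (2 * s1 ** 2)))
        + h2 * np.exp(-(((xx - c2[0]) ** 2 + (yy - c2[1]) ** 2) / (2 * s2 ** 2)))
        + rng.uniform(0, 0.3, size=(n, n))
    )
    return vals


# -- CCE --------------------------------------------------------------------

def naive_matrix_power(S: np.ndarray, k: int) -> np.ndarray:
    out = S.copy()
    for _ in range(k - 1):
        out = out @ S
    return out


def brute_force_centers(S_k: np.ndarray) -> list[int]:
    """Row-by-row scan of the center condition with lower-index tie rule."""
    n = S_k.shape[0]
    centers = []
    for i in range(n):
        ok = True
        for j in range(n):
            if j == i:
                continue
            if S_k[i, j] > S_k[i, i]:
                ok = False
            elif S_k[i, j] == S_k[i, i] and j < i:
                ok = False
        if ok:
            centers.append(i)
    return centers


def brute_force_assignment(S_k: np.ndarray, centers: list[int]) -> list[int]:
    """Per-point scan of relative connectivity, lowest center wins ties."""
    assignment = []
    for j in range(S_k.shape[0]):
        best_val, best_c = -np.inf, None
        for ci, c in enumerate(centers):
            rcon = S_k[c, j] / S_k[c, c]
            if rcon > best_val:
                best_val, best_c = rcon, ci
        assignment.append(best_c)
    return assignment


# -- matching ---------------------------------------------------------------

def brute_force_matching(detected, reference, max_xy_dist, max_rel_height_diff):
    """Exhaustive best one-to-one matching under the same criterion.

    Feasible pairs respect the distance and relative-height thresholds.
    The best matching maximizes pair count, then minimizes total height
    difference, then total distance.
    """
    det = detected.reset_index(drop=True)
    ref = reference.reset_index(drop=True)
    feasible = []
    for i in range(len(det)):
        for j in range(len(ref)):
            dist = np.hypot(det.x[i] - ref.x[j], det.y[i] - ref.y[j])
            hdiff = abs(det.height[i] - ref.height[j])
            if dist <= max_xy_dist and hdiff <= max_rel_height_diff * ref.height[j]:
                feasible.append((i, j, hdiff, dist))
    best = (0, np.inf, np.inf, [])
    n_det = len(det)
    for size in range(min(n_det, len(ref)), -1, -1):
        for det_subset in itertools.combinations(range(n_det), size):
            pool = [f for f in feasible if f[0] in det_subset]
            for perm in itertools.permutations(range(len(ref)), size):
                pairing = []
                ok = True
                for di, rj in zip(det_subset, perm):
                    match = [f for f in pool if f[0] == di and f[1] == rj]
                    if not match:
                        ok = False
                        break
                    pairing.append(match[0])
                if not ok:
                    continue
                tot_h = sum(p[2] for p in pairing)
                tot_d = sum(p[3] for p in pairing)
                cand = (-size, tot_h, tot_d)
                if cand < (-best[0], best[1], best[2]):
                    best = (size, tot_h, tot_d, [(p[0], p[1]) for p in pairing])
        if best[0] == size and best[0] > 0:
            break
    return best[3]
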