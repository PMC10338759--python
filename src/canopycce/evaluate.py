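"""Detection matching and forest-inventory accuracy metrics.

Detected trees are matched one-to-one to reference trees, highest
detected tree first: candidates are the unmatched reference trees within
``max_xy_dist`` whose relative height difference is at most
``max_rel_height_diff``; the candidate with the smallest height
difference wins (distance breaks height ties). From the resulting
TP/FP/FN counts the five standard rates follow:

    R_extraction = (TP + FP) / (TP + FN)     detected / reference
    R_match      = TP / (TP + FN)            recall
    R_commission = FP / (TP + FP) = 1 - R_match / R_extraction
    R_omission   = FN / (TP + FN) = 1 - R_match
    F            = harmonic mean of R_match and R_match / R_extraction

Height accuracy of the matched pairs is reported as R^2 and RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MatchParams",
    "MatchReport",
    "match_trees",
    "compute_detection_metrics",
    "metrics_from_rates",
    "height_accuracy",
    "evaluate_detection",
]

log = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class MatchParams:
    max_xy_dist: float = 5.0            # m
    max_rel_height_diff: float = 0.2    # fraction of reference height

    def __post_init__(self) -> None:
        if self.max_xy_dist <= 0 or self.max_rel_height_diff <= 0:
            raise ValueError("matching thresholds must be positive")


@dataclass
class MatchReport:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple] = field(default_factory=list)  # (detected_id, reference_id)
    metrics: dict = field(default_factory=dict)
    height_r2: float = np.nan
    height_rmse: float = np.nan


def match_trees(detected: pd.DataFrame, reference: pd.DataFrame,
                params: MatchParams | None = None) -> MatchReport:
    """One-to-one matching of detected against reference trees."""
    params = params or MatchParams()
    if len(reference) == 0:
        raise EvaluationError("reference tree table is empty")
    det = detected.sort_values(["height", "tree_id"], ascending=[False, True])
    ref_x = reference["x"].to_numpy(dtype=float)
    ref_y = reference["y"].to_numpy(dtype=float)
    ref_h = reference["height"].to_numpy(dtype=float)
    ref_id = reference["tree_id"].to_numpy()
    taken = np.zeros(len(reference), dtype=bool)
    pairs = []
    for _, row in det.iterrows():
        dist = np.hypot(ref_x - row["x"], ref_y - row["y"])
        hdiff = np.abs(ref_h - row["height"])
        ok = (~taken) & (dist <= params.max_xy_dist) & (hdiff <= params.max_rel_height_diff * ref_h)
        if not ok.any():
            continue
        cand = np.flatnonzero(ok)
        # smallest height difference wins; distance breaks ties
        order = np.lexsort((dist[cand], hdiff[cand]))
        best = cand[order[0]]
        taken[best] = True
        pairs.append((row["tree_id"], ref_id[best]))
    tp = len(pairs)
    return MatchReport(tp=tp, fp=len(detected) - tp, fn=len(reference) - tp, pairs=pairs)


def compute_detection_metrics(tp: int, fp: int, fn: int) -> dict:
    """The five detection rates from TP/FP/FN counts."""
    n_ref = tp + fn
    if n_ref <= 0:
        raise EvaluationError("TP + FN must be positive (no reference trees)")
    r_match = tp / n_ref
    r_extraction = (tp + fp) / n_ref
    if tp + fp == 0:
        log.warning("no detected trees; commission rate reported as 0")
        r_commission = 0.0
    else:
        r_commission = fp / (tp + fp)
    r_omission = fn / n_ref
    if tp == 0:
        f = 0.0
    else:
        precision = tp / (tp + fp)
        f = 2 * r_match * precision / (r_match + precision)
    return {
        "R_match": r_match,
        "R_extraction": r_extraction,
        "F": f,
        "R_omission": r_omission,
        "R_commission": r_commission,
    }


def metrics_from_rates(r_match: float, r_extraction: float) -> dict:
    """Derive F, omission and commission from the two primary rates.

    Uses the printed identities: precision = R_match / R_extraction,
    F = 2 p r / (p + r), R_omission = 1 - R_match,
    R_commission = 1 - R_match / R_extraction.
    """
    if r_extraction <= 0:
        raise EvaluationError("R_extraction must be positive")
    precision = r_match / r_extraction
    f = 0.0 if r_match == 0 else 2 * r_match * precision / (r_match + precision)
    return {
        "R_match": r_match,
        "R_extraction": r_extraction,
        "F": f,
        "R_omission": 1.0 - r_match,
        "R_commission": 1.0 - precision,
    }


def height_accuracy(detected_heights, reference_heights) -> tuple[float, float]:
    """(R^2, RMSE) of detected vs reference heights of matched pairs."""
    d = np.asarray(detected_heights, dtype=float)
    r = np.asarray(reference_heights, dtype=float)
    if d.size < 2 or d.size != r.size:
        raise EvaluationError("height accuracy needs >= 2 matched pairs")
    ss_tot = float(((r - r.mean()) ** 2).sum())
    if ss_tot == 0:
        raise EvaluationError("reference heights have zero variance; R^2 undefined")
    ss_res = float(((d - r) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((d - r) ** 2)))
    return r2, rmse


def evaluate_detection(detected: pd.DataFrame, reference: pd.DataFrame,
                       params: MatchParams | None = None) -> MatchReport:
    """Full evaluation: matching, detection rates, height accuracy."""
    report = match_trees(detected, reference, params)
    report.metrics = compute_detection_metrics(report.tp, report.fp, report.fn)
    if report.tp >= 2:
        det_h = detected.set_index("tree_id")["height"]
        ref_h = reference.set_index("tree_id")["height"]
        d = [det_h[di] for di, _ in report.pairs]
        r = [ref_h[ri] for _, ri in report.pairs]
        try:
            report.height_r2, report.height_rmse = height_accuracy(d, r)
        except EvaluationError:
            pass
    return report
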