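"""Evaluation utilities scoring pipeline output against ground truth.

These are used by the test-bench and validation scripts: greedy spot
matching for detection precision/recall/F1, IoU-based cell matching for
segmentation, and entry-wise count-matrix agreement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .quantify import CountMatrix
from .segment import LabelVolume

__all__ = [
    "match_spots",
    "detection_scores",
    "match_cells_iou",
    "count_matrix_agreement",
    "gate_scores",
]


def match_spots(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    radius: float = 2.0,
    keys: tuple[str, ...] = ("fov", "round", "channel"),
) -> int:
    """Number of 1:1 matches within ``radius`` voxels, greedy by distance.

    Matching is restricted to spots sharing the grouping ``keys`` so a
    detection in one channel can never claim a true spot from another.
    """
    if detected.empty or truth.empty:
        return 0
    n_matched = 0
    t_groups = truth.groupby(list(keys)).indices
    for key, d_idx in detected.groupby(list(keys)).indices.items():
        t_idx = t_groups.get(key)
        if t_idx is None:
            continue
        d = detected.iloc[d_idx][["z", "y", "x"]].to_numpy(float)
        t = truth.iloc[t_idx][["z", "y", "x"]].to_numpy(float)
        pairs = cKDTree(d).query_ball_tree(cKDTree(t), r=radius)
        cands = [
            (float(np.linalg.norm(d[i] - t[j])), i, j)
            for i, js in enumerate(pairs)
            for j in js
        ]
        cands.sort()
        used_d: set[int] = set()
        used_t: set[int] = set()
        for _, i, j in cands:
            if i in used_d or j in used_t:
                continue
            used_d.add(i)
            used_t.add(j)
            n_matched += 1
    return n_matched


def detection_scores(
    detected: pd.DataFrame, truth: pd.DataFrame, radius: float = 2.0
) -> dict[str, float]:
    """Precision, recall and F1 of detections against true spots."""
    tp = match_spots(detected, truth, radius)
    precision = tp / len(detected) if len(detected) else 0.0
    recall = tp / len(truth) if len(truth) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1, "tp": tp}


def match_cells_iou(
    predicted: LabelVolume, truth: LabelVolume, iou_threshold: float = 0.5
) -> pd.DataFrame:
    """Greedy 1:1 matching of predicted to true cells by IoU.

    Returns a table (true_id, pred_id, iou); unmatched true cells appear
    with pred_id 0 and iou 0.
    """
    p, t = predicted.labels.ravel(), truth.labels.ravel()
    fg = (p > 0) | (t > 0)
    pairs, counts = np.unique(
        np.stack([t[fg], p[fg]]), axis=1, return_counts=True
    )
    t_sizes = {i: (t == i).sum() for i in np.unique(t) if i > 0}
    p_sizes = {i: (p == i).sum() for i in np.unique(p) if i > 0}
    cands = []
    for (ti, pi), inter in zip(pairs.T, counts):
        if ti == 0 or pi == 0:
            continue
        union = t_sizes[ti] + p_sizes[pi] - inter
        cands.append((inter / union, int(ti), int(pi)))
    cands.sort(reverse=True)
    used_t: set[int] = set()
    used_p: set[int] = set()
    rows = []
    for iou, ti, pi in cands:
        if ti in used_t or pi in used_p or iou < iou_threshold:
            continue
        used_t.add(ti)
        used_p.add(pi)
        rows.append({"true_id": ti, "pred_id": pi, "iou": float(iou)})
    for ti in t_sizes:
        if ti not in used_t:
            rows.append({"true_id": ti, "pred_id": 0, "iou": 0.0})
    return pd.DataFrame(rows, columns=["true_id", "pred_id", "iou"])


def count_matrix_agreement(
    measured: CountMatrix, truth: CountMatrix
) -> dict[str, float]:
    """Fraction of gene x cell entries agreeing exactly, on shared cells."""
    shared = [
        c for c in truth.cells["cell_id"] if c in set(measured.cells["cell_id"])
    ]
    mt = measured.to_frame()[shared].loc[truth.genes]
    tt = truth.to_frame()[shared].loc[truth.genes]
    exact = float((mt.to_numpy() == tt.to_numpy()).mean()) if shared else 0.0
    return {
        "exact_fraction": exact,
        "n_shared_cells": len(shared),
        "n_true_cells": truth.n_cells,
    }


def gate_scores(
    passing: set, truth_positive: set, universe: set | None = None
) -> dict[str, float]:
    """Precision/recall of a gated cell set against planted positives."""
    tp = len(passing & truth_positive)
    precision = tp / len(passing) if passing else 0.0
    recall = tp / len(truth_positive) if truth_positive else 0.0
    return {"precision": precision, "recall": recall, "tp": tp}
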