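"""Comparing pipeline output against phantom ground truth.

Segmented ROI labels and ground-truth labels generally disagree in
numbering, so structures are matched greedily by overlap before scoring
intersection-over-union or classification accuracy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def match_labels(pred: np.ndarray, true: np.ndarray) -> dict[int, int]:
    """Map each predicted label to the true label it overlaps most.

    Unmatched predictions map to 0.
    """
    mapping: dict[int, int] = {}
    for p in np.unique(pred):
        if p == 0:
            continue
        overlap = true[pred == p]
        overlap = overlap[overlap > 0]
        mapping[int(p)] = int(np.bincount(overlap).argmax()) if overlap.size else 0
    return mapping


def iou_per_structure(pred: np.ndarray, true: np.ndarray) -> dict[int, float]:
    """IoU for every true structure against its best-overlapping prediction.

    True structures with no overlapping prediction score 0.
    """
    mapping = match_labels(pred, true)
    inverse: dict[int, list[int]] = {}
    for p, t in mapping.items():
        inverse.setdefault(t, []).append(p)
    out: dict[int, float] = {}
    for t in np.unique(true):
        if t == 0:
            continue
        t_mask = true == t
        best = 0.0
        for p in inverse.get(int(t), []):
            p_mask = pred == p
            inter = np.count_nonzero(t_mask & p_mask)
            union = np.count_nonzero(t_mask | p_mask)
            best = max(best, inter / union if union else 0.0)
        out[int(t)] = best
    return out


def classification_accuracy(
    records: pd.DataFrame,
    truth: pd.DataFrame,
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
) -> tuple[float, pd.DataFrame]:
    """Five-way accuracy of predicted records against phantom truth.

    Predicted ROIs are matched to true islets by overlap; a true islet
    with no surviving matched record counts as an error.  Returns
    (accuracy, per-islet comparison table).
    """
    mapping = match_labels(pred_labels, true_labels)
    pred_cat = dict(zip(records["islet_id"], records["category"]))
    rows = []
    for row in truth.itertuples(index=False):
        t_id = int(row.islet_id)
        matched = [p for p, t in mapping.items() if t == t_id and p in pred_cat]
        predicted = pred_cat[matched[0]] if matched else "MISSED"
        rows.append(
            {"islet_id": t_id, "true_category": row.true_category,
             "predicted_category": predicted,
             "correct": predicted == row.true_category}
        )
    table = pd.DataFrame(rows)
    return float(table["correct"].mean()), table
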