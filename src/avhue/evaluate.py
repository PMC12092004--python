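"""Ground-truth evaluation helpers for synthetic scenes.

Matches detected vesicles to simulator ground truth by centroid
proximity (greedy nearest-pair, one-to-one) and scores subtype recovery
and per-neuron count agreement.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .segment import Vesicle
from .simulate import SyntheticGroundTruth

__all__ = ["match_vesicles", "classification_accuracy", "per_neuron_count_error"]


def match_vesicles(
    gt: SyntheticGroundTruth,
    vesicles: Sequence[Vesicle],
    max_dist_px: float | None = None,
) -> pd.DataFrame:
    """Greedy one-to-one matching of ground-truth vesicles to detections.

    A ground-truth vesicle may match a detection whose centroid lies within
    ``max(2 px, its own radius)`` (or ``max_dist_px`` when given); closest
    pairs are committed first.  Returns one row per ground-truth vesicle with
    the matched detection id (or -1), true subtype, and predicted subtype.
    """
    truth = gt.vesicles
    det_centroids = np.array([v.centroid for v in vesicles], float).reshape(-1, 2)
    det_subtypes = [getattr(v.subtype, "value", v.subtype) for v in vesicles]

    pairs: list[tuple[float, int, int]] = []
    for gi, row in enumerate(truth.itertuples(index=False)):
        limit = max_dist_px if max_dist_px is not None else max(2.0, float(row.radius_px))
        if len(det_centroids) == 0:
            continue
        d = np.hypot(det_centroids[:, 0] - row.row, det_centroids[:, 1] - row.col)
        for di in np.flatnonzero(d <= limit):
            pairs.append((float(d[di]), gi, int(di)))
    pairs.sort()
    matched_gt: dict[int, int] = {}
    used_det: set[int] = set()
    for _, gi, di in pairs:
        if gi in matched_gt or di in used_det:
            continue
        matched_gt[gi] = di
        used_det.add(di)

    rows = []
    for gi, row in enumerate(truth.itertuples(index=False)):
        di = matched_gt.get(gi, -1)
        rows.append(
            {
                "gt_vesicle_id": int(row.vesicle_id),
                "neuron_id": int(row.neuron_id),
                "true_subtype": row.subtype,
                "detection_id": int(vesicles[di].id) if di >= 0 else -1,
                "predicted_subtype": det_subtypes[di] if di >= 0 else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gt_vesicle_id", "neuron_id", "true_subtype", "detection_id", "predicted_subtype"],
    )


def classification_accuracy(gt: SyntheticGroundTruth, vesicles: Sequence[Vesicle]) -> float:
    """Fraction of ground-truth vesicles recovered with their true subtype.

    Unmatched ground-truth vesicles count as errors.
    """
    matches = match_vesicles(gt, vesicles)
    if matches.empty:
        return float("nan")
    correct = (matches["predicted_subtype"] == matches["true_subtype"]).sum()
    return float(correct) / float(len(matches))


def per_neuron_count_error(gt: SyntheticGroundTruth, vesicles: Sequence[Vesicle]) -> pd.DataFrame:
    """Detected vs. true total vesicle count per neuron."""
    detected = pd.Series([v.neuron_id for v in vesicles if v.neuron_id > 0]).value_counts()
    rows = []
    for row in gt.composition.itertuples(index=False):
        nid = int(row.neuron_id)
        rows.append(
            {
                "neuron_id": nid,
                "true_count": int(row.total),
                "detected_count": int(detected.get(nid, 0)),
            }
        )
    frame = pd.DataFrame(rows, columns=["neuron_id", "true_count", "detected_count"])
    frame["error"] = frame["detected_count"] - frame["true_count"]
    return frame
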