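"""Ground-truth evaluation helpers for the synthetic benchmark.

Matches detections to simulated ground-truth positions (one-to-one,
globally optimal within a gating radius) and scores tracking output
against ground-truth trajectories.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def match_points(detected, truth, radius: float):
    """One-to-one matching of two point sets within ``radius``.

    Returns (pairs, unmatched_detected, unmatched_truth); pairs is a
    list of (detected_index, truth_index) minimizing total distance.
    """
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    n, m = len(detected), len(truth)
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    d = np.hypot(detected[:, None, 0] - truth[None, :, 0],
                 detected[:, None, 1] - truth[None, :, 1])
    big = 10 * radius * max(n, m) + 1.0
    cost = np.where(d <= radius, d, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if d[r, c] <= radius]
    matched_d = {r for r, _ in pairs}
    matched_t = {c for _, c in pairs}
    return (pairs, [i for i in range(n) if i not in matched_d],
            [j for j in range(m) if j not in matched_t])


def detection_scores(detections_by_frame, gt_tracks, radius: float = 2.0):
    """Frame-wise recall and precision of detections vs ground truth."""
    truth_by_frame = {}
    for tr in gt_tracks:
        for f, x, y in zip(tr.frames, tr.x_px, tr.y_px):
            truth_by_frame.setdefault(int(f), []).append((x, y))
    tp = fp = fn = 0
    for f, dets in enumerate(detections_by_frame):
        det_xy = [(d.x_px, d.y_px) for d in dets]
        truth = truth_by_frame.get(f, [])
        pairs, un_d, un_t = match_points(det_xy, truth, radius)
        tp += len(pairs)
        fp += len(un_d)
        fn += len(un_t)
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return {"recall": recall, "precision": precision,
            "tp": tp, "fp": fp, "fn": fn}


def assign_tracks_to_truth(tracks, gt_tracks, radius: float = 3.0):
    """Per-observation assignment of each track to ground-truth cells.

    Returns, per track, the sequence of ground-truth cell ids its
    observations fall on (within ``radius``; -1 when none), and the
    number of identity switches (changes of assigned cell along a
    track, ignoring unassigned observations).
    """
    truth_by_frame = {}
    for tr in gt_tracks:
        for f, x, y in zip(tr.frames, tr.x_px, tr.y_px):
            truth_by_frame.setdefault(int(f), []).append((tr.cell_id, x, y))
    assignments, switches = {}, {}
    for tr in tracks:
        ids = []
        for f, x, y in zip(tr.frames, tr.x, tr.y):
            best, best_d = -1, radius
            for cid, tx, ty in truth_by_frame.get(int(f), []):
                d = float(np.hypot(x - tx, y - ty))
                if d <= best_d:
                    best, best_d = cid, d
            ids.append(best)
        assigned = [i for i in ids if i >= 0]
        n_switch = sum(1 for a, b in zip(assigned, assigned[1:]) if a != b)
        assignments[tr.track_id] = ids
        switches[tr.track_id] = n_switch
    return assignments, switches
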