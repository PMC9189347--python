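"""Two-pass linear-assignment-problem (LAP) cell tracking.

Pass 1 links detections between consecutive frames; pass 2 joins the
resulting track segments across short detection gaps.  Both passes
solve a global assignment in which every detection (or segment end)
may alternatively stay unmatched at a "birth/death" cost priced just
above the most expensive admissible link, so linking is always
preferred when admissible but never forced.

Because the channels confine motion to lanes stacked along y, linking
costs penalize cross-lane (y) displacement.  The default ``anisotropic``
cost is  c = dx² + (1 + w)·dy²  with weight w; an alternative
``trackmate`` mode reproduces the TrackMate feature-penalty convention
p = 3·w·|y_a − y_b| / (y_a + y_b),  c = d²·(1 + p)².  Gating always
uses the plain Euclidean distance, which keeps the distance bounds
(100 px linking, 150 px gap closing) interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

_BIG = 1e30


@dataclass(frozen=True)
class LinkingParams:
    """LAP tracker parameters (defaults match the microchannel assays)."""

    max_link_dist: float = 100.0
    max_gap_dist: float = 150.0
    max_gap_frames: int = 15
    y_penalty_weight: float = 15.0
    penalty_mode: str = "anisotropic"   # or "trackmate"
    alternative_cost_factor: float = 1.05

    def __post_init__(self):
        if self.max_link_dist <= 0 or self.max_gap_dist <= 0:
            raise ValueError("distance bounds must be > 0")
        if self.max_gap_frames < 1:
            raise ValueError("max_gap_frames must be >= 1")
        if self.y_penalty_weight < 0:
            raise ValueError("y_penalty_weight must be >= 0")
        if self.penalty_mode not in ("anisotropic", "trackmate"):
            raise ValueError("penalty_mode must be 'anisotropic' or 'trackmate'")
        if self.alternative_cost_factor <= 1.0:
            raise ValueError("alternative_cost_factor must be > 1")


@dataclass
class Track:
    """A time-ordered sequence of linked detections (gaps allowed)."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    det_labels: list = field(default_factory=list)
    flagged_short: bool = False

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self):
        return len(self.frames)

    @property
    def observations(self):
        return list(zip(self.frames.tolist(), self.x.tolist(), self.y.tolist()))


def pair_cost(ax, ay, bx, by, params: LinkingParams) -> float:
    """Penalized linking cost between two positions."""
    dx, dy = bx - ax, by - ay
    if params.penalty_mode == "anisotropic":
        return dx * dx + (1.0 + params.y_penalty_weight) * dy * dy
    d2 = dx * dx + dy * dy
    denom = ay + by
    p = 3.0 * params.y_penalty_weight * abs(ay - by) / denom if denom != 0 else 0.0
    return d2 * (1.0 + p) ** 2


def _solve_lap(cost: np.ndarray, alt_factor: float):
    """Solve the augmented assignment.

    ``cost`` is the n×m admissible-link matrix with ``np.inf`` where the
    gate forbids a link.  Returns (links, unmatched_rows, unmatched_cols,
    total_cost) where total_cost = Σ link costs + b·(#unmatched), with
    b = alt_factor × max admissible cost.
    """
    n, m = cost.shape
    finite = np.isfinite(cost)
    if not finite.any():
        return [], list(range(n)), list(range(m)), 0.0
    b = alt_factor * float(cost[finite].max())
    if b <= 0:
        b = alt_factor  # all admissible costs are zero; still prefer linking
    aug = np.full((n + m, n + m), _BIG)
    aug[:n, :m] = np.where(finite, cost, _BIG)
    aug[np.arange(n), m + np.arange(n)] = b          # death of row i
    aug[n + np.arange(m), np.arange(m)] = b          # birth of column j
    aug[n:, m:] = 0.0                                # completion block
    rows, cols = linear_sum_assignment(aug)
    links, un_a, un_b = [], [], []
    for r, c in zip(rows, cols):
        if r < n and c < m:
            if finite[r, c]:
                links.append((int(r), int(c)))
            else:  # forced infeasible pairing cannot occur: alternatives exist
                un_a.append(int(r))
                un_b.append(int(c))
        elif r < n:
            un_a.append(int(r))
        elif c < m:
            un_b.append(int(c))
    total = sum(cost[r, c] for r, c in links) + b * (len(un_a) + len(un_b))
    links.sort()
    return links, sorted(un_a), sorted(un_b), float(total)


def link_frames(dets_a, dets_b, params: LinkingParams | None = None):
    """Link detections of two consecutive frames.

    Pairs farther apart than ``max_link_dist`` (Euclidean) are
    forbidden; among admissible assignments the globally cheapest is
    returned.  Returns ``(links, unmatched_a, unmatched_b, total_cost)``
    with links as (index in a, index in b) pairs.
    """
    params = params or LinkingParams()
    n, m = len(dets_a), len(dets_b)
    cost = np.full((n, m), np.inf)
    for i, da in enumerate(dets_a):
        for j, db in enumerate(dets_b):
            dist = np.hypot(db.x_px - da.x_px, db.y_px - da.y_px)
            if dist <= params.max_link_dist:
                cost[i, j] = pair_cost(da.x_px, da.y_px, db.x_px, db.y_px, params)
    return _solve_lap(cost, params.alternative_cost_factor)


def _gap_cost_matrix(segments, params: LinkingParams):
    n = len(segments)
    cost = np.full((n, n), np.inf)
    for i, seg_end in enumerate(segments):
        ef, ex, ey = seg_end.frames[-1], seg_end.x[-1], seg_end.y[-1]
        for j, seg_start in enumerate(segments):
            if i == j:
                continue
            sf, sx, sy = seg_start.frames[0], seg_start.x[0], seg_start.y[0]
            dt = sf - ef
            if not (1 <= dt <= params.max_gap_frames + 1):
                continue
            if np.hypot(sx - ex, sy - ey) > params.max_gap_dist:
                continue
            cost[i, j] = pair_cost(ex, ey, sx, sy, params)
    return cost


def close_gaps(segments, params: LinkingParams | None = None):
    """Join track segments across detection gaps.

    A segment end may join a later segment start if the frame gap is at
    most ``max_gap_frames`` (i.e. start − end ≤ max_gap_frames + 1) and
    the Euclidean distance at most ``max_gap_dist``.  A second LAP picks
    the cheapest non-conflicting set of joins; joined tracks concatenate
    their observations without interpolating across the gap.
    """
    params = params or LinkingParams()
    segments = list(segments)
    if len(segments) < 2:
        return [replace(s) for s in segments]
    cost = _gap_cost_matrix(segments, params)
    links, _, _, _ = _solve_lap(cost, params.alternative_cost_factor)
    follower = dict(links)                     # end index -> start index
    has_predecessor = {j for _, j in links}
    merged = []
    for i, seg in enumerate(segments):
        if i in has_predecessor:
            continue
        chain = [i]
        while chain[-1] in follower:
            chain.append(follower[chain[-1]])
        parts = [segments[k] for k in chain]
        merged.append(Track(
            track_id=seg.track_id,
            frames=np.concatenate([p.frames for p in parts]),
            x=np.concatenate([p.x for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            det_labels=[lbl for p in parts for lbl in p.det_labels]))
    return merged


def track_movie(detections_by_frame, params: LinkingParams | None = None,
                min_track_length: int = 5):
    """Full tracking pass over a movie's detections.

    ``detections_by_frame`` is a sequence of per-frame detection lists
    (index = frame).  Frame-to-frame linking runs over every consecutive
    frame pair, then gap closing joins segments across dropouts.  Tracks
    shorter than ``min_track_length`` observations are flagged, not
    deleted; every detection ends up in exactly one track.
    """
    params = params or LinkingParams()
    frames = list(detections_by_frame)
    segments = []
    open_by_index = {}    # detection index in current frame -> segment
    next_id = 0
    prev = []
    for f, dets in enumerate(frames):
        if f == 0:
            links, un_a, un_b = [], [], list(range(len(dets)))
        else:
            links, un_a, un_b, _ = link_frames(prev, dets, params)
        new_open = {}
        for i, j in links:
            seg = open_by_index[i]
            seg["frames"].append(f)
            seg["x"].append(dets[j].x_px)
            seg["y"].append(dets[j].y_px)
            seg["labels"].append((f, dets[j].label))
            new_open[j] = seg
        for j in un_b:
            seg = {"id": next_id, "frames": [f], "x": [dets[j].x_px],
                   "y": [dets[j].y_px], "labels": [(f, dets[j].label)]}
            next_id += 1
            segments.append(seg)
            new_open[j] = seg
        open_by_index = new_open
        prev = dets
    seg_tracks = [Track(track_id=s["id"], frames=s["frames"], x=s["x"],
                        y=s["y"], det_labels=s["labels"]) for s in segments]
    tracks = close_gaps(seg_tracks, params)
    for tr in tracks:
        tr.flagged_short = len(tr) < min_track_length
    tracks.sort(key=lambda t: t.track_id)
    return tracks


def tracks_to_dataframe(tracks) -> pd.DataFrame:
    rows = [(t.track_id, int(f), float(x), float(y), t.flagged_short)
            for t in tracks for f, x, y in zip(t.frames, t.x, t.y)]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px",
                                       "flagged_short"])


def dataframe_to_tracks(df: pd.DataFrame):
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        flagged = bool(grp["flagged_short"].iloc[0]) if "flagged_short" in grp else False
        tracks.append(Track(track_id=int(tid), frames=grp["frame"].to_numpy(),
                            x=grp["x_px"].to_numpy(), y=grp["y_px"].to_numpy(),
                            flagged_short=flagged))
    return tracks
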