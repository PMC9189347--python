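"""Constriction-passage scoring from tracks.

A cell "passes" a constriction when its centroid trajectory moves from
the near side of the throat (beyond a margin) to the far side; the
entry frame is the last frame on the near side and the exit frame the
first frame on the far side, so the passage time is frame-quantized:
``(exit − entry) × frame_interval``.  A cell that approaches, dwells
and retreats without emerging on the far side produces no event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ChannelGeometry

DEFAULT_MARGIN_PX = 4.0  # one typical cell radius at 1 µm/px


@dataclass(frozen=True)
class PassageEvent:
    """One completed transit of one track through one constriction."""

    track_id: int
    constriction_index: int      # 1-based, ordered along the channel axis
    entry_frame: int             # last frame on the near side
    exit_frame: int              # first frame on the far side
    passage_time_min: float
    direction: int               # +1 rightward, -1 leftward

    def __post_init__(self):
        if self.exit_frame <= self.entry_frame:
            raise ValueError("exit_frame must be greater than entry_frame")
        if self.passage_time_min <= 0:
            raise ValueError("passage_time_min must be > 0")


def _sides(x: np.ndarray, lo: float, hi: float, margin: float) -> np.ndarray:
    """Classify axial positions: -1 near side, +1 far side, 0 within."""
    out = np.zeros(len(x), dtype=int)
    out[x < lo - margin] = -1
    out[x > hi + margin] = 1
    return out


def _crossings(frames, x, lo, hi, margin):
    """Yield (entry_frame, exit_frame, direction) for each side-to-side
    crossing of one throat.  Maximal intervals: entry is the last frame
    on the starting side, exit the first frame on the other side."""
    sides = _sides(np.asarray(x, dtype=float), lo, hi, margin)
    events = []
    prev_side = 0
    prev_frame = None
    for f, s in zip(frames, sides):
        if s == 0:
            continue
        if prev_side != 0 and s != prev_side:
            events.append((int(prev_frame), int(f), int(s)))
        prev_side = s
        prev_frame = f
    return events


def scripted_passages(frames, x, geometry: ChannelGeometry, margin_px: float):
    """Derive (constriction_index, entry_frame, exit_frame) triples from a
    trajectory by the same entry/exit rule the detector uses.  Used by the
    simulator to emit ground-truth passage events."""
    out = []
    for k in range(1, geometry.n_constrictions + 1):
        lo, hi = geometry.constriction_bounds_px(k)
        for entry, exit_, _direction in _crossings(frames, x, lo, hi, margin_px):
            out.append((k, entry, exit_))
    out.sort(key=lambda e: (e[1], e[0]))
    return out


def detect_passages(track, geometry: ChannelGeometry,
                    margin_px: float = DEFAULT_MARGIN_PX):
    """Detect completed constriction passages of one track.

    Parameters
    ----------
    track : object with ``track_id``, ``frames``, ``x`` attributes
        A track from the tracking stage (or a ground-truth track, in
        which case ``x_px`` is accepted too).
    geometry : ChannelGeometry
        Must be of kind ``"constriction"``.
    margin_px : float
        Distance beyond the throat ends that the centroid must clear to
        count as being on a side; default one typical cell radius.

    Returns a list of :class:`PassageEvent`, ordered by entry frame.
    """
    if geometry.kind != "constriction":
        raise ValueError("geometry must be a constriction channel")
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    frames = np.asarray(track.frames)
    x = np.asarray(track.x if hasattr(track, "x") else track.x_px, dtype=float)
    tid = int(getattr(track, "track_id", getattr(track, "cell_id", -1)))
    dt = geometry.frame_interval_min
    events = []
    for k in range(1, geometry.n_constrictions + 1):
        lo, hi = geometry.constriction_bounds_px(k)
        for entry, exit_, direction in _crossings(frames, x, lo, hi, margin_px):
            events.append(PassageEvent(track_id=tid, constriction_index=k,
                                       entry_frame=entry, exit_frame=exit_,
                                       passage_time_min=(exit_ - entry) * dt,
                                       direction=direction))
    events.sort(key=lambda e: (e.entry_frame, e.constriction_index))
    return events


def count_passages(events, n_constrictions: int = 4) -> np.ndarray:
    """Number of distinct tracks with at least one passage per constriction.

    A track oscillating back and forth through the same throat is
    counted once, regardless of direction.
    """
    counts = np.zeros(n_constrictions, dtype=int)
    for k in range(1, n_constrictions + 1):
        tracks = {e.track_id for e in events if e.constriction_index == k}
        counts[k - 1] = len(tracks)
    return counts


def first_passage_times(events):
    """Per-track time (min) to pass the first constriction.

    Returns ``(times, excluded)``: a dict mapping track_id to the
    minimum passage time at constriction 1, and the sorted list of
    track ids that produced events but never passed constriction 1.
    """
    times = {}
    seen = set()
    for e in events:
        seen.add(e.track_id)
        if e.constriction_index == 1:
            t = times.get(e.track_id)
            times[e.track_id] = e.passage_time_min if t is None else min(t, e.passage_time_min)
    excluded = sorted(seen - set(times))
    return times, excluded


def events_to_dataframe(events) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.track_id, e.constriction_index, e.entry_frame, e.exit_frame,
          e.passage_time_min, e.direction) for e in events],
        columns=["track_id", "constriction_index", "entry_frame",
                 "exit_frame", "passage_time_min", "direction"])
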