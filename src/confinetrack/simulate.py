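"""Synthetic microchannel movie generator with ground truth.

Renders phase-contrast-like time-lapse movies of lymphoma-sized cells
migrating inside microfabricated channels, together with the exact
per-frame centroid of every cell.  The generator exists so that the
downstream segmentation, tracking, motility and constriction-passage
stages can be validated end-to-end against a known answer.

Motion model
------------
Confined cells in channels narrower than their own diameter move
essentially one-dimensionally, so motile cells follow a persistent
random walk along the channel axis: each frame the cell advances
``speed × frame_interval / pixel_size`` pixels in its current
direction and reverses direction with probability ``switch_prob``.
A small cross-axis jitter (σ = 0.2 px) is always added — including to
"immotile" cells, which would otherwise be absorbed exactly into the
temporal-median background and become invisible by construction.

Appearance
----------
Cells are rendered as dark ellipses on a brighter background (the
segmentation recipe's black top-hat enhances locally dark objects);
fast uropod-bearing cells (mode ``A2``) carry a small trailing blob.
Channel walls are static and therefore removed by the temporal-median
background subtraction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ChannelGeometry
from .movie import MovieStack

CROSS_AXIS_JITTER_PX = 0.2
IMMOTILE_SPEED_BOUND = 0.05  # µm/min; at or below this a cell only jitters

MODES = ("immotile", "A1", "A2")


@dataclass
class CellSpec:
    """One simulated cell.

    ``mode`` follows the amoeboid-migration nomenclature: ``A1`` is slow
    crawling, ``A2`` fast migration with a uropod (trailing protrusion)
    at the rear; ``immotile`` cells only jitter in place.
    """

    mode: str = "A1"
    speed_um_per_min: float = 0.9
    switch_prob: float = 0.1
    radius_um: float = 3.5
    uropod: bool | None = None
    start_position_um: tuple | None = None
    start_frame: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.speed_um_per_min < 0:
            raise ValueError("speed must be >= 0")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")
        if self.radius_um <= 0:
            raise ValueError("radius must be > 0")
        if self.mode == "immotile" and self.speed_um_per_min > IMMOTILE_SPEED_BOUND:
            raise ValueError("immotile cells must have speed at or below "
                             f"{IMMOTILE_SPEED_BOUND} µm/min")
        if self.uropod is None:
            self.uropod = self.mode == "A2"
        if self.start_frame < 0:
            raise ValueError("start_frame must be >= 0")


@dataclass
class NoiseParams:
    """Imaging-noise and contrast model for rendered movies."""

    background_level: float = 200.0
    wall_contrast: float = 60.0
    gaussian_sigma: float = 0.0
    cell_contrast: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.cell_contrast <= 0:
            raise ValueError("cell_contrast must be > 0")


@dataclass
class GroundTruthTrack:
    """Exact trajectory of one simulated cell.

    ``passages`` lists scripted constriction-transit events as
    ``(constriction_index, entry_frame, exit_frame)`` with the 1-based
    constriction index, the last frame on the near side and the first
    frame on the far side.
    """

    cell_id: int
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    mode: str
    passages: list = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")


# ---------------------------------------------------------------------------
# rendering helpers

def _interior_mask(geometry: ChannelGeometry, shape) -> np.ndarray:
    """Boolean mask of the channel interior (True inside a lane)."""
    h, w = shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    half = 0.5 * geometry.channel_width_um / geometry.pixel_size_um
    inside = np.zeros((h, w), dtype=bool)
    for yc in geometry.lane_centers_px():
        lane = np.abs(rows - yc) <= half - 0.5
        inside |= np.broadcast_to(lane, (h, w))
    if geometry.kind == "constriction":
        chalf = 0.5 * geometry.constriction_width_um / geometry.pixel_size_um
        lhalf = 0.5 * geometry.constriction_length_um / geometry.pixel_size_um
        for xc in geometry.constriction_centers_px():
            throat_cols = np.abs(cols - xc) <= lhalf
            narrow = np.zeros((h, w), dtype=bool)
            for yc in geometry.lane_centers_px():
                narrow |= np.broadcast_to(np.abs(rows - yc) <= chalf - 0.5, (h, w))
            inside = np.where(throat_cols, inside & narrow, inside)
    return inside


def _paint_ellipse(canvas, interior, cx, cy, a, b, value):
    h, w = canvas.shape
    r0 = max(int(np.floor(cy - b - 2)), 0)
    r1 = min(int(np.ceil(cy + b + 2)) + 1, h)
    c0 = max(int(np.floor(cx - a - 2)), 0)
    c1 = min(int(np.ceil(cx + a + 2)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    mask = ((cols - cx) / a) ** 2 + ((rows - cy) / b) ** 2 <= 1.0
    mask &= interior[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1][mask] = value


def _render_frame(geometry, noise, interior, cell_states, rng):
    h, w = interior.shape
    bg = noise.background_level
    canvas = np.where(interior, bg, bg - noise.wall_contrast).astype(np.float64)
    value = bg - noise.cell_contrast
    for st in cell_states:
        _paint_ellipse(canvas, interior, st["x"], st["y"], st["a"], st["b"], value)
        if st.get("uropod"):
            ur = 0.45 * st["b"]
            ux = st["x"] - st["dir"] * (st["a"] + 0.5 * ur)
            _paint_ellipse(canvas, interior, ux, st["y"], ur, ur, value)
    if noise.gaussian_sigma > 0:
        canvas = canvas + rng.normal(0.0, noise.gaussian_sigma, size=canvas.shape)
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


def _auto_positions(geometry, cells):
    """Round-robin lane assignment.

    Straight channels spread cells evenly along the lane; constriction
    channels queue them near the channel entry, upstream of the first
    constriction, so that every cell approaches the throats from the
    near side.
    """
    n_lanes = len(geometry.lane_centers_um)
    w_um = geometry.channel_length_um
    per_lane = {}
    for j, cell in enumerate(cells):
        per_lane.setdefault(j % n_lanes, []).append(j)
    positions = [None] * len(cells)
    for lane, members in per_lane.items():
        yc = geometry.lane_centers_um[lane]
        for k, j in enumerate(members):
            if geometry.kind == "constriction":
                base = max(0.35 * geometry.constriction_centers_um[0],
                           cells[j].radius_um + 3.0)
                spacing = max(4.0 * cells[j].radius_um, 14.0)
                x = max(base - k * spacing, cells[j].radius_um + 2.0)
            else:
                x = w_um * (k + 1) / (len(members) + 1)
            positions[j] = (x, yc)
    return positions


def _resolve_starts(geometry, cells):
    px = geometry.pixel_size_um
    auto = _auto_positions(geometry, cells)
    starts = []
    lane_centers = np.asarray(geometry.lane_centers_px())
    for cell, fallback in zip(cells, auto):
        pos = cell.start_position_um if cell.start_position_um is not None else fallback
        x, y = pos[0] / px, pos[1] / px
        lane = int(np.argmin(np.abs(lane_centers - y)))
        starts.append((x, lane_centers[lane], lane))
    # reject overlapping starts within a lane
    for i in range(len(starts)):
        for j in range(i + 1, len(starts)):
            if starts[i][2] == starts[j][2]:
                min_sep = (cells[i].radius_um + cells[j].radius_um) / px
                if abs(starts[i][0] - starts[j][0]) < min_sep:
                    raise ValueError(f"cells {i} and {j} start overlapping "
                                     "in the same lane")
    return starts


# ---------------------------------------------------------------------------
# straight channels

def simulate_straight_movie(geometry: ChannelGeometry, cells, n_frames: int,
                            noise: NoiseParams):
    """Simulate a straight-channel movie.

    Returns ``(MovieStack, list of GroundTruthTrack)``.  Deterministic
    given ``noise.seed``; all randomness (direction reversals, jitter,
    imaging noise) comes from a single seeded generator.
    """
    if geometry.kind != "straight":
        raise ValueError("geometry must be a straight channel")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    px = geometry.pixel_size_um
    h, w = geometry.image_shape()
    for cell in cells:
        if 2 * cell.radius_um > geometry.channel_width_um:
            raise ValueError("cell diameter exceeds channel width")
        step = cell.speed_um_per_min * geometry.frame_interval_min / px
        if step >= w - 2 * (cell.radius_um / px + 2):
            raise ValueError("per-frame step exceeds channel length")
    starts = _resolve_starts(geometry, cells)
    rng = np.random.default_rng(noise.seed)
    interior = _interior_mask(geometry, (h, w))

    a_axes = [1.3 * c.radius_um / px for c in cells]
    b_axes = [min(c.radius_um / px,
                  0.5 * geometry.channel_width_um / px - 0.7) for c in cells]
    steps = [c.speed_um_per_min * geometry.frame_interval_min / px for c in cells]
    x = np.array([s[0] for s in starts], dtype=float)
    y0 = np.array([s[1] for s in starts], dtype=float)
    lanes = [s[2] for s in starts]
    y = y0.copy()
    dirs = np.where(rng.random(len(cells)) < 0.5, -1.0, 1.0)

    frames_data = np.empty((n_frames, h, w), dtype=np.uint8)
    gt = {j: {"frames": [], "x": [], "y": []} for j in range(len(cells))}

    for t in range(n_frames):
        states = []
        for j, cell in enumerate(cells):
            if t < cell.start_frame:
                continue
            gt[j]["frames"].append(t)
            gt[j]["x"].append(x[j])
            gt[j]["y"].append(y[j])
            states.append({"x": x[j], "y": y[j], "a": a_axes[j], "b": b_axes[j],
                           "dir": dirs[j], "uropod": cell.uropod})
        frames_data[t] = _render_frame(geometry, noise, interior, states, rng)

        # advance to the next frame
        for j, cell in enumerate(cells):
            if t + 1 < cell.start_frame or t == n_frames - 1:
                continue
            motile = cell.speed_um_per_min > IMMOTILE_SPEED_BOUND
            if not motile:
                x[j] = starts[j][0] + rng.normal(0, CROSS_AXIS_JITTER_PX)
                y[j] = y0[j] + rng.normal(0, CROSS_AXIS_JITTER_PX)
                continue
            if rng.random() < cell.switch_prob:
                dirs[j] = -dirs[j]
            margin = a_axes[j] + 1.5
            prop = x[j] + dirs[j] * steps[j]
            if prop < margin or prop > w - 1 - margin:
                dirs[j] = -dirs[j]
                prop = x[j] + dirs[j] * steps[j]
                if prop < margin or prop > w - 1 - margin:
                    prop = x[j]
            # same-lane collision: treat the neighbour as a wall
            for k in range(len(cells)):
                if k != j and lanes[k] == lanes[j]:
                    min_sep = (cells[j].radius_um + cells[k].radius_um) / px + 1
                    if abs(prop - x[k]) < min_sep:
                        dirs[j] = -dirs[j]
                        alt = x[j] + dirs[j] * steps[j]
                        if (margin <= alt <= w - 1 - margin
                                and abs(alt - x[k]) >= min_sep):
                            prop = alt
                        else:
                            prop = x[j]
                        break
            x[j] = prop
            y[j] = y0[j] + rng.normal(0, CROSS_AXIS_JITTER_PX)

    tracks = [GroundTruthTrack(cell_id=j, frames=gt[j]["frames"], x_px=gt[j]["x"],
                               y_px=gt[j]["y"], mode=cells[j].mode)
              for j in range(len(cells))]
    stack = MovieStack(frames_data, pixel_size_um=px,
                       frame_interval_min=geometry.frame_interval_min)
    return stack, tracks


# ---------------------------------------------------------------------------
# constriction channels

def simulate_constriction_movie(geometry: ChannelGeometry, cells, n_frames: int,
                                noise: NoiseParams, transit_delay_frames,
                                event_margin_px: float | None = None):
    """Simulate a constriction-channel movie with scripted transit delays.

    Each cell runs rightward at its programmed speed; on reaching a
    constriction entrance it holds position for ``transit_delay_frames``
    frames (its behavioural transit delay) and then emerges on the far
    side, so that the scripted passage satisfies
    ``exit_frame − entry_frame == delay``.  While inside the throat the
    cell is rendered compressed to fit the constriction width.  A delay
    of 0 means the cell traverses the throat at its normal speed.

    ``event_margin_px`` is the margin used to derive the scripted
    entry/exit frames from the trajectory (default: one cell radius),
    matching the margin convention of the passage detector.
    """
    if geometry.kind != "constriction":
        raise ValueError("geometry must be a constriction channel")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    delays = list(transit_delay_frames)
    if len(delays) != len(cells):
        raise ValueError("one transit delay per cell is required")
    for d in delays:
        if d < 0 or int(d) != d:
            raise ValueError("transit delays must be non-negative integers")
    px = geometry.pixel_size_um
    h, w = geometry.image_shape()
    starts = _resolve_starts(geometry, cells)
    rng = np.random.default_rng(noise.seed)
    interior = _interior_mask(geometry, (h, w))

    centers = geometry.constriction_centers_px()
    lhalf = 0.5 * geometry.constriction_length_um / px
    chalf = 0.5 * geometry.constriction_width_um / px
    clearance = 2.0

    x = np.array([s[0] for s in starts], dtype=float)
    y0 = np.array([s[1] for s in starts], dtype=float)
    y = y0.copy()
    steps = [c.speed_um_per_min * geometry.frame_interval_min / px for c in cells]
    a_axes = [1.3 * c.radius_um / px for c in cells]
    b_axes = [min(c.radius_um / px,
                  0.5 * geometry.channel_width_um / px - 0.7) for c in cells]
    margins = [(event_margin_px if event_margin_px is not None
                else c.radius_um / px) for c in cells]
    # first constriction ahead of each cell's start position
    target = [int(np.searchsorted(np.asarray(centers), x[j]))
              for j in range(len(cells))]
    phase = ["run"] * len(cells)
    counter = [0] * len(cells)
    dirs = np.ones(len(cells))  # post-completion bounce direction

    frames_data = np.empty((n_frames, h, w), dtype=np.uint8)
    gt = {j: {"frames": [], "x": [], "y": []} for j in range(len(cells))}

    def inside_throat(xj):
        return any(abs(xj - xc) < lhalf for xc in centers)

    for t in range(n_frames):
        states = []
        for j, cell in enumerate(cells):
            gt[j]["frames"].append(t)
            gt[j]["x"].append(x[j])
            gt[j]["y"].append(y[j])
            if inside_throat(x[j]):
                b = min(chalf - 0.3, b_axes[j])
                a = max(a_axes[j], 0.95 * (cell.radius_um / px) ** 2 / b)
            else:
                a, b = a_axes[j], b_axes[j]
            states.append({"x": x[j], "y": y[j], "a": a, "b": b,
                           "dir": 1.0, "uropod": cell.uropod})
        frames_data[t] = _render_frame(geometry, noise, interior, states, rng)

        if t == n_frames - 1:
            break
        for j, cell in enumerate(cells):
            k = target[j]
            if phase[j] == "run":
                if cell.speed_um_per_min <= IMMOTILE_SPEED_BOUND:
                    x[j] = starts[j][0] + rng.normal(0, CROSS_AXIS_JITTER_PX)
                elif k < len(centers):
                    prop = x[j] + steps[j]
                    wait_x = centers[k] - lhalf - margins[j] - clearance
                    if x[j] < wait_x <= prop and delays[j] > 0:
                        prop = wait_x
                        phase[j] = "transit"
                        counter[j] = 0
                    elif delays[j] == 0 and prop >= centers[k] + lhalf + margins[j] + clearance:
                        target[j] = k + 1
                    x[j] = min(prop, w - 1 - a_axes[j] - 2)
                else:
                    # finished all constrictions: bounce between the far
                    # side of the last throat and the channel end, so the
                    # cell keeps moving and never merges into the
                    # temporal-median background
                    low = centers[-1] + lhalf + margins[j] + clearance + 1
                    end = w - 1 - a_axes[j] - 2
                    prop = x[j] + dirs[j] * steps[j]
                    if prop > end or prop < low:
                        dirs[j] = -dirs[j]
                        prop = x[j] + dirs[j] * steps[j]
                        prop = min(max(prop, low), end)
                    x[j] = prop
            elif phase[j] == "transit":
                counter[j] += 1
                if counter[j] < delays[j]:
                    x[j] = centers[k]
                else:
                    x[j] = centers[k] + lhalf + margins[j] + clearance
                    phase[j] = "run"
                    target[j] = k + 1
            y[j] = y0[j] + rng.normal(0, CROSS_AXIS_JITTER_PX)

    tracks = []
    from .constrictions import scripted_passages  # shared entry/exit rule
    for j, cell in enumerate(cells):
        tr = GroundTruthTrack(cell_id=j, frames=gt[j]["frames"], x_px=gt[j]["x"],
                              y_px=gt[j]["y"], mode=cell.mode)
        tr.passages = scripted_passages(np.asarray(gt[j]["frames"]),
                                        np.asarray(gt[j]["x"]),
                                        geometry, margins[j])
        tracks.append(tr)
    stack = MovieStack(frames_data, pixel_size_um=px,
                       frame_interval_min=geometry.frame_interval_min)
    return stack, tracks


# ---------------------------------------------------------------------------
# ground-truth I/O

def write_ground_truth(tracks, path) -> None:
    """Write ground-truth tracks to CSV (cell_id, frame, x_px, y_px, mode)."""
    rows = []
    for tr in tracks:
        for f, xi, yi in zip(tr.frames, tr.x_px, tr.y_px):
            rows.append((tr.cell_id, int(f), float(xi), float(yi), tr.mode))
    df = pd.DataFrame(rows, columns=["cell_id", "frame", "x_px", "y_px", "mode"])
    df.to_csv(path, index=False)


def read_ground_truth(path):
    df = pd.read_csv(Path(path))
    tracks = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(GroundTruthTrack(cell_id=int(cid),
                                       frames=grp["frame"].to_numpy(),
                                       x_px=grp["x_px"].to_numpy(),
                                       y_px=grp["y_px"].to_numpy(),
                                       mode=str(grp["mode"].iloc[0])))
    return tracks


def write_scripted_passages(tracks, path) -> None:
    """Write scripted constriction-passage events to CSV."""
    rows = []
    for tr in tracks:
        for (k, entry, exit_) in tr.passages:
            rows.append((tr.cell_id, k, entry, exit_))
    df = pd.DataFrame(rows, columns=["cell_id", "constriction_index",
                                     "entry_frame", "exit_frame"])
    df.to_csv(path, index=False)
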