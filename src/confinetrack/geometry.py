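"""Microchannel geometry descriptions.

A :class:`ChannelGeometry` records the physical layout of a PDMS
microchannel chip in micrometres together with the imaging calibration
(µm per pixel, minutes per frame).  The same object is shared by the
movie simulator, which renders channel walls from it, and by the
constriction-passage analysis, which needs the constriction positions
to score entry and exit events.

Coordinate convention: ``x`` runs along the channel axis (image
columns), ``y`` across it (image rows).  Cells migrate along ``x``;
parallel lanes are stacked along ``y`` at ``lane_centers_um``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ChannelGeometry:
    """Layout of a straight or constriction-bearing microchannel array.

    Parameters
    ----------
    kind : {"straight", "constriction"}
        Channel type.  Constriction channels carry one or more narrowed
        throats along the channel axis.
    channel_width_um : float
        In-plane (cross-axis) channel width.
    channel_height_um : float
        Out-of-plane channel height; metadata only (the analysis is 2-D).
    channel_length_um : float
        Length of the imaged channel segment along the migration axis.
    lane_centers_um : tuple of float
        Cross-axis centres of the parallel lanes.
    constriction_width_um, constriction_length_um : float, optional
        Cross-axis width and axial length of each constriction throat
        (constriction channels only).
    constriction_centers_um : tuple of float
        Axial positions of the constriction centres, strictly increasing.
    pixel_size_um : float
        Image calibration, µm per pixel.
    frame_interval_min : float
        Time between consecutive frames, minutes.
    """

    kind: str
    channel_width_um: float
    channel_height_um: float
    channel_length_um: float
    lane_centers_um: tuple = ()
    constriction_width_um: float | None = None
    constriction_length_um: float | None = None
    constriction_centers_um: tuple = ()
    pixel_size_um: float = 1.0
    frame_interval_min: float = 10.0

    def __post_init__(self):
        if self.kind not in ("straight", "constriction"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        for name in ("channel_width_um", "channel_height_um",
                     "channel_length_um", "pixel_size_um",
                     "frame_interval_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.lane_centers_um:
            raise ValueError("at least one lane centre is required")
        object.__setattr__(self, "lane_centers_um",
                           tuple(float(c) for c in self.lane_centers_um))
        object.__setattr__(self, "constriction_centers_um",
                           tuple(float(c) for c in self.constriction_centers_um))
        if self.kind == "constriction":
            if self.constriction_width_um is None or self.constriction_length_um is None:
                raise ValueError("constriction channels need a constriction "
                                 "width and length")
            if self.constriction_width_um <= 0 or self.constriction_length_um <= 0:
                raise ValueError("constriction dimensions must be > 0")
            if self.constriction_width_um >= self.channel_width_um:
                raise ValueError("constriction must be narrower than the channel")
            if not self.constriction_centers_um:
                raise ValueError("constriction channels need constriction centres")
            cc = self.constriction_centers_um
            if any(b <= a for a, b in zip(cc, cc[1:])):
                raise ValueError("constriction centres must be strictly increasing")

    # -- pixel-space helpers -------------------------------------------------

    @property
    def n_constrictions(self) -> int:
        return len(self.constriction_centers_um)

    def image_shape(self) -> tuple:
        """(height, width) in pixels of a movie rendered on this geometry."""
        px = self.pixel_size_um
        h = math.ceil((max(self.lane_centers_um) + self.channel_width_um) / px)
        w = math.ceil(self.channel_length_um / px)
        return h, w

    def lane_centers_px(self) -> list:
        return [c / self.pixel_size_um for c in self.lane_centers_um]

    def constriction_centers_px(self) -> list:
        return [c / self.pixel_size_um for c in self.constriction_centers_um]

    def constriction_bounds_px(self, index: int) -> tuple:
        """(near, far) x bounds in pixels of the 1-based ``index``-th throat."""
        center = self.constriction_centers_um[index - 1] / self.pixel_size_um
        half = 0.5 * self.constriction_length_um / self.pixel_size_um
        return center - half, center + half


def straight_channel(n_lanes: int = 5, length_um: float = 400.0,
                     lane_pitch_um: float = 12.0,
                     channel_width_um: float = 8.0,
                     channel_height_um: float = 10.0,
                     pixel_size_um: float = 1.0,
                     frame_interval_min: float = 10.0) -> ChannelGeometry:
    """Straight-channel array as used for baseline lymphoma motility assays:
    8 µm wide, 10 µm high lanes imaged every 10 minutes."""
    centers = tuple(lane_pitch_um * (i + 0.5) for i in range(n_lanes))
    return ChannelGeometry(kind="straight",
                           channel_width_um=channel_width_um,
                           channel_height_um=channel_height_um,
                           channel_length_um=length_um,
                           lane_centers_um=centers,
                           pixel_size_um=pixel_size_um,
                           frame_interval_min=frame_interval_min)


def constriction_channel(n_lanes: int = 4, length_um: float = 320.0,
                         lane_pitch_um: float = 18.0,
                         channel_width_um: float = 12.0,
                         channel_height_um: float = 12.0,
                         constriction_width_um: float = 4.0,
                         constriction_length_um: float = 12.0,
                         n_constrictions: int = 4,
                         first_center_um: float = 80.0,
                         spacing_um: float = 60.0,
                         pixel_size_um: float = 1.0,
                         frame_interval_min: float = 4.0) -> ChannelGeometry:
    """Constriction-channel array: 12 µm × 12 µm lanes with 12 µm × 4 µm
    constriction throats, imaged every 4 minutes."""
    centers = tuple(first_center_um + spacing_um * i for i in range(n_constrictions))
    lanes = tuple(lane_pitch_um * (i + 0.5) for i in range(n_lanes))
    return ChannelGeometry(kind="constriction",
                           channel_width_um=channel_width_um,
                           channel_height_um=channel_height_um,
                           channel_length_um=length_um,
                           lane_centers_um=lanes,
                           constriction_width_um=constriction_width_um,
                           constriction_length_um=constriction_length_um,
                           constriction_centers_um=centers,
                           pixel_size_um=pixel_size_um,
                           frame_interval_min=frame_interval_min)
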