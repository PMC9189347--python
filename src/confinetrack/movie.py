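"""Time-lapse movie container and TIFF round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class MovieStack:
    """A T×H×W grayscale time-lapse stack with acquisition metadata.

    ``data`` holds raw intensities (8- or 16-bit unsigned in practice);
    ``pixel_size_um`` and ``frame_interval_min`` carry the spatial and
    temporal calibration needed to express motility in µm/min.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_min: float = 10.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be a T×H×W array")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("calibration values must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape


def write_movie(stack: MovieStack, path) -> None:
    """Write a movie as a multi-page grayscale TIFF (lossless)."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack",
                     metadata={"pixel_size_um": stack.pixel_size_um,
                               "frame_interval_min": stack.frame_interval_min})


def read_movie(path, pixel_size_um: float | None = None,
               frame_interval_min: float | None = None) -> MovieStack:
    """Read a multi-page TIFF; calibration can be overridden or is taken
    from the ImageJ-style metadata written by :func:`write_movie`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    px = pixel_size_um if pixel_size_um is not None else float(meta.get("pixel_size_um", 1.0))
    dt = (frame_interval_min if frame_interval_min is not None
          else float(meta.get("frame_interval_min", 10.0)))
    return MovieStack(data=data, pixel_size_um=px, frame_interval_min=dt)
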