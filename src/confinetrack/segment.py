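"""Five-step segmentation of microchannel time-lapse movies.

The recipe targets movies in which the only static structures are the
channel walls and the cells are locally dark:

1. a median filter removes shot noise from each frame;
2. a temporal-median background (per-pixel median over all frames)
   is subtracted, removing the microchannels from the image;
3. a mean filter smooths the residual;
4. a black top-hat (morphological closing minus image, disc structuring
   element) enhances the dark cells as a positive response;
5. a Yen threshold binarizes the response, followed by binary opening,
   hole filling, small-object removal and 8-connected labelling.

Static cells merge into the temporal-median background and are not
detected; this is inherent to the method, not a defect.  Subtraction is
kept signed (no clipping at zero) so that dark cells survive step 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.measure import label, regionprops
from skimage.morphology import black_tophat, disk

from .movie import MovieStack


@dataclass(frozen=True)
class SegmentationParams:
    """Filter sizes and cleanup thresholds for the segmentation recipe.

    The top-hat disc radius must exceed the cell radius so the closing
    can fill cells completely; defaults suit cells of radius ~3-5 px.
    """

    median_radius_px: int = 2
    mean_radius_px: int = 2
    tophat_radius_px: int = 15
    min_area_px2: int = 30
    opening_radius_px: int = 1
    fill_holes: bool = True

    def __post_init__(self):
        for name in ("median_radius_px", "mean_radius_px", "tophat_radius_px",
                     "opening_radius_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.min_area_px2 < 1:
            raise ValueError("min_area_px2 must be >= 1")


@dataclass(frozen=True)
class Detection:
    """One segmented cell in one frame.

    ``x_px`` is the centroid along the channel axis (image columns),
    ``y_px`` across it (image rows); both are subpixel, unweighted
    (binary) region centroids, 0-based with integer pixel centres.
    """

    frame: int
    label: int
    x_px: float
    y_px: float
    area_px2: int


def compute_background(stack) -> np.ndarray:
    """Per-pixel temporal median over all frames.

    For an even number of frames the lower midpoint of the two central
    order statistics is returned (a pure order statistic, so integer
    images yield integer backgrounds exactly).
    """
    data = stack.data if isinstance(stack, MovieStack) else np.asarray(stack)
    if data.ndim != 3 or data.shape[0] < 3:
        raise ValueError("background requires a stack of at least 3 frames")
    t = data.shape[0]
    srt = np.sort(data, axis=0)
    return srt[(t - 1) // 2]


def yen_threshold(histogram) -> int:
    """Threshold bin maximizing Yen's maximum-correlation criterion.

    With normalized bin frequencies p_i, P1(t) = Σ_{i<=t} p_i,
    G1(t) = Σ_{i<=t} p_i² and G2(t) = Σ_{i>t} p_i², the criterion is

        TC(t) = -ln(G1(t)·G2(t)) + 2·ln(P1(t)·(1-P1(t))).

    Bins with P1 ∈ {0, 1} are excluded; ties break toward the lowest
    bin.  Raises ``ValueError`` for a single-valued histogram, where no
    threshold exists.
    """
    counts = np.asarray(histogram, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("histogram must be a 1-D array of at least 2 bins")
    total = counts.sum()
    if np.count_nonzero(counts) < 2:
        raise ValueError("no threshold exists for a single-valued histogram")
    # histogram counts are integers: accumulate exactly in int64 and
    # divide once, so class probabilities carry no summation-order error
    if np.allclose(counts, np.round(counts)):
        ic = np.round(counts).astype(np.int64)
        csum = np.cumsum(ic)
        sq = np.cumsum(ic * ic)
        total_i = csum[-1]
        p1 = csum / total_i
        g1 = sq / (total_i * total_i)
        g2 = (sq[-1] - sq) / (total_i * total_i)
        valid = (csum > 0) & (csum < total_i)
    else:
        csum = np.cumsum(counts)
        p = counts / total
        p1 = csum / total
        g1 = np.cumsum(p * p)
        g2 = g1[-1] - g1
        valid = (csum > 0) & (csum < total)
    with np.errstate(divide="ignore", invalid="ignore"):
        tc = -np.log(g1 * g2) + 2 * np.log(p1 * (1.0 - p1))
    tc[~valid | ~np.isfinite(tc)] = -np.inf
    return int(np.argmax(tc))


def _disc_mean(image: np.ndarray, radius: int) -> np.ndarray:
    fp = disk(radius).astype(float)
    fp /= fp.sum()
    return ndi.convolve(image, fp, mode="nearest")


def _median_filter(image: np.ndarray, radius: int) -> np.ndarray:
    return ndi.median_filter(image, footprint=disk(radius), mode="nearest")


def _segment_residual(residual: np.ndarray, frame_index: int,
                      params: SegmentationParams):
    """Steps 3-5 on the signed background-subtracted residual."""
    smoothed = _disc_mean(residual, params.mean_radius_px)
    response = black_tophat(smoothed, disk(params.tophat_radius_px))
    lo, hi = float(response.min()), float(response.max())
    if hi - lo < 1e-9:
        return []
    scaled = np.round((response - lo) * (255.0 / (hi - lo))).astype(np.uint8)
    hist = np.bincount(scaled.ravel(), minlength=256)
    try:
        t = yen_threshold(hist)
    except ValueError:
        return []
    mask = scaled > t
    mask = ndi.binary_opening(mask, structure=disk(params.opening_radius_px))
    if params.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    labelled = label(mask, connectivity=2)
    dets = []
    next_label = 1
    for region in regionprops(labelled):
        if region.area < params.min_area_px2:
            continue
        cy, cx = region.centroid
        dets.append(Detection(frame=frame_index, label=next_label,
                              x_px=float(cx), y_px=float(cy),
                              area_px2=int(region.area)))
        next_label += 1
    return dets


def segment_frame(frame: np.ndarray, background: np.ndarray,
                  params: SegmentationParams | None = None, *,
                  frame_index: int = 0):
    """Segment one frame against a given background image.

    The frame is median-filtered, the background subtracted (signed),
    then smoothed, top-hat filtered, thresholded and cleaned up.
    Returns a list of :class:`Detection` (possibly empty).
    """
    params = params or SegmentationParams()
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background must have the same shape")
    filtered = _median_filter(frame, params.median_radius_px)
    return _segment_residual(filtered - background, frame_index, params)


def segment_movie(stack: MovieStack, params: SegmentationParams | None = None):
    """Segment every frame of a movie.

    The median filter is applied to each frame first and the temporal-
    median background is computed from the filtered frames, so frame and
    background live in the same (denoised) domain.  Returns a list of
    per-frame detection lists.
    """
    params = params or SegmentationParams()
    data = stack.data.astype(float)
    filtered = np.stack([_median_filter(data[t], params.median_radius_px)
                         for t in range(data.shape[0])])
    background = compute_background(filtered)
    return [_segment_residual(filtered[t] - background, t, params)
            for t in range(data.shape[0])]


def detections_to_dataframe(detections_by_frame) -> pd.DataFrame:
    rows = [(d.frame, d.label, d.x_px, d.y_px, d.area_px2)
            for dets in detections_by_frame for d in dets]
    return pd.DataFrame(rows, columns=["frame", "label", "x_px", "y_px", "area_px2"])


def dataframe_to_detections(df: pd.DataFrame):
    """Group a detections table back into per-frame lists."""
    if len(df) == 0:
        return []
    n = int(df["frame"].max()) + 1
    out = [[] for _ in range(n)]
    for row in df.itertuples(index=False):
        out[int(row.frame)].append(Detection(frame=int(row.frame),
                                             label=int(row.label),
                                             x_px=float(row.x_px),
                                             y_px=float(row.y_px),
                                             area_px2=int(row.area_px2)))
    return out
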