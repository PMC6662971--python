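"""Background modelling, intermodes binarization and blob detection.

The segmentation chain mirrors a classical tank-video workflow: build a
median time-projection background, take the absolute difference per
frame, binarize with the intermodes histogram threshold, clean the mask
with a median filter, and keep 8-connected components inside a size
gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .video_io import GrayFrame

__all__ = [
    "BackgroundModel",
    "BinaryMask",
    "Detection",
    "NotBimodalError",
    "median_projection",
    "subtract_background",
    "intermodes_threshold",
    "segment_frame",
]

MAX_SMOOTHING_ITERATIONS = 10_000


class NotBimodalError(ValueError):
    """Raised when a histogram cannot be smoothed into exactly two modes."""


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pixel temporal median of a greyscale sequence."""

    values: np.ndarray
    n_frames_used: int


@dataclass(frozen=True)
class BinaryMask:
    values: np.ndarray
    frame_index: int


@dataclass(frozen=True)
class Detection:
    """One segmented candidate fish in one frame.

    ``centroid`` is the unweighted mean of the pixel (x, y) coordinates.
    """

    frame_index: int
    centroid: tuple[float, float]
    area: int
    pixels: frozenset[tuple[int, int]]
    label: int

    def __post_init__(self) -> None:
        if self.area != len(self.pixels) or self.area < 1:
            raise ValueError("area must equal |pixels| and be >= 1")


def median_projection(grays: list[GrayFrame]) -> BackgroundModel:
    """Per-pixel temporal median (lower-median convention for even counts)."""
    if not grays:
        raise ValueError("cannot build a background from zero frames")
    stack = np.stack([g.values for g in grays])
    n = stack.shape[0]
    kth = (n - 1) // 2
    med = np.partition(stack, kth, axis=0)[kth]
    return BackgroundModel(values=med, n_frames_used=n)


def subtract_background(frame: GrayFrame, bg: BackgroundModel) -> GrayFrame:
    """Absolute per-pixel difference |frame - background|."""
    if frame.shape != bg.values.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {bg.values.shape}"
        )
    return GrayFrame(values=np.abs(frame.values - bg.values))


def _local_maxima(hist: np.ndarray) -> np.ndarray:
    """Plateau-aware local maxima: a run of equal bins flanked by strictly
    smaller values (or the array boundary) is one maximum at its centre."""
    starts = [0]
    for i in range(1, len(hist)):
        if hist[i] != hist[starts[-1]]:
            starts.append(i)
    maxima = []
    for idx, s in enumerate(starts):
        e = starts[idx + 1] - 1 if idx + 1 < len(starts) else len(hist) - 1
        left_ok = idx == 0 or hist[starts[idx - 1]] < hist[s]
        right_ok = idx == len(starts) - 1 or hist[e + 1] < hist[s]
        if hist[s] > 0 and left_ok and right_ok:
            maxima.append((s + e) // 2)
    return np.array(maxima, dtype=int)


def intermodes_threshold(histogram: np.ndarray) -> int:
    """Intermodes threshold of a 256-bin intensity histogram.

    The histogram is repeatedly smoothed with a 3-bin moving mean until
    exactly two local maxima ``j < k`` remain; the threshold is
    ``(j + k) // 2``. Foreground is defined as strictly above the
    threshold.

    Raises
    ------
    NotBimodalError
        If the histogram never passes through a two-mode state (e.g.
        unimodal or degenerate input).
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size != 256:
        raise ValueError("expected a 256-bin histogram")
    if hist.sum() <= 0:
        raise ValueError("histogram has zero total count")
    kernel = np.full(3, 1.0 / 3.0)
    for _ in range(MAX_SMOOTHING_ITERATIONS):
        maxima = _local_maxima(hist)
        if len(maxima) == 2:
            j, k = maxima
            return int((j + k) // 2)
        if len(maxima) < 2:
            raise NotBimodalError(
                "histogram became unimodal before reaching two modes"
            )
        hist = np.convolve(hist, kernel, mode="same")
    raise NotBimodalError(
        f"histogram not bimodal after {MAX_SMOOTHING_ITERATIONS} smoothing "
        "iterations"
    )


def _disk_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= r**2


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def binarize_frame(diff: GrayFrame, frame_index: int = 0) -> tuple[BinaryMask, int]:
    """Intermodes-binarize one difference image; returns (mask, threshold)."""
    vals = np.clip(diff.values, 0.0, 255.0)
    hist = np.bincount(np.rint(vals).astype(np.int64).ravel(), minlength=256)
    t = intermodes_threshold(hist[:256])
    return BinaryMask(values=vals > t, frame_index=frame_index), t


def segment_frame(
    diff: GrayFrame,
    median_radius: int = 2,
    min_area: int = 100,
    max_area: int = 50_000,
    frame_index: int = 0,
) -> list[Detection]:
    """Extract size-gated candidate fish from one background-subtracted frame.

    Binarize with the intermodes threshold of the frame's own 256-bin
    histogram, median-filter the mask, label 8-connected components and
    keep those with ``min_area <= area <= max_area``.
    """
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    mask, _ = binarize_frame(diff, frame_index)
    filtered = mask.values
    if median_radius > 0:
        filtered = (
            ndimage.median_filter(
                filtered.astype(np.uint8), footprint=_disk_footprint(median_radius)
            )
            > 0
        )
    labels, n = ndimage.label(filtered, structure=_EIGHT_CONNECTED)
    detections: list[Detection] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        area = rows.size
        if not (min_area <= area <= max_area):
            continue
        pixels = frozenset(zip(cols.tolist(), rows.tolist()))
        detections.append(
            Detection(
                frame_index=frame_index,
                centroid=(float(cols.mean()), float(rows.mean())),
                area=int(area),
                pixels=pixels,
                label=lab,
            )
        )
    return detections
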