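"""Frame decoding and colour-deconvolution greyscale conversion.

Videos are decoded either from a standard container (AVI/MP4/MOV, via
imageio) or from a directory of lexicographically ordered still frames.
RGB frames are converted to a contrast-enhanced greyscale channel by
optical-density unmixing against a configurable stain matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "DEFAULT_FPS",
    "FrameSequence",
    "GrayFrame",
    "read_frames",
    "unmix_optical_density",
    "deconvolve_to_gray",
    "deconvolve_sequence",
]

#: Frame rate of the original overhead recordings.
DEFAULT_FPS = 24.96

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


@dataclass(frozen=True)
class FrameSequence:
    """An ordered stack of same-sized 8-bit RGB frames.

    Parameters
    ----------
    frames
        List of ``(H, W, 3)`` uint8 arrays, temporally ordered and
        0-indexed contiguously.
    fps
        Frames per second; must be positive.
    pixel_scale
        Optional mm-per-pixel calibration. When absent all downstream
        quantities stay in pixel units.
    """

    frames: list[np.ndarray]
    fps: float = DEFAULT_FPS
    pixel_scale: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("frame sequence is empty")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )
            if f.ndim != 3 or f.shape[2] != 3:
                raise ValueError("frames must be (H, W, 3) RGB arrays")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames[0].shape[:2]


@dataclass(frozen=True)
class GrayFrame:
    """A single greyscale frame of finite float intensities."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("GrayFrame expects a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GrayFrame contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _as_rgb(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    elif img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"cannot interpret image of shape {img.shape} as RGB")
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def read_frames(path: str | Path, fps_override: float | None = None) -> FrameSequence:
    """Decode a video container or a directory of frames.

    Directories are read in lexicographic filename order and require
    ``fps_override`` (still images carry no timing metadata).
    """
    path = Path(path)
    if path.is_dir():
        if fps_override is None:
            raise ValueError("fps_override is required for frame directories")
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not files:
            raise ValueError(f"no image frames found in {path}")
        frames = [_as_rgb(iio.imread(f)) for f in files]
        return FrameSequence(frames=frames, fps=float(fps_override))
    if not path.exists():
        raise FileNotFoundError(path)
    frames = [_as_rgb(f) for f in iio.imiter(path)]
    fps = fps_override
    if fps is None:
        meta = iio.immeta(path, exclude_applied=False)
        fps = meta.get("fps")
        if fps is None:
            raise ValueError(
                f"container {path} carries no fps metadata; pass fps_override"
            )
    return FrameSequence(frames=frames, fps=float(fps))


def _normalized_stain_matrix(stain_matrix: np.ndarray | None) -> np.ndarray:
    if stain_matrix is None:
        return np.eye(3)
    m = np.asarray(stain_matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("stain matrix must be 3x3")
    norms = np.linalg.norm(m, axis=1)
    if np.any(norms == 0):
        raise ValueError("stain matrix rows must be non-zero")
    m = m / norms[:, None]
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("stain matrix is singular")
    return m


def unmix_optical_density(
    frame: np.ndarray, stain_matrix: np.ndarray | None = None
) -> np.ndarray:
    """Convert an RGB frame to unmixed optical-density channels.

    Per pixel, ``OD_c = -log10(max(I_c, 1) / 255)`` for each of R, G, B;
    the OD vector is then unmixed by the inverse of the (row-normalized)
    stain matrix. Returns an ``(H, W, 3)`` float array.
    """
    m = _normalized_stain_matrix(stain_matrix)
    rgb = np.asarray(frame, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB frame")
    # clamp 0 -> 1 so OD stays finite
    od = -np.log10(np.clip(rgb, 1.0, 255.0) / 255.0)
    return od @ np.linalg.inv(m)


def _rescale(values: np.ndarray, value_range: tuple[float, float]) -> np.ndarray:
    lo, hi = value_range
    if hi <= lo:
        return np.zeros_like(values)
    return (values - lo) * (255.0 / (hi - lo))


def deconvolve_to_gray(
    frame: np.ndarray,
    stain_matrix: np.ndarray | None = None,
    channel: int = 0,
    value_range: tuple[float, float] | None = None,
) -> GrayFrame:
    """Unmix one stain channel and rescale it linearly to [0, 255].

    ``value_range`` fixes the (min, max) used for rescaling; supply the
    per-video global range for temporally comparable output (see
    :func:`deconvolve_sequence`). When absent the frame's own range is
    used.
    """
    if channel not in (0, 1, 2):
        raise ValueError("channel must be 0, 1 or 2")
    raw = unmix_optical_density(frame, stain_matrix)[:, :, channel]
    if value_range is None:
        value_range = (float(raw.min()), float(raw.max()))
    return GrayFrame(values=_rescale(raw, value_range))


def deconvolve_sequence(
    seq: FrameSequence,
    stain_matrix: np.ndarray | None = None,
    channel: int = 0,
) -> list[GrayFrame]:
    """Deconvolve every frame, rescaled against the per-video global range.

    A single (min, max) over the whole sequence keeps grey levels
    comparable across time, which the background model depends on.
    """
    raws = [
        unmix_optical_density(f, stain_matrix)[:, :, channel].astype(np.float32)
        for f in seq.frames
    ]
    lo = min(float(r.min()) for r in raws)
    hi = max(float(r.max()) for r in raws)
    return [GrayFrame(values=_rescale(r, (lo, hi))) for r in raws]
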