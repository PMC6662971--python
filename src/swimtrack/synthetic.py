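"""Synthetic overhead tank videos with exact per-frame ground truth.

Each fish is drawn as a dark capsule whose midline is a constant-
curvature arc; the arc's signed curvature oscillates sinusoidally over
time (tail beating) while the centroid translates at a programmed speed
and reflects off the tank walls. The renderer adds a fixed seeded
background texture and per-frame pixel noise. Ground truth (centroid,
heading, speed, curvature per fish per frame) is returned alongside the
video, so the whole tracking pipeline can be validated with no external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .video_io import DEFAULT_FPS, FrameSequence

__all__ = [
    "FishParams",
    "SwimConfig",
    "GroundTruth",
    "simulate_swim",
    "midline_points",
    "render_video",
    "write_frames",
]


@dataclass(frozen=True)
class FishParams:
    """Geometry and motion programme of one simulated fish."""

    body_length: float = 60.0
    body_width: float = 12.0
    speed: float = 4.0  # px/frame
    heading: float = 0.0  # radians, initial
    heading_sd: float = 0.0  # per-frame random-walk SD, radians
    curvature_amplitude: float = 0.008  # px^-1
    beat_hz: float = 1.0
    phase: float = 0.0
    start_xy: tuple[float, float] | None = None


@dataclass(frozen=True)
class SwimConfig:
    n_fish: int = 2
    frame_size: tuple[int, int] = (640, 360)  # (width, height)
    fps: float = DEFAULT_FPS
    n_frames: int = 500
    fish: tuple[FishParams, ...] | None = None
    background_level: float = 200.0
    texture_sd: float = 6.0
    contrast: float = 80.0  # fish darker than background by this many grey levels
    pixel_noise_sd: float = 2.0
    seed: int = 0

    def fish_params(self) -> tuple[FishParams, ...]:
        if self.fish is not None:
            if len(self.fish) != self.n_fish:
                raise ValueError("len(fish) must equal n_fish")
            return self.fish
        return tuple(
            FishParams(phase=2.0 * np.pi * i / max(self.n_fish, 1))
            for i in range(self.n_fish)
        )

    def __post_init__(self) -> None:
        if self.n_fish < 1 or self.n_frames < 1:
            raise ValueError("need at least one fish and one frame")
        w, h = self.frame_size
        if w < 1 or h < 1 or self.fps <= 0:
            raise ValueError("invalid frame size or fps")
        for fp in self.fish_params():
            if fp.body_length <= 0 or fp.body_width <= 0 or fp.speed < 0:
                raise ValueError("fish geometry/speed must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-fish, per-frame programmed state; arrays shaped (n_fish, n_frames)."""

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    speed: np.ndarray
    curvature: np.ndarray
    fps: float

    @property
    def n_fish(self) -> int:
        return self.x.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        n_fish, n_frames = self.x.shape
        return pd.DataFrame(
            {
                "fish_id": np.repeat(np.arange(n_fish), n_frames),
                "frame": np.tile(np.arange(n_frames), n_fish),
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "heading": self.heading.ravel(),
                "speed": self.speed.ravel(),
                "curvature": self.curvature.ravel(),
            }
        )


def _initial_positions(config: SwimConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = config.frame_size
    params = config.fish_params()
    margin = max(fp.body_length / 2 + fp.body_width for fp in params) + 2
    if 2 * margin >= w or 2 * margin >= h:
        raise ValueError(
            f"frame {w}x{h} too small for fish margin {margin:.0f}px; "
            "shrink body_length/body_width or enlarge the frame"
        )
    if any(fp.start_xy is not None for fp in params):
        if not all(fp.start_xy is not None for fp in params):
            raise ValueError("either all or no fish may fix start_xy")
        pos = np.array([fp.start_xy for fp in params], dtype=float)
    else:
        min_sep = 2 * max(fp.body_length for fp in params)
        for _ in range(1000):
            pos = np.column_stack(
                [
                    rng.uniform(margin, w - margin, config.n_fish),
                    rng.uniform(margin, h - margin, config.n_fish),
                ]
            )
            if config.n_fish == 1 or cdist(pos, pos)[
                np.triu_indices(config.n_fish, 1)
            ].min() >= min_sep:
                break
        else:
            raise ValueError(
                "could not place fish with the required pairwise separation"
            )
    if np.any(pos[:, 0] < margin) or np.any(pos[:, 0] > w - margin) or np.any(
        pos[:, 1] < margin
    ) or np.any(pos[:, 1] > h - margin):
        raise ValueError("fish start positions fall outside the tank margin")
    return pos


def simulate_swim(config: SwimConfig) -> GroundTruth:
    """Generate deterministic ground-truth trajectories for a config.

    Signed midline curvature follows kappa(t) = A sin(2 pi f t + phase);
    the centroid advances by ``speed`` along the heading each frame and
    reflects off the tank walls, so consecutive centroids are always
    exactly ``speed`` apart.
    """
    rng = np.random.default_rng(config.seed)
    params = config.fish_params()
    w, h = config.frame_size
    margin = max(fp.body_length / 2 + fp.body_width for fp in params) + 2
    pos = _initial_positions(config, rng)
    n, T = config.n_fish, config.n_frames
    x = np.empty((n, T))
    y = np.empty((n, T))
    heading = np.empty((n, T))
    speed = np.empty((n, T))
    curvature = np.empty((n, T))
    theta = np.array([fp.heading for fp in params], dtype=float)
    for t in range(T):
        for i, fp in enumerate(params):
            if t > 0:
                if fp.heading_sd > 0:
                    theta[i] += rng.normal(0.0, fp.heading_sd)
                dx = fp.speed * np.cos(theta[i])
                dy = fp.speed * np.sin(theta[i])
                if not margin <= pos[i, 0] + dx <= w - margin:
                    theta[i] = np.pi - theta[i]
                    dx = fp.speed * np.cos(theta[i])
                if not margin <= pos[i, 1] + dy <= h - margin:
                    theta[i] = -theta[i]
                    dy = fp.speed * np.sin(theta[i])
                pos[i, 0] = np.clip(pos[i, 0] + dx, margin, w - margin)
                pos[i, 1] = np.clip(pos[i, 1] + dy, margin, h - margin)
            x[i, t], y[i, t] = pos[i]
            heading[i, t] = theta[i]
            speed[i, t] = fp.speed
            curvature[i, t] = fp.curvature_amplitude * np.sin(
                2.0 * np.pi * fp.beat_hz * t / config.fps + fp.phase
            )
    return GroundTruth(
        x=x, y=y, heading=heading, speed=speed, curvature=curvature, fps=config.fps
    )


def midline_points(
    centroid: tuple[float, float],
    heading: float,
    curvature: float,
    body_length: float,
    spacing: float = 0.5,
) -> np.ndarray:
    """Dense points of a constant-curvature arc midline, recentred on centroid.

    The arc has the given signed curvature and arc length; it is shifted
    so its own point-mean sits exactly at ``centroid``, which keeps the
    rendered blob's centroid aligned with the programmed trajectory even
    while the body bends.
    """
    n = max(int(np.ceil(body_length / spacing)) + 1, 5)
    u = np.linspace(-body_length / 2, body_length / 2, n)
    if abs(curvature) < 1e-9:
        pts = np.column_stack([u * np.cos(heading), u * np.sin(heading)])
    else:
        k = curvature
        pts = np.column_stack(
            [
                (np.sin(heading + k * u) - np.sin(heading)) / k,
                -(np.cos(heading + k * u) - np.cos(heading)) / k,
            ]
        )
    pts -= pts.mean(axis=0)
    pts += np.asarray(centroid, dtype=float)
    return pts


def _render_frame(
    truth: GroundTruth,
    config: SwimConfig,
    t: int,
    texture: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    w, h = config.frame_size
    canvas = config.background_level + texture
    params = config.fish_params()
    for i, fp in enumerate(params):
        pts = midline_points(
            (truth.x[i, t], truth.y[i, t]),
            truth.heading[i, t],
            truth.curvature[i, t],
            fp.body_length,
        )
        half_w = fp.body_width / 2
        pad = half_w + 2
        c0 = max(int(np.floor(pts[:, 0].min() - pad)), 0)
        c1 = min(int(np.ceil(pts[:, 0].max() + pad)) + 1, w)
        r0 = max(int(np.floor(pts[:, 1].min() - pad)), 0)
        r1 = min(int(np.ceil(pts[:, 1].max() + pad)) + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        grid = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
        d = cdist(grid, pts).min(axis=1).reshape(rows.shape)
        coverage = np.clip(half_w + 0.5 - d, 0.0, 1.0)
        canvas[r0:r1, c0:c1] -= config.contrast * coverage
    if config.pixel_noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.pixel_noise_sd, canvas.shape)
    gray = np.clip(canvas, 0, 255).astype(np.uint8)
    return np.stack([gray] * 3, axis=-1)


def render_video(
    truth: GroundTruth, config: SwimConfig, out: str | Path | None = None
) -> FrameSequence:
    """Render a ground truth to RGB frames; optionally write them to disk.

    Writing produces lossless numbered PNGs (``frame_00000.png``, ...)
    plus ``ground_truth.csv`` in ``out``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    w, h = config.frame_size
    texture = (
        rng.normal(0.0, config.texture_sd, (h, w)) if config.texture_sd > 0 else np.zeros((h, w))
    )
    frames = [
        _render_frame(truth, config, t, texture, rng) for t in range(config.n_frames)
    ]
    seq = FrameSequence(frames=frames, fps=config.fps)
    if out is not None:
        write_frames(seq, truth, out)
    return seq


def write_frames(seq: FrameSequence, truth: GroundTruth | None, out: str | Path) -> Path:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(seq.frames):
        iio.imwrite(out / f"frame_{t:05d}.png", frame)
    if truth is not None:
        truth.to_dataframe().to_csv(out / "ground_truth.csv", index=False)
    return out
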