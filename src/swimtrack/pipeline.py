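"""End-to-end orchestration: frames -> detections -> tracks -> summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import backbone as bb
from . import behavior_stats as bs
from . import segmentation as seg
from . import tracking as tr
from . import video_io as vio

__all__ = ["PipelineConfig", "PipelineResult", "detect_frames", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    stain_matrix: np.ndarray | None = None
    channel: int = 0
    median_radius: int = 2
    min_area: int = 100
    max_area: int = 50_000
    max_link_distance: float = tr.DEFAULT_MAX_LINK_DISTANCE
    min_track_frames: int = tr.DEFAULT_MIN_TRACK_FRAMES
    n_active: int = bs.DEFAULT_N_ACTIVE
    spline_smoothing: float | None = None
    curvature_samples: int = bb.DEFAULT_CURVATURE_SAMPLES
    pixel_scale: float | None = None


@dataclass(frozen=True)
class PipelineResult:
    tracks: list[tr.Track]
    speeds: dict[int, tr.SpeedSeries]
    curvatures: dict[int, np.ndarray]  # one scalar per track frame (NaN = unmeasured)
    summaries: list[bs.FishSummary]

    def tracks_frame(self) -> pd.DataFrame:
        rows = [
            (t.track_id, d.frame_index, d.centroid[0], d.centroid[1], d.area)
            for t in self.tracks
            for d in t.detections
        ]
        return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "area"])

    def speeds_frame(self) -> pd.DataFrame:
        rows = [
            (tid, t.start_frame + 1 + i, float(v))
            for t in self.tracks
            for tid, ss in ((t.track_id, self.speeds[t.track_id]),)
            for i, v in enumerate(ss.speeds)
        ]
        return pd.DataFrame(rows, columns=["track_id", "frame", "speed_px_per_frame"])

    def summaries_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fish_id": s.fish_id,
                    "mean_velocity": s.mean_velocity,
                    "range_of_movement": s.range_of_movement,
                    "n_frames_used": s.n_frames_used,
                    "short_series": s.short_series,
                }
                for s in self.summaries
            ]
        )


def detect_frames(
    seq: vio.FrameSequence, config: PipelineConfig = PipelineConfig()
) -> list[list[seg.Detection]]:
    """Deconvolve, background-subtract and segment every frame."""
    grays = vio.deconvolve_sequence(seq, config.stain_matrix, config.channel)
    background = seg.median_projection(grays)
    detections_by_frame = []
    for idx, g in enumerate(grays):
        diff = seg.subtract_background(g, background)
        try:
            dets = seg.segment_frame(
                diff,
                median_radius=config.median_radius,
                min_area=config.min_area,
                max_area=config.max_area,
                frame_index=idx,
            )
        except seg.NotBimodalError:
            dets = []
        detections_by_frame.append(dets)
    return detections_by_frame


def _track_curvatures(track: tr.Track, config: PipelineConfig) -> np.ndarray:
    curv = np.full(len(track), np.nan)
    previous = None
    for i, det in enumerate(track.detections):
        try:
            spine = bb.extract_backbone(det.pixels)
            spline = bb.fit_spline(spine, smoothing=config.spline_smoothing)
            profile = bb.curvature_profile(
                spline, M=config.curvature_samples, previous=previous
            )
        except bb.BackboneError:
            continue
        previous = profile
        curv[i] = profile.frame_curvature
    return curv


def run_pipeline(
    seq: vio.FrameSequence, config: PipelineConfig = PipelineConfig()
) -> PipelineResult:
    """Run the full chain and summarize each surviving track as one fish."""
    detections_by_frame = detect_frames(seq, config)
    tracks = tr.build_tracks(detections_by_frame, config.max_link_distance)
    tracks = tr.filter_short_tracks(tracks, config.min_track_frames)
    speeds: dict[int, tr.SpeedSeries] = {}
    curvatures: dict[int, np.ndarray] = {}
    summaries: list[bs.FishSummary] = []
    for t in tracks:
        ss = tr.instantaneous_speeds(t, seq.fps, config.pixel_scale)
        curv = _track_curvatures(t, config)
        speeds[t.track_id] = ss
        curvatures[t.track_id] = curv
        summaries.append(bs.summarize_fish(t, ss, curv, n_active=config.n_active))
    return PipelineResult(
        tracks=tracks, speeds=speeds, curvatures=curvatures, summaries=summaries
    )
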