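"""Shared fixtures: the canonical synthetic end-to-end run.

The two-fish, 500-frame, 640x360 simulation is the workhorse for the
pipeline-level checks; it is computed once per session and shared.
Fish swim in separate horizontal lanes (no heading noise), so their
vertical separation stays at 180 px >= 2x the 80 px link gate for the
identity-preservation checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from swimtrack.pipeline import PipelineConfig, run_pipeline
from swimtrack.synthetic import FishParams, SwimConfig, render_video, simulate_swim

E2E_SPEED = 4.0
E2E_AMPLITUDE = 0.008
E2E_GATE = 80.0


def e2e_config(n_frames: int = 500, seed: int = 11) -> SwimConfig:
    return SwimConfig(
        n_fish=2,
        n_frames=n_frames,
        frame_size=(640, 360),
        seed=seed,
        fish=(
            FishParams(
                body_length=80.0,
                speed=E2E_SPEED,
                start_xy=(160.0, 90.0),
                heading=0.0,
                curvature_amplitude=E2E_AMPLITUDE,
                beat_hz=1.0,
            ),
            FishParams(
                body_length=80.0,
                speed=E2E_SPEED,
                start_xy=(480.0, 270.0),
                heading=np.pi,
                curvature_amplitude=E2E_AMPLITUDE,
                beat_hz=1.0,
                phase=1.0,
            ),
        ),
    )


@pytest.fixture(scope="session")
def e2e():
    """(config, truth, frames, pipeline result) of the canonical run."""
    config = e2e_config()
    truth = simulate_swim(config)
    seq = render_video(truth, config)
    result = run_pipeline(seq, PipelineConfig(max_link_distance=E2E_GATE))
    return config, truth, seq, result
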