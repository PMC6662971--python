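# swimtrack

Quantification of adult-fish swim behavior from overhead tank videos,
plus the organism-level statistics that go with a mutant-line study:

- **video_io** — decode videos / frame directories; colour-deconvolution
  (optical-density unmixing) greyscale conversion with per-video rescaling.
- **segmentation** — median time-projection background, absolute
  subtraction, intermodes histogram binarization, median filtering and
  size-gated 8-connected blob detection.
- **tracking** — Munkres (Hungarian) detection-to-track linking on
  centroid distances with gating, immediate termination on missed frames,
  the 50-frame false-track filter, and instantaneous (frame-to-frame)
  speeds.
- **backbone** — skeletonization, longest-geodesic midline ordering,
  cubic smoothing splines, signed local curvature, backbone length, and
  per-fish range of movement (max − min frame curvature).
- **behavior_stats** — most-active-frame selection, per-fish summaries,
  balanced two-way ANOVA with Sidak adjustment, BMI and Fulton's K, and
  Mendelian segregation chi-square tests.
- **synthetic** — a deterministic generator of overhead videos of dark,
  undulating, translating capsule-bodied fish with exact per-frame ground
  truth (centroid, speed, signed midline curvature), so the entire
  pipeline is testable offline.

## CLI

```sh
# write a synthetic video (numbered PNGs + ground_truth.csv)
swimtrack simulate --out video/ --seed 1 --n-fish 2 --n-frames 500

# detect + link fish -> track_id,frame,x,y,area CSV
swimtrack track video/ --fps 24.96 --out tracks.csv

# per-fish mean velocity and range of movement over the 100 most-active frames
swimtrack summarize video/ --fps 24.96 --out summaries.csv

# organism-level statistics
swimtrack stats chi2 --observed 7,131 --ratio 1,15
swimtrack stats morpho fish.csv --out fish_with_indices.csv
swimtrack stats anova tidy.csv --factor-a genotype --factor-b sex --value value
```

`track`/`summarize` accept a video container (if an imageio decoder
plugin is available) or a directory of lexicographically ordered frames
(`--fps` required). Key knobs: `--stain-matrix` (9 row-major numbers),
`--channel`, `--median-radius`, `--min-area`/`--max-area`,
`--max-link-distance`, `--min-track-frames`.

## Library use

```python
from swimtrack import SwimConfig, simulate_swim, render_video
from swimtrack.pipeline import PipelineConfig, run_pipeline

config = SwimConfig(n_fish=2, n_frames=500, frame_size=(640, 360), seed=11)
truth = simulate_swim(config)
frames = render_video(truth, config)
result = run_pipeline(frames, PipelineConfig(max_link_distance=80))
print(result.summaries_frame())
```

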