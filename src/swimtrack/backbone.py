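"""Midline extraction, spline fitting and curvature measurement.

Each detection mask is thinned to a 1-px skeleton; the midline is the
longest endpoint-to-endpoint geodesic through the skeleton graph. Cubic
smoothing splines in x and y against normalized chord length give a
twice-differentiable backbone from which signed local curvature and arc
length are measured. The per-frame curvature scalar is the mean signed
curvature over the interior of the spline, with head/tail orientation
carried across frames for sign stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.interpolate import UnivariateSpline
from skimage.morphology import skeletonize

__all__ = [
    "Backbone",
    "SplineModel",
    "CurvatureProfile",
    "BackboneError",
    "extract_backbone",
    "fit_spline",
    "curvature_profile",
    "range_of_movement",
]

#: Fraction of normalized arc length trimmed from each end before
#: sampling curvature; spline end effects dominate outside it.
END_TRIM = 0.05
DEFAULT_CURVATURE_SAMPLES = 100


class BackboneError(ValueError):
    """Raised when a mask is too small or round to yield a usable midline."""


@dataclass(frozen=True)
class Backbone:
    """Ordered midline pixels from one end of the body to the other."""

    points: np.ndarray  # (N, 2) of (x, y)
    n_endpoints_found: int

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SplineModel:
    """Smoothed parametric midline x(s), y(s), s in [0, 1]."""

    x: UnivariateSpline
    y: UnivariateSpline
    smoothing: float
    backbone_length: float

    def point(self, s: float) -> tuple[float, float]:
        return float(self.x(s)), float(self.y(s))


@dataclass(frozen=True)
class CurvatureProfile:
    """Signed curvature samples and the per-frame curvature scalar.

    ``head_point`` is the fitted-curve end currently treated as the
    head; passing the profile as ``previous`` to the next frame keeps
    the curvature sign consistent while the fish turns.
    """

    samples: np.ndarray
    frame_curvature: float
    orientation_sign: int
    head_point: tuple[float, float]


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    nodes = set(zip(rows.tolist(), cols.tolist()))
    for r, c in nodes:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in nodes:
                    g.add_edge((r, c), nb, weight=np.hypot(dr, dc))
    return g


def extract_backbone(mask_pixels: Iterable[tuple[int, int]]) -> Backbone:
    """Thin a pixel set to its longest endpoint-to-endpoint skeleton path.

    ``mask_pixels`` are (x, y) integer coordinates. Branched skeletons
    are resolved by taking the maximum-length geodesic between skeleton
    endpoints (degree-1 nodes), which drops side branches.
    """
    pts = np.array(sorted(mask_pixels), dtype=int)
    if len(pts) < 20:
        raise BackboneError(f"mask has only {len(pts)} pixels (< 20)")
    x0, y0 = pts[:, 0].min() - 1, pts[:, 1].min() - 1
    w = pts[:, 0].max() - x0 + 2
    h = pts[:, 1].max() - y0 + 2
    img = np.zeros((h, w), dtype=bool)
    img[pts[:, 1] - y0, pts[:, 0] - x0] = True
    skel = skeletonize(img)
    g = _skeleton_graph(skel)
    if g.number_of_nodes() < 5:
        raise BackboneError("skeleton has fewer than 5 points")
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if len(endpoints) < 2:
        raise BackboneError(
            f"skeleton has {len(endpoints)} endpoints; need at least 2"
        )
    best: tuple[float, tuple, tuple] | None = None
    for i, src in enumerate(endpoints):
        lengths = nx.single_source_dijkstra_path_length(g, src, weight="weight")
        for dst in endpoints[i + 1 :]:
            if dst in lengths and (best is None or lengths[dst] > best[0]):
                best = (lengths[dst], src, dst)
    if best is None:
        raise BackboneError("no path joins any pair of skeleton endpoints")
    path = nx.dijkstra_path(g, best[1], best[2], weight="weight")
    if len(path) < 5:
        raise BackboneError("longest skeleton path has fewer than 5 points")
    xy = np.array([(c + x0, r + y0) for r, c in path], dtype=float)
    return Backbone(points=xy, n_endpoints_found=len(endpoints))


def fit_spline(backbone: Backbone, smoothing: float | None = None) -> SplineModel:
    """Fit cubic smoothing splines x(s), y(s) against normalized chord length.

    ``smoothing`` is the residual-sum bound of the smoothing spline;
    defaults to ``0.5 * N`` for N backbone points. Arc length is
    integrated numerically on a dense grid.
    """
    pts = np.asarray(backbone.points, dtype=float)
    if len(pts) < 5:
        raise BackboneError("need at least 5 points to fit a spline")
    steps = np.hypot(*np.diff(pts, axis=0).T)
    total = steps.sum()
    if total == 0:
        raise BackboneError("degenerate backbone: all points identical")
    s = np.concatenate(([0.0], np.cumsum(steps))) / total
    s, keep = np.unique(s, return_index=True)
    pts = pts[keep]
    if len(pts) < 5:
        raise BackboneError("fewer than 5 distinct backbone points")
    if smoothing is None:
        smoothing = 0.5 * len(pts)
    spl_x = UnivariateSpline(s, pts[:, 0], k=3, s=smoothing)
    spl_y = UnivariateSpline(s, pts[:, 1], k=3, s=smoothing)
    grid = np.linspace(0.0, 1.0, 513)
    length = float(
        np.trapezoid(np.hypot(spl_x.derivative()(grid), spl_y.derivative()(grid)), grid)
    )
    if not np.isfinite(length) or length <= 0:
        raise BackboneError("non-positive fitted backbone length")
    return SplineModel(x=spl_x, y=spl_y, smoothing=float(smoothing), backbone_length=length)


def curvature_profile(
    spline: SplineModel,
    M: int = DEFAULT_CURVATURE_SAMPLES,
    previous: CurvatureProfile | None = None,
) -> CurvatureProfile:
    """Sample signed curvature along the spline interior.

    kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2) at ``M`` evenly spaced
    s in [END_TRIM, 1 - END_TRIM]. The head end is chosen as the spline
    end nearer the previous frame's head; a tail-end head flips the sign
    of every sample (equivalent to reversing the parameterization). The
    per-frame scalar is the arithmetic mean of the samples.
    """
    ss = np.linspace(END_TRIM, 1.0 - END_TRIM, M)
    x1 = spline.x.derivative(1)(ss)
    y1 = spline.y.derivative(1)(ss)
    x2 = spline.x.derivative(2)(ss)
    y2 = spline.y.derivative(2)(ss)
    denom = (x1**2 + y1**2) ** 1.5
    if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
        raise BackboneError("degenerate spline: vanishing first derivative")
    kappa = (x1 * y2 - y1 * x2) / denom
    if not np.all(np.isfinite(kappa)):
        raise BackboneError("non-finite curvature")
    head, tail = spline.point(0.0), spline.point(1.0)
    sign = 1
    if previous is not None:
        ph = np.asarray(previous.head_point)
        if np.linalg.norm(np.asarray(tail) - ph) < np.linalg.norm(
            np.asarray(head) - ph
        ):
            sign = -1
            head = tail
            kappa = -kappa[::-1]
    return CurvatureProfile(
        samples=kappa,
        frame_curvature=float(kappa.mean()),
        orientation_sign=sign,
        head_point=head,
    )


def range_of_movement(frame_curvatures: Iterable[float]) -> float:
    """Max minus min of a per-frame curvature series (>= 0)."""
    vals = np.asarray(list(frame_curvatures), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one frame curvature")
    if not np.all(np.isfinite(vals)):
        raise ValueError("frame curvatures must be finite")
    return float(vals.max() - vals.min())
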