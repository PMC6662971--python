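"""Per-fish kinematic summaries and organism-level statistics.

Covers: selection of the most-active frames, per-fish mean velocity and
range of movement, balanced two-way ANOVA with Sidak adjustment,
morphometric indices (BMI, Fulton's K), and Mendelian segregation
chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .backbone import range_of_movement
from .tracking import SpeedSeries, Track

__all__ = [
    "FishSummary",
    "AnovaTable",
    "GenotypeCounts",
    "Morphometrics",
    "Chi2Result",
    "ActiveFrames",
    "select_active_frames",
    "summarize_fish",
    "two_way_anova",
    "sidak_adjust",
    "bmi",
    "fulton_k",
    "mendelian_chi2",
    "genotype_percent",
]

DEFAULT_N_ACTIVE = 100


class ActiveFrames(NamedTuple):
    indices: np.ndarray
    short_series: bool


@dataclass(frozen=True)
class FishSummary:
    """Mean velocity and range of movement of one fish over its most-active frames."""

    fish_id: int
    mean_velocity: float
    range_of_movement: float
    n_frames_used: int
    genotype_label: str | None = None
    short_series: bool = False

    def __post_init__(self) -> None:
        if self.mean_velocity < 0 or self.range_of_movement < 0:
            raise ValueError("summary metrics must be non-negative")


@dataclass(frozen=True)
class AnovaTable:
    """Fixed-effects two-way ANOVA decomposition.

    ``table`` rows: factor_a, factor_b, interaction (when estimable) and
    residual, with columns sum_sq, df, mean_sq, F, p.
    """

    table: pd.DataFrame
    note: str | None = None


@dataclass(frozen=True)
class GenotypeCounts:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.expected_ratio) or len(self.observed) < 2:
            raise ValueError("observed and ratio must have equal length >= 2")
        if any(o < 0 for o in self.observed) or sum(self.observed) <= 0:
            raise ValueError("observed counts must be non-negative with positive total")
        if any(r <= 0 for r in self.expected_ratio):
            raise ValueError("expected ratio weights must be positive")


class Chi2Result(NamedTuple):
    statistic: float
    p_value: float
    df: int
    expected: np.ndarray


@dataclass(frozen=True)
class Morphometrics:
    """One fish's weight/length record with derived condition indices."""

    fish_id: str
    sex: str
    genotype_label: str
    weight: float
    length: float
    bmi: float = field(init=False)
    fulton_k: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bmi", bmi(self.weight, self.length))
        object.__setattr__(self, "fulton_k", fulton_k(self.weight, self.length))


def select_active_frames(
    speed_by_frame: Sequence[float], n: int = DEFAULT_N_ACTIVE
) -> ActiveFrames:
    """Indices of the ``n`` highest-activity frames, ties to earlier frames.

    If fewer than ``n`` frames are available, all are returned and the
    short-series flag is set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    vals = np.asarray(speed_by_frame, dtype=float)
    if vals.size == 0:
        raise ValueError("empty activity series")
    order = np.argsort(-vals, kind="stable")  # stable: ties -> earlier frame
    chosen = np.sort(order[:n])
    return ActiveFrames(indices=chosen, short_series=vals.size < n)


def summarize_fish(
    track: Track,
    speeds: SpeedSeries,
    curvatures: Sequence[float],
    n_active: int = DEFAULT_N_ACTIVE,
    genotype_label: str | None = None,
) -> FishSummary:
    """Per-fish mean velocity and range of movement over the most-active frames.

    ``curvatures`` holds one per-frame curvature scalar per track frame
    (NaN where the backbone could not be measured). Each instantaneous
    speed is attributed to the later frame of its step; activity
    selection, the velocity mean and the curvature range are all
    restricted to the selected frames.
    """
    L = len(track)
    curv = np.asarray(curvatures, dtype=float)
    if curv.shape != (L,):
        raise ValueError("need one curvature scalar per track frame")
    if speeds.speeds.shape != (L - 1,):
        raise ValueError("speed series length must be track length - 1")
    active = select_active_frames(speeds.speeds, n=n_active)
    steps = active.indices  # step i <-> frame offset i + 1
    mean_velocity = float(speeds.speeds[steps].mean())
    curv_sel = curv[steps + 1]
    curv_sel = curv_sel[np.isfinite(curv_sel)]
    if curv_sel.size == 0:
        raise ValueError("no curvature measurements overlap the active frames")
    return FishSummary(
        fish_id=track.track_id,
        mean_velocity=mean_velocity,
        range_of_movement=range_of_movement(curv_sel),
        n_frames_used=int(steps.size),
        genotype_label=genotype_label,
        short_series=active.short_series,
    )


def two_way_anova(
    values: Iterable[tuple[str, str, float]],
) -> AnovaTable:
    """Balanced fixed-effects two-way ANOVA with interaction.

    ``values`` are (factor A level, factor B level, response) triples.
    The design must be balanced (full A x B grid, equal cell counts).
    With one observation per cell the interaction is not estimable and
    is dropped, noted in ``note``.
    """
    df = pd.DataFrame(values, columns=["a", "b", "value"])
    if df.empty:
        raise ValueError("no observations")
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = df.groupby(["a", "b"], sort=True).size()
    full_grid = df["a"].nunique() * df["b"].nunique()
    if len(counts) != full_grid or counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: every factor-level combination must appear "
            "with the same number of observations"
        )
    per_cell = int(counts.iloc[0])
    note = None
    if per_cell == 1:
        formula = "value ~ C(a) + C(b)"
        note = (
            "one observation per cell: interaction not estimable, "
            "additive model fitted"
        )
    else:
        formula = "value ~ C(a) * C(b)"
    fit = ols(formula, data=df).fit()
    raw = sm.stats.anova_lm(fit, typ=2)
    rename = {
        "C(a)": "factor_a",
        "C(b)": "factor_b",
        "C(a):C(b)": "interaction",
        "Residual": "residual",
    }
    out = raw.rename(index=rename)
    out = out.rename(columns={"PR(>F)": "p"})
    out["mean_sq"] = out["sum_sq"] / out["df"]
    out = out[["sum_sq", "df", "mean_sq", "F", "p"]]
    return AnovaTable(table=out, note=note)


def sidak_adjust(p_values: Sequence[float], m: int) -> np.ndarray:
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


def bmi(weight: float, length: float) -> float:
    """Body mass index: weight (g) / length (cm) squared."""
    if weight <= 0 or length <= 0:
        raise ValueError("weight and length must be positive")
    return weight / length**2


def fulton_k(weight: float, length: float) -> float:
    """Fulton's condition factor: 100 * weight (g) / length (cm) cubed."""
    if weight <= 0 or length <= 0:
        raise ValueError("weight and length must be positive")
    return 100.0 * weight / length**3


def mendelian_chi2(counts: GenotypeCounts) -> Chi2Result:
    """Chi-square goodness of fit of observed genotype counts to a Mendelian ratio.

    Expected counts are the total apportioned by ``expected_ratio``; the
    statistic uses no continuity correction; df = classes - 1; the
    p-value is the upper tail of the chi-square distribution.
    """
    obs = np.asarray(counts.observed, dtype=float)
    ratio = np.asarray(counts.expected_ratio, dtype=float)
    expected = obs.sum() * ratio / ratio.sum()
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    stat, p = stats.chisquare(obs, f_exp=expected)
    return Chi2Result(
        statistic=float(stat), p_value=float(p), df=len(obs) - 1, expected=expected
    )


def genotype_percent(k: int, n: int, decimals: int = 0) -> float:
    """Percentage 100*k/n rounded to the printed precision."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return float(np.round(100.0 * k / n, decimals))
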