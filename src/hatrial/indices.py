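"""Linear indicator scoring and the radar-chart-area quality indices.

The soil quality index (SQI) and plant growth index (PGI) summarize a set
of n indicators per group as the area of a radar polygon whose vertices are
linear scores SL_i in [0, 1] placed at angles 2*pi*i/n.

Two area variants are provided:

``squared_term``
    area = 0.5 * sum_i SL_i^2 * sin(2*pi/n) — the index formula exactly as
    published. Each term is the area of an isoceles triangle of two equal
    sides SL_i, so the result is permutation-invariant.

``adjacent_product``
    area = 0.5 * sum_i SL_i * SL_{i+1 mod n} * sin(2*pi/n) — the true
    geometric area of the radar polygon (the published squared form may be
    a typesetting of this). Depends on indicator order.

Both attain their maximum 0.5 * n * sin(2*pi/n) when every score is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import LESS_IS_BETTER, MORE_IS_BETTER, IndicatorSpec
from .errors import CoverageError, DegenerateInputError, DomainError, ValidationError

VARIANTS = ("squared_term", "adjacent_product")


@dataclass(frozen=True)
class ScoreTable:
    """Ordered vector of linear scores for one group."""

    group: str
    indicator_order: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.indicator_order) != len(self.scores):
            raise ValidationError("indicator_order and scores must align")
        if len(self.scores) < 3:
            raise DomainError("need at least 3 indicators for a radar polygon")
        arr = np.asarray(self.scores, dtype=float)
        if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
            raise ValidationError("scores must lie in [0, 1]")


@dataclass(frozen=True)
class IndexResult:
    """Radar-polygon area index for one group."""

    group: str
    area: float
    variant: str
    n: int

    @property
    def max_area(self) -> float:
        """Area of the full polygon (all scores 1): 0.5 * n * sin(2*pi/n)."""
        return 0.5 * self.n * np.sin(2 * np.pi / self.n)


def linear_score(values, direction: str) -> np.ndarray:
    """Linear scores in [0, 1] for one indicator across groups.

    more_is_better: SL = x / max(x); less_is_better: SL = min(x) / x.
    The best group scores exactly 1 under either direction.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DomainError("values must be finite")
    if direction == MORE_IS_BETTER:
        top = x.max()
        if top == 0:
            raise DegenerateInputError("all values are zero; scores undefined")
        if top < 0:
            raise DomainError("more_is_better scoring requires a positive maximum")
        return x / top
    if direction == LESS_IS_BETTER:
        if (x <= 0).any():
            raise DomainError("less_is_better scoring requires strictly positive values")
        return x.min() / x
    raise DomainError(f"unknown direction {direction!r}")


def relative_response(group_means: pd.Series, control: str) -> pd.Series:
    """Response ratios to the control, rescaled so the maximum is exactly 1.

    This is the 0-1 normalization radar charts display: r_t = mean_t /
    mean_control, then divided by max_t(r_t).
    """
    if control not in group_means.index:
        raise DomainError(f"control group {control!r} not among group means")
    c = group_means[control]
    if c == 0:
        raise DomainError("control mean is zero; relative response undefined")
    ratios = group_means / c
    return ratios / ratios.max()


def radar_area(scores: ScoreTable, variant: str = "squared_term") -> IndexResult:
    """Area of the radar polygon for one group's score vector."""
    if variant not in VARIANTS:
        raise DomainError(f"variant must be one of {VARIANTS}")
    sl = np.asarray(scores.scores, dtype=float)
    n = len(sl)
    wedge = np.sin(2 * np.pi / n)
    if variant == "squared_term":
        area = 0.5 * float(np.sum(sl**2)) * wedge
    else:
        area = 0.5 * float(np.sum(sl * np.roll(sl, -1))) * wedge
    return IndexResult(group=scores.group, area=area, variant=variant, n=n)


def score_indicators(
    obs: pd.DataFrame,
    indicators: list[IndicatorSpec],
    layer: str,
    level: str = "treatment_mean",
) -> list[ScoreTable]:
    """Assemble per-group score vectors for a layer's indicator set.

    At ``level="treatment_mean"`` the comparison set is the treatment means
    within the layer (one polygon per treatment); at ``level="plot"`` it is
    all plots within the layer (one polygon per plot, enabling ANOVA on the
    resulting indices). Scores for each indicator are computed across the
    whole comparison set, so they are comparable exactly within it.
    """
    if level not in ("treatment_mean", "plot"):
        raise DomainError("level must be 'treatment_mean' or 'plot'")
    sub = obs[obs["layer"] == layer]
    order = tuple(spec.name for spec in indicators)
    key = "treatment" if level == "treatment_mean" else "plot_id"

    wide = sub.pivot_table(
        index=key, columns="indicator", values="value", aggfunc="mean"
    )
    missing: list[str] = []
    for spec in indicators:
        if spec.name not in wide.columns or wide[spec.name].isna().any():
            missing.append(spec.name)
    if missing:
        raise CoverageError(
            f"layer {layer!r}: indicator(s) {missing} not observed for every group"
        )

    score_matrix = {
        spec.name: linear_score(wide[spec.name].to_numpy(), spec.direction)
        for spec in indicators
    }
    return [
        ScoreTable(
            group=str(g),
            indicator_order=order,
            scores=tuple(float(score_matrix[name][i]) for name in order),
        )
        for i, g in enumerate(wide.index)
    ]


def compute_index(
    obs: pd.DataFrame,
    indicators: list[IndicatorSpec],
    layer: str,
    level: str = "treatment_mean",
    variant: str = "squared_term",
) -> list[IndexResult]:
    """Radar-area index per group for one layer.

    Convenience composition of :func:`score_indicators` and
    :func:`radar_area`; see those for the contract.
    """
    tables = score_indicators(obs, indicators, layer, level)
    return [radar_area(t, variant) for t in tables]


def index_frame(results: list[IndexResult]) -> pd.DataFrame:
    """Tabulate index results (group, area, normalized area, variant, n)."""
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "area": [r.area for r in results],
            "area_normalized": [r.area / r.max_area for r in results],
            "variant": [r.variant for r in results],
            "n": [r.n for r in results],
        }
    )
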