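"""Multi-objective ranking and the two-category final challenge score.

Each method receives a rank per metric (1 = best, ties averaged —
fractional ranking).  Metrics belong to one of two categories, image
quality or network complexity; ranks are averaged within each category
and the final score is the sum of the two category means, so lower is
better.  A metric's direction is ``higher_better``, ``lower_better``, or
``closest_to_reference`` (rank by absolute deviation from a supplied
reference value, used e.g. for speckle-SNR preservation against the
fully compounded image).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ValidationError

__all__ = [
    "MetricTable",
    "FinalScore",
    "rank_metric",
    "rank_table",
    "final_score",
    "combine_category_ranks",
]

DIRECTIONS = ("higher_better", "lower_better", "closest_to_reference")
CATEGORIES = ("image_quality", "network_complexity")


@dataclass
class MetricTable:
    """Per-method metric values plus per-metric direction and category.

    ``values`` is a DataFrame with methods as rows and metrics as columns;
    ``directions`` and ``categories`` map each metric name to its
    direction and category; ``references`` supplies the target value for
    every ``closest_to_reference`` metric.
    """

    values: pd.DataFrame
    directions: dict[str, str]
    categories: dict[str, str]
    references: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for metric in self.values.columns:
            d = self.directions.get(metric)
            if d not in DIRECTIONS:
                raise ValidationError(
                    f"metric {metric!r} needs a direction in {DIRECTIONS}, got {d!r}"
                )
            c = self.categories.get(metric)
            if c not in CATEGORIES:
                raise ValidationError(
                    f"metric {metric!r} needs a category in {CATEGORIES}, got {c!r}"
                )
            if d == "closest_to_reference" and metric not in self.references:
                raise ValidationError(
                    f"metric {metric!r} ranks by closeness but has no reference value"
                )


@dataclass
class FinalScore:
    """Per-method ranks, category mean ranks, and the additive total."""

    ranks: pd.DataFrame
    category_means: pd.DataFrame
    final: pd.Series  # lower is better


def rank_metric(
    values: np.ndarray | pd.Series,
    direction: str,
    reference: float | None = None,
) -> np.ndarray:
    """Fractional ranks (1 = best) of one metric across methods."""
    vals = np.asarray(values, dtype=float)
    if direction not in DIRECTIONS:
        raise ValidationError(f"unknown direction {direction!r}")
    if direction == "closest_to_reference":
        if reference is None:
            raise ValidationError(
                "closest_to_reference ranking requires a reference value"
            )
        key = np.abs(vals - reference)
    elif direction == "higher_better":
        key = -vals
    else:
        key = vals
    if np.any(~np.isfinite(key)):
        raise ValidationError("metric values must be finite to rank")
    return rankdata(key, method="average")


def rank_table(table: MetricTable) -> pd.DataFrame:
    """Per-method per-metric fractional ranks for a whole table."""
    ranks = {}
    for metric in table.values.columns:
        ranks[metric] = rank_metric(
            table.values[metric],
            table.directions[metric],
            table.references.get(metric),
        )
    return pd.DataFrame(ranks, index=table.values.index)


def final_score(table: MetricTable) -> FinalScore:
    """Rank every metric, average within categories, sum the two means.

    Both categories must be represented; with a single method every rank
    is 1 and the final score is 2.
    """
    ranks = rank_table(table)
    for cat in CATEGORIES:
        if not any(table.categories[m] == cat for m in ranks.columns):
            raise ValidationError(f"empty category: {cat}")
    cat_of = pd.Series({m: table.categories[m] for m in ranks.columns})
    means = ranks.T.groupby(cat_of).mean().T
    return FinalScore(
        ranks=ranks,
        category_means=means,
        final=means.sum(axis=1).rename("final_score"),
    )


def combine_category_ranks(
    image_quality_ranks: list[float], network_complexity_ranks: list[float]
) -> float:
    """Final score from already-determined per-category ranks.

    The additive scoring rule: mean image-quality rank plus mean
    network-complexity rank.  Useful when the per-category ranks (or
    their means) are given directly rather than recomputed from a metric
    table.
    """
    if not image_quality_ranks or not network_complexity_ranks:
        raise ValidationError("both categories must be non-empty")
    return float(
        np.mean(image_quality_ranks) + np.mean(network_complexity_ranks)
    )
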