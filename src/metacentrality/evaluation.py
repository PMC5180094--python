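"""Recognition-rate evaluation of predictor rankings against ground truth.

The recognition rate at fraction f compares only the top f share of the two
rankings: with k = ceil(f*n), it is |I_f intersect S_f| / |I_f| where I_f
is the simulated ground truth's top-k and S_f a predictor's top-k. Since
both sets have size k the rate is symmetric in its arguments. Rates are
reported over a grid of f values together with per-predictor summary
statistics (mean, std, min, quartiles, max) for judging a predictor
across ranking depths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .ranking import Ranking

__all__ = [
    "DEFAULT_F_GRID",
    "EvaluationConfig",
    "RecognitionResult",
    "recognition_rate",
    "evaluate",
]

DEFAULT_F_GRID = (0.05, 0.10, 0.15, 0.20, 0.25, 0.50)


@dataclass(frozen=True)
class EvaluationConfig:
    f_values: tuple[float, ...] = DEFAULT_F_GRID

    def __post_init__(self) -> None:
        if not self.f_values:
            raise ValueError("f_values must be nonempty")
        for f in self.f_values:
            if not 0 < f <= 1:
                raise ValueError(f"f={f} outside (0, 1]")


@dataclass(frozen=True)
class RecognitionResult:
    """Per-(predictor, f) rates plus per-predictor summaries.

    ``rates`` is a DataFrame indexed by predictor with one column per f;
    ``summary`` carries mean/std/min/quartiles/max over the f grid;
    ``uplift_pct`` is the percentage rise of the requested aggregated
    predictor's mean over the best remaining predictor's mean (NaN when not
    applicable).
    """

    rates: pd.DataFrame
    summary: pd.DataFrame
    uplift_pct: float = float("nan")
    uplift_against: str = ""


def recognition_rate(truth: Ranking, predictor: Ranking, f: float) -> float:
    """Share of the ground-truth top-f set recovered by the predictor."""
    if truth.nodes != predictor.nodes:
        raise ValueError("truth and predictor must rank the same node set")
    if not 0 < f <= 1:
        raise ValueError(f"f={f} outside (0, 1]")
    n = len(truth)
    k = math.ceil(f * n)
    top_truth = set(truth.top(k))
    top_pred = set(predictor.top(k))
    return len(top_truth & top_pred) / k


def evaluate(
    truth: Ranking,
    predictors: Mapping[str, Ranking],
    config: EvaluationConfig | None = None,
    aggregated: str | Sequence[str] = ("A1",),
) -> RecognitionResult:
    """Rate table and summaries for every named predictor.

    If a predictor named in *aggregated* is present, its mean rate is
    compared with the best mean among the remaining (single-measure)
    predictors and the percentage rise is reported.
    """
    config = config or EvaluationConfig()
    if not predictors:
        raise ValueError("need at least one predictor")
    agg_names = (aggregated,) if isinstance(aggregated, str) else tuple(aggregated)
    rows = {
        name: [recognition_rate(truth, r, f) for f in config.f_values]
        for name, r in predictors.items()
    }
    rates = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"f={f:g}" for f in config.f_values]
    )
    summary = pd.DataFrame(
        {
            "mean": rates.mean(axis=1),
            "std": rates.std(axis=1, ddof=0),
            "min": rates.min(axis=1),
            "q25": rates.quantile(0.25, axis=1),
            "median": rates.quantile(0.50, axis=1),
            "q75": rates.quantile(0.75, axis=1),
            "max": rates.max(axis=1),
        }
    )
    uplift = float("nan")
    against = ""
    present = [a for a in agg_names if a in rows]
    singles = summary.drop(index=present)
    if present and not singles.empty:
        best_single = singles["mean"].idxmax()
        base = summary.loc[best_single, "mean"]
        headline = summary.loc[present[0], "mean"]
        if base > 0:
            uplift = 100.0 * (headline - base) / base
            against = str(best_single)
    return RecognitionResult(
        rates=rates, summary=summary, uplift_pct=uplift, uplift_against=against
    )
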