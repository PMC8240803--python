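"""Future-signal statistics: degree of diffusion, growth rate, average DF.

The degree of diffusion (DoD) of keyword i in period j is its normalized
document frequency with a linear time discount that favours recent periods:

    DoD_ij = (DF_ij / NN_j) * (1 - tw * (n - j)),    j = 1..n

where NN_j is the total number of documents in period j, n the number of
periods, and tw a time weight (0.05 by convention in text-mining-based
weak-signal studies). The average DoD growth rate (mean period-over-period
relative change) and the average DF are the two coordinates of the keyword
issue map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tagging import KeywordPeriodMatrix
from .utils import round_half_up_int

#: Conventional time weight in the weak-signal literature.
DEFAULT_TW = 0.05


class ComputationError(ValueError):
    """A signal statistic cannot be computed on the given inputs."""


@dataclass(frozen=True)
class TimeWeightConfig:
    """Dimensionless time weight tw; requires tw*(n-1) < 1 so every period
    weight stays positive."""

    tw: float = DEFAULT_TW

    def validate_for(self, n: int) -> None:
        if self.tw * (n - 1) >= 1:
            raise ComputationError(
                f"time weight tw={self.tw} gives a non-positive weight for the "
                f"earliest of {n} periods (need tw*(n-1) < 1)")

    def weights(self, n: int) -> np.ndarray:
        self.validate_for(n)
        j = np.arange(1, n + 1)
        return 1.0 - self.tw * (n - j)


def degree_of_diffusion(matrix: KeywordPeriodMatrix,
                        cfg: TimeWeightConfig = TimeWeightConfig()) -> np.ndarray:
    """DoD_ij for every keyword and period, shape (K, n)."""
    zero_periods = np.flatnonzero(matrix.nn == 0)
    if zero_periods.size:
        label = matrix.period_labels[int(zero_periods[0])]
        raise ComputationError(f"period {label!r} has NN_j = 0; DoD is undefined there")
    weights = cfg.weights(matrix.n)
    return (matrix.df / matrix.nn[None, :]) * weights[None, :]


def average_growth(dod_series: Sequence[float]) -> float:
    """Mean period-over-period relative change of one DoD series.

    Pairs whose predecessor is zero are skipped (a relative change from
    nothing is undefined); if every pair is skipped the growth is reported
    as 0.0 with a warning.
    """
    series = np.asarray(dod_series, dtype=float)
    if series.size < 2:
        raise ComputationError("average growth needs at least 2 periods")
    prev, curr = series[:-1], series[1:]
    usable = prev > 0
    if not usable.any():
        warnings.warn("all growth pairs have a zero predecessor; reporting 0.0",
                      stacklevel=2)
        return 0.0
    return float(np.mean((curr[usable] - prev[usable]) / prev[usable]))


def average_df(df_series: Sequence[float]) -> int:
    """Arithmetic mean DF, rounded half-up to an integer for reporting."""
    series = np.asarray(df_series, dtype=float)
    if series.size == 0:
        raise ComputationError("average DF needs at least 1 period")
    return round_half_up_int(float(series.mean()))


def compute_signal_metrics(matrix: KeywordPeriodMatrix,
                           cfg: TimeWeightConfig = TimeWeightConfig()) -> pd.DataFrame:
    """Per-keyword signal metrics table.

    Columns: one ``dod_<period>`` per period, ``avg_growth``,
    ``avg_df_exact`` (unrounded, used for map coordinates) and ``avg_df``
    (rounded for reporting). Indexed by keyword concept id.
    """
    dod = degree_of_diffusion(matrix, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        growth = [average_growth(dod[i]) for i in range(dod.shape[0])]
    frame = pd.DataFrame(dod, index=matrix.keywords,
                         columns=[f"dod_{p}" for p in matrix.period_labels])
    frame["avg_growth"] = growth
    frame["avg_df_exact"] = matrix.df.mean(axis=1)
    frame["avg_df"] = [average_df(matrix.df[i]) for i in range(len(matrix.keywords))]
    frame["label"] = [matrix.labels.get(k, k) for k in matrix.keywords]
    return frame
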