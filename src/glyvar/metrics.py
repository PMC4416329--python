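"""Closed-form glycemic variability metrics.

All metrics operate on a :class:`~glyvar.series.GriddedSeries` in mg/dL and
return ``None`` when the quantity is undefined for the input (too few
observations, recording too short) — never a fabricated zero.

Conventions
-----------
* A slot is *observed* when measured or interpolated; missing slots are
  excluded slot-wise (AUC, time-in-range, SD) or pair-wise (CONGA, MODD).
* AUC metrics use the rectangle rule — each observed slot contributes its
  exceedance for one sampling interval — and divide by the total observed
  duration, so a series constantly 10 mg/dL above the upper target gives
  Avg. AUC-H = 10 mg/dL exactly.
* Threshold comparisons are strict (``G > TR_H``, ``G < TR_L``); values
  exactly on a threshold count as in range.
* SD and CONGA use the sample (N-1) denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .exceptions import ConfigError
from .series import GriddedSeries

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class TargetRange:
    """Glycemic target range, mg/dL: ``tr_low < tr_high``, both > 0."""

    tr_low: float
    tr_high: float

    def __post_init__(self) -> None:
        if not (0 < self.tr_low < self.tr_high):
            raise ConfigError(
                f"invalid target range [{self.tr_low}, {self.tr_high}] "
                "(need 0 < low < high)"
            )


@dataclass(frozen=True)
class LagDifferenceSet:
    """Glucose differences ``D_t = G_t - G_{t-lag}`` at a fixed lag.

    Only pairs with both endpoints observed are kept; ``k`` is the number of
    usable pairs.
    """

    lag_min: int
    diffs: np.ndarray
    k: int


class TimeInRanges(NamedTuple):
    """Percentages of observed time above / below / inside the target range."""

    patr: float
    pbtr: float
    in_range: float


def _observed_values(gridded: GriddedSeries) -> np.ndarray:
    return gridded.values[gridded.observed]


def lag_differences(gridded: GriddedSeries, lag_min: int) -> LagDifferenceSet:
    """Build the set of differences at ``lag_min`` minutes (pairwise exclusion)."""
    lag_slots, rem = divmod(lag_min, gridded.interval_min)
    if rem != 0 or lag_slots <= 0:
        raise ConfigError(
            f"lag of {lag_min} min is not a positive multiple of the "
            f"{gridded.interval_min}-min sampling interval"
        )
    if lag_slots >= gridded.n_slots:
        return LagDifferenceSet(lag_min=lag_min, diffs=np.empty(0), k=0)
    obs = gridded.observed
    usable = obs[lag_slots:] & obs[:-lag_slots]
    diffs = (gridded.values[lag_slots:] - gridded.values[:-lag_slots])[usable]
    return LagDifferenceSet(lag_min=lag_min, diffs=diffs, k=len(diffs))


def avg_auc_high(gridded: GriddedSeries, tr_high: float) -> Optional[float]:
    """Average exposure to hyperglycemia: time-average of ``(G - TR_H)+``.

    The denominator is the whole observed duration, not just hyperglycemic
    time, so the result reads "on average the glucose exceeded TR_H by this
    many mg/dL".  ``None`` when no slot is observed.
    """
    values = _observed_values(gridded)
    if len(values) == 0:
        return None
    return float(np.mean(np.where(values > tr_high, values - tr_high, 0.0)))


def avg_auc_low(gridded: GriddedSeries, tr_low: float) -> Optional[float]:
    """Average exposure to hypoglycemia: time-average of ``(TR_L - G)+``."""
    values = _observed_values(gridded)
    if len(values) == 0:
        return None
    return float(np.mean(np.where(values < tr_low, tr_low - values, 0.0)))


def time_in_ranges(
    gridded: GriddedSeries, target_range: TargetRange
) -> Optional[TimeInRanges]:
    """PATR / PBTR / in-range percentages of observed time.

    Slot-count percentages (equivalent to time percentages on a uniform
    grid).  Boundary values count as in range.  ``None`` when no slot is
    observed.
    """
    values = _observed_values(gridded)
    if len(values) == 0:
        return None
    n = len(values)
    patr = 100.0 * np.sum(values > target_range.tr_high) / n
    pbtr = 100.0 * np.sum(values < target_range.tr_low) / n
    return TimeInRanges(float(patr), float(pbtr), float(100.0 - patr - pbtr))


def conga(gridded: GriddedSeries, n_hours: int = 1) -> Optional[float]:
    """CONGA(n): sample SD of glucose differences at lag ``n`` hours.

    With ``D_t = G_t - G_{t - n*60min}`` over the ``k`` slots where both
    endpoints are observed, returns ``sqrt(sum((D_t - mean D)^2) / (k - 1))``.
    ``None`` when fewer than two usable pairs exist.
    """
    if n_hours <= 0:
        raise ConfigError("CONGA order must be a positive number of hours")
    lags = lag_differences(gridded, n_hours * 60)
    if lags.k < 2:
        return None
    return float(np.std(lags.diffs, ddof=1))


def modd(gridded: GriddedSeries) -> Optional[float]:
    """MODD: mean absolute difference between values exactly 24 h apart.

    ``None`` when the recording does not span more than 24 h or no slot pair
    1440 min apart has both endpoints observed.
    """
    if gridded.span_min <= MINUTES_PER_DAY:
        return None
    lags = lag_differences(gridded, MINUTES_PER_DAY)
    if lags.k == 0:
        return None
    return float(np.mean(np.abs(lags.diffs)))


def glucose_sd(gridded: GriddedSeries) -> Optional[float]:
    """Sample standard deviation (N-1) over observed slots; ``None`` if < 2."""
    values = _observed_values(gridded)
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1))
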