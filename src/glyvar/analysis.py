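"""End-to-end analysis: read → grid → interpolate → window → metrics → report."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import io as gio
from .exceptions import ConfigError
from .grid import DEFAULT_MAX_GAP, align_to_grid, interpolate_gaps, select_window
from .mage import DEFAULT_ME, compute_mage
from .metrics import (
    TargetRange,
    avg_auc_high,
    avg_auc_low,
    conga,
    glucose_sd,
    modd,
    time_in_ranges,
)
from .report import VariabilityReport
from .series import GlucoseSeries, GriddedSeries, Unit


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything one analysis run needs (mirrors the CLI flags)."""

    input_path: str
    tr_low: float
    tr_high: float
    dialect: str = "generic"  # "generic" or "carelink"
    timestamp_column: str = "timestamp"
    glucose_column: str = "glucose"
    unit: Unit = Unit.MG_DL
    dayfirst: bool = False
    me: float = DEFAULT_ME
    conga_n: int = 1
    interval_min: int = 5
    max_gap: int = DEFAULT_MAX_GAP
    window_start: Optional[str] = None
    window_hours: Optional[float] = None
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        TargetRange(self.tr_low, self.tr_high)  # validates
        if self.me <= 0 or self.interval_min <= 0 or self.max_gap < 0:
            raise ConfigError("thresholds and intervals must be positive")


def analyze_gridded(
    gridded: GriddedSeries,
    target_range: TargetRange,
    *,
    me: float = DEFAULT_ME,
    conga_n: int = 1,
    max_gap: int = DEFAULT_MAX_GAP,
    window_start: Optional[str] = None,
    window_hours: Optional[float] = None,
) -> VariabilityReport:
    """Compute every metric on an already gridded (and interpolated) series."""
    tir = time_in_ranges(gridded, target_range)
    mage = compute_mage(gridded, me)
    return VariabilityReport(
        avg_auc_high=avg_auc_high(gridded, target_range.tr_high),
        avg_auc_low=avg_auc_low(gridded, target_range.tr_low),
        patr=tir.patr if tir else None,
        pbtr=tir.pbtr if tir else None,
        in_range=tir.in_range if tir else None,
        sd=glucose_sd(gridded),
        conga=conga(gridded, conga_n),
        modd=modd(gridded),
        mage_plus=mage.mage_plus,
        mage_minus=mage.mage_minus,
        mage_avg=mage.mage_avg,
        excursion_frequency=mage.excursion_frequency,
        alert_visual_analysis=mage.alert_visual_analysis,
        n_total_points=gridded.n_observed,
        n_interpolated_points=gridded.n_interpolated,
        tr_low=target_range.tr_low,
        tr_high=target_range.tr_high,
        me=me,
        conga_n=conga_n,
        interval_min=gridded.interval_min,
        max_gap=max_gap,
        window_start=window_start,
        window_hours=window_hours,
        patient_id=gridded.patient_id,
    )


def analyze_series(series: GlucoseSeries, config: AnalysisConfig) -> VariabilityReport:
    """Grid, interpolate, window, and compute the report for a parsed series."""
    series = gio.convert_units(series, Unit.MG_DL)
    gridded = align_to_grid(series, config.interval_min)
    if config.window_start is not None or config.window_hours is not None:
        if config.window_start is None or config.window_hours is None:
            raise ConfigError("window requires both start and duration")
        gridded = select_window(
            gridded,
            pd.Timestamp(config.window_start),
            int(round(config.window_hours * 60)),
        )
    gridded = interpolate_gaps(gridded, config.max_gap)
    return analyze_gridded(
        gridded,
        TargetRange(config.tr_low, config.tr_high),
        me=config.me,
        conga_n=config.conga_n,
        max_gap=config.max_gap,
        window_start=config.window_start,
        window_hours=config.window_hours,
    )


def run_analysis(config: AnalysisConfig) -> VariabilityReport:
    """Read the configured input and produce the full variability report."""
    if config.dialect == "carelink":
        series = gio.read_carelink_export(
            config.input_path,
            dayfirst=config.dayfirst,
            patient_id=config.patient_id,
        )
    elif config.dialect == "generic":
        series = gio.read_generic_csv(
            config.input_path,
            config.timestamp_column,
            config.glucose_column,
            config.unit,
            dayfirst=config.dayfirst,
            patient_id=config.patient_id,
        )
    else:
        raise ConfigError(f"unknown dialect: {config.dialect!r}")
    return analyze_series(series, config)
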