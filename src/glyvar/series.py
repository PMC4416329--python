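"""Core containers for CGM time series.

Two containers cover the pipeline:

* :class:`GlucoseSeries` — raw timestamped readings in a declared unit, as
  parsed from a device export.  Timestamps are strictly increasing; values
  are finite and positive.
* :class:`GriddedSeries` — the same data aligned to a fixed sampling grid
  (nominally 5 minutes), with one slot per grid time and an explicit
  per-slot source flag (measured / interpolated / missing).  All variability
  metrics operate on this container, in mg/dL.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import GlyvarError

#: mg/dL per mmol/L (molar mass of glucose 180.182 g/mol, divided by 10).
MGDL_PER_MMOLL = 18.0182


class Unit(str, enum.Enum):
    """Glucose concentration unit."""

    MG_DL = "mg_dL"
    MMOL_L = "mmol_L"


class SourceFlag(enum.IntEnum):
    """Provenance of a grid slot's value."""

    MEASURED = 0
    INTERPOLATED = 1
    MISSING = 2


@dataclass(frozen=True)
class GlucoseSeries:
    """Ordered timestamped glucose readings in a single unit.

    Parameters
    ----------
    data : pandas.Series
        Glucose values indexed by a ``DatetimeIndex`` with minute (or finer)
        resolution.  Must be sorted strictly ascending with no duplicate
        timestamps; values must be finite and > 0.
    unit : Unit
        Unit shared by every sample.
    patient_id : str, optional
        Opaque label carried through to reports.
    nominal_interval_min : int
        Nominal sampling interval of the device, minutes (default 5).
    """

    data: pd.Series
    unit: Unit = Unit.MG_DL
    patient_id: Optional[str] = None
    nominal_interval_min: int = 5

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise GlyvarError("GlucoseSeries requires a DatetimeIndex")
        if len(self.data) == 0:
            raise GlyvarError("GlucoseSeries must contain at least one sample")
        idx = self.data.index
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise GlyvarError("timestamps must be strictly increasing")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise GlyvarError("glucose values must be finite and > 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_unit(self, target: Unit) -> "GlucoseSeries":
        """Convert to ``target`` unit (see :func:`glyvar.io.convert_units`)."""
        if Unit(target) == self.unit:
            return self
        if self.unit == Unit.MMOL_L:
            converted = self.data * MGDL_PER_MMOLL
        else:
            converted = self.data / MGDL_PER_MMOLL
        return replace(self, data=converted, unit=Unit(target))


@dataclass(frozen=True)
class GriddedSeries:
    """A glucose series aligned to a fixed sampling grid.

    Slot ``k`` corresponds to time ``start + k * interval_min``.  ``values``
    holds mg/dL with ``NaN`` marking missing slots; ``flags`` records each
    slot's provenance.  Invariant: ``flags[k] == MISSING`` iff
    ``values[k]`` is NaN.
    """

    start: pd.Timestamp
    interval_min: int
    values: np.ndarray
    flags: np.ndarray
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        flags = np.asarray(self.flags, dtype=np.uint8)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "flags", flags)
        if values.shape != flags.shape or values.ndim != 1:
            raise GlyvarError("values and flags must be 1-D arrays of equal length")
        missing = flags == SourceFlag.MISSING
        if not np.array_equal(missing, np.isnan(values)):
            raise GlyvarError("NaN values and MISSING flags must coincide")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_slots(self) -> int:
        return len(self.values)

    @property
    def n_measured(self) -> int:
        return int(np.sum(self.flags == SourceFlag.MEASURED))

    @property
    def n_interpolated(self) -> int:
        return int(np.sum(self.flags == SourceFlag.INTERPOLATED))

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.flags == SourceFlag.MISSING))

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of slots with a value (measured or interpolated)."""
        return self.flags != SourceFlag.MISSING

    @property
    def n_observed(self) -> int:
        return int(np.sum(self.observed))

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.n_slots) * self.interval_min, unit="min"
        )

    @property
    def span_min(self) -> int:
        """Duration covered by the grid, minutes (half-open convention)."""
        return self.n_slots * self.interval_min

    def slot_time(self, k: int) -> pd.Timestamp:
        return self.start + pd.Timedelta(minutes=k * self.interval_min)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: timestamp, glucose (mg/dL), source flag name."""
        return pd.DataFrame(
            {
                "timestamp": self.times,
                "glucose_mgdl": self.values,
                "source": [SourceFlag(f).name.lower() for f in self.flags],
            }
        )
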