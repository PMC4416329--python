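"""Grid alignment, bounded gap interpolation, and window selection.

CGM devices sample on a nominal 5-minute schedule but exports routinely
contain missing samples (late calibration, sensor dropout).  The pipeline
here is:

1. :func:`align_to_grid` — snap each reading to its nearest slot on a fixed
   grid anchored at the first sample's floored timestamp; unfilled slots are
   marked missing.
2. :func:`interpolate_gaps` — fill interior missing runs of at most
   ``max_gap`` consecutive slots (default 21) by linear interpolation between
   the bounding measurements.  Longer runs, and leading/trailing runs, are
   never filled: extrapolation would invent data.
3. :func:`select_window` — cut an analysis window (e.g. 48 h) out of a longer
   recording, on the same grid.

Interpolated values always lie between their bounding measurements, so
filling can only reduce apparent variability — a caveat that applies to any
linearly-imputed CGM trace.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import GridError
from .series import GlucoseSeries, GriddedSeries, SourceFlag, Unit

#: Longest missing run (consecutive slots) that interpolation will fill.
DEFAULT_MAX_GAP = 21


def align_to_grid(series: GlucoseSeries, interval_min: int = 5) -> GriddedSeries:
    """Assign each sample of ``series`` to its nearest slot on a fixed grid.

    The grid is anchored at the first sample's timestamp rounded down to a
    whole multiple of ``interval_min``; slot ``k`` sits at
    ``anchor + k * interval_min``.  Each sample maps to the nearest slot
    (always within ``interval_min / 2``).  Two samples mapping to one slot is
    ambiguous sampling and raises :class:`~glyvar.exceptions.GridError`.

    The series must be in mg/dL; convert first (metrics are defined in
    mg/dL throughout).
    """
    if series.unit != Unit.MG_DL:
        raise GridError("align_to_grid expects mg/dL; call convert_units first")
    if interval_min <= 0:
        raise GridError("interval must be positive")

    idx = series.timestamps
    anchor = idx[0].floor(f"{interval_min}min")
    offsets_min = (idx - anchor) / pd.Timedelta(minutes=1)
    slots = np.rint(np.asarray(offsets_min) / interval_min).astype(np.int64)

    unique, counts = np.unique(slots, return_counts=True)
    if np.any(counts > 1):
        clash = unique[counts > 1][0]
        t = anchor + pd.Timedelta(minutes=int(clash) * interval_min)
        raise GridError(f"two samples map to the same grid slot at {t}")

    n_slots = int(slots[-1]) + 1
    values = np.full(n_slots, np.nan)
    flags = np.full(n_slots, SourceFlag.MISSING, dtype=np.uint8)
    values[slots] = series.values
    flags[slots] = SourceFlag.MEASURED
    return GriddedSeries(
        start=anchor,
        interval_min=interval_min,
        values=values,
        flags=flags,
        patient_id=series.patient_id,
    )


def _missing_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of missing slots as (start, length) pairs."""
    missing = flags == SourceFlag.MISSING
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(flags)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def interpolate_gaps(
    gridded: GriddedSeries, max_gap: int = DEFAULT_MAX_GAP
) -> GriddedSeries:
    """Fill bounded missing runs of length <= ``max_gap`` linearly.

    A run is filled only when flanked by non-missing slots on both sides;
    filled slots are flagged ``INTERPOLATED``.  Leading and trailing runs and
    runs longer than ``max_gap`` remain missing.  Idempotent.
    """
    if np.sum(gridded.observed) < 2:
        raise GridError("interpolation needs at least two observed slots")
    values = gridded.values.copy()
    flags = gridded.flags.copy()
    n = len(values)
    for start, length in _missing_runs(gridded.flags):
        lo, hi = start - 1, start + length
        if lo < 0 or hi >= n or length > max_gap:
            continue
        filled = np.interp(
            np.arange(start, hi), [lo, hi], [values[lo], values[hi]]
        )
        values[start:hi] = filled
        flags[start:hi] = SourceFlag.INTERPOLATED
    return GriddedSeries(
        start=gridded.start,
        interval_min=gridded.interval_min,
        values=values,
        flags=flags,
        patient_id=gridded.patient_id,
    )


def select_window(
    gridded: GriddedSeries, start: pd.Timestamp, duration_min: int
) -> GriddedSeries:
    """Cut the half-open window ``[start, start + duration_min)`` out of a grid.

    ``start`` must fall on the recording's grid and the window must lie
    within the recording span; a 48 h window on a 5-minute grid yields 576
    slots.  Counts of measured/interpolated slots are recomputed implicitly
    from the sliced flags.
    """
    start = pd.Timestamp(start)
    if duration_min <= 0:
        raise GridError("window duration must be positive")
    offset_min = (start - gridded.start) / pd.Timedelta(minutes=1)
    k0, rem = divmod(offset_min, gridded.interval_min)
    if rem != 0:
        raise GridError(f"window start {start} is not on the sampling grid")
    n_win, rem = divmod(duration_min, gridded.interval_min)
    if rem != 0:
        raise GridError("window duration must be a multiple of the interval")
    k0 = int(k0)
    k1 = k0 + int(n_win)
    if k0 < 0 or k1 > gridded.n_slots:
        raise GridError("window lies outside the recording span")
    return GriddedSeries(
        start=start,
        interval_min=gridded.interval_min,
        values=gridded.values[k0:k1],
        flags=gridded.flags[k0:k1],
        patient_id=gridded.patient_id,
    )
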