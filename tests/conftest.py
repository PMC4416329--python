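"""Shared fixtures and builders for the glyvar test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glyvar import GriddedSeries, SourceFlag

START = pd.Timestamp("2013-06-01 00:00:00")


def make_gridded(values, interval_min=5, start=START, interpolated=()):
    """Build a GriddedSeries from a value list; NaN marks missing slots."""
    values = np.asarray(values, dtype=float)
    flags = np.where(
        np.isnan(values), SourceFlag.MISSING, SourceFlag.MEASURED
    ).astype(np.uint8)
    for k in interpolated:
        flags[k] = SourceFlag.INTERPOLATED
    return GriddedSeries(
        start=start, interval_min=interval_min, values=values, flags=flags
    )


def random_walk_values(seed, n_slots, baseline=140.0, step_sd=8.0):
    """Seeded random-walk glucose trace clipped to a physiological band."""
    rng = np.random.default_rng(seed)
    walk = baseline + np.cumsum(rng.normal(0.0, step_sd, size=n_slots))
    return np.clip(walk, 40.0, 400.0)


@pytest.fixture
def gridded_random_walk():
    def _build(seed, n_slots=576, missing_runs=()):
        values = random_walk_values(seed, n_slots)
        for start_slot, length in missing_runs:
            values[start_slot : start_slot + length] = np.nan
        return make_gridded(values)

    return _build


@pytest.fixture
def generic_csv(tmp_path):
    """Write rows to a generic timestamp,glucose CSV and return the path."""

    def _write(rows, header="timestamp,glucose"):
        path = tmp_path / "input.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return _write
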