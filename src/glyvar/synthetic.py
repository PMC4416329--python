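"""Seeded synthetic CGM fixtures with known variability structure.

Every metric in the package is testable without clinical data: the
generator emits glucose series on the nominal 5-minute grid — the sampling
scheme of real sensor exports — as deterministic waveforms (constant, ramp,
sinusoid, triangle "sawtooth", square wave) or a seeded random walk, with
optional Gaussian sensor noise and injected missing runs.  For the
analytic, noise-free waveforms :func:`known_answer` returns the closed-form
value of each metric, giving an exact oracle for the whole pipeline.

Conventions: a ``duration``-hour recording covers the half-open interval
``[start, start + duration)``, so a 48 h fixture holds 576 slots at 5-minute
spacing (288 per day, the daily maximum of a real sensor).  The triangle
wave starts at its nadir and swings by ``amplitude`` every half ``period``.
The square wave sits at ``baseline + amplitude`` for the first half of each
period and ``baseline - amplitude`` for the second.  The ramp rises by
``amplitude`` per ``period`` minutes.  Random-walk steps are Gaussian with
SD ``amplitude`` per slot, reflected into [40, 400] mg/dL to stay
physiologically plausible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .series import GlucoseSeries, Unit

DEFAULT_START = pd.Timestamp("2013-06-01 00:00:00")


class Waveform(str, enum.Enum):
    CONSTANT = "constant"
    RAMP = "ramp"
    SINUSOID = "sinusoid"
    SAWTOOTH = "sawtooth"
    SQUARE_WAVE = "square_wave"
    RANDOM_WALK = "random_walk"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic CGM recording.

    Defaults mirror a typical study window: 48 h at 5-minute sampling around
    a 140 mg/dL baseline, noise-free and gap-free unless requested.
    """

    kind: Waveform = Waveform.CONSTANT
    duration_h: float = 48.0
    interval_min: int = 5
    baseline: float = 140.0
    amplitude: float = 0.0
    period_min: float = 240.0
    noise_sd: float = 0.0
    gap_runs: Sequence[tuple[int, int]] = field(default_factory=tuple)
    seed: int = 0
    start: pd.Timestamp = DEFAULT_START

    @property
    def n_slots(self) -> int:
        return int(round(self.duration_h * 60 / self.interval_min))


def _waveform(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_slots
    t = np.arange(n) * spec.interval_min  # minutes since start
    kind = Waveform(spec.kind)
    if kind is Waveform.CONSTANT:
        return np.full(n, spec.baseline)
    if kind is Waveform.RAMP:
        return spec.baseline + spec.amplitude * t / spec.period_min
    if kind is Waveform.SINUSOID:
        return spec.baseline + spec.amplitude * np.sin(2 * np.pi * t / spec.period_min)
    if kind is Waveform.SAWTOOTH:
        phase = (t % spec.period_min) / spec.period_min  # 0..1
        tri = np.where(phase < 0.5, 2 * phase, 2 * (1 - phase))
        return spec.baseline + spec.amplitude * tri
    if kind is Waveform.SQUARE_WAVE:
        high = (t % spec.period_min) < spec.period_min / 2
        return spec.baseline + np.where(high, spec.amplitude, -spec.amplitude)
    if kind is Waveform.RANDOM_WALK:
        steps = rng.normal(0.0, spec.amplitude, size=n)
        steps[0] = 0.0
        walk = spec.baseline + np.cumsum(steps)
        # reflect into the physiological band
        lo, hi = 40.0, 400.0
        period = 2 * (hi - lo)
        folded = np.mod(walk - lo, period)
        return lo + np.minimum(folded, period - folded)
    raise ConfigError(f"unknown waveform kind: {spec.kind!r}")


def generate(spec: FixtureSpec) -> GlucoseSeries:
    """Generate the series described by ``spec`` (deterministic given seed)."""
    if spec.duration_h <= 0 or spec.interval_min <= 0:
        raise ConfigError("duration and interval must be positive")
    if spec.amplitude < 0 or spec.noise_sd < 0:
        raise ConfigError("amplitude and noise_sd must be non-negative")
    rng = np.random.default_rng(spec.seed)
    values = _waveform(spec, rng)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=len(values))
    values = np.maximum(values, 1.0)  # container requires glucose > 0

    keep = np.ones(spec.n_slots, dtype=bool)
    for gap_start, gap_len in spec.gap_runs:
        if gap_start < 0 or gap_start + gap_len > spec.n_slots:
            raise ConfigError(f"gap run {(gap_start, gap_len)} outside the recording")
        keep[gap_start : gap_start + gap_len] = False

    times = spec.start + pd.to_timedelta(
        np.arange(spec.n_slots) * spec.interval_min, unit="min"
    )
    data = pd.Series(values[keep], index=times[keep])
    return GlucoseSeries(
        data=data,
        unit=Unit.MG_DL,
        patient_id=f"synthetic-{Waveform(spec.kind).value}-{spec.seed}",
        nominal_interval_min=spec.interval_min,
    )


# ---------------------------------------------------------------------------
# closed-form oracle registry
# ---------------------------------------------------------------------------


def _is_analytic(spec: FixtureSpec) -> bool:
    return (
        Waveform(spec.kind) is not Waveform.RANDOM_WALK
        and spec.noise_sd == 0
        and len(spec.gap_runs) == 0
    )


def known_answer(spec: FixtureSpec, metric: str, **params) -> Optional[float]:
    """Closed-form metric value for an analytic noise-free spec, else ``None``.

    Supported where a closed form exists:

    * ``constant`` — every metric (AUC/PATR against ``tr_high``/``tr_low``
      params, CONGA/MODD/SD = 0, MAGE undefined → ``None`` is the *answer*
      for mage and is indistinguishable from "no closed form"; tests use
      explicit expectations for undefined MAGE).
    * ``ramp`` — ``conga`` = 0; ``modd`` = amplitude · 1440 / period.
    * periodic kinds whose period divides 1440 min — ``modd`` = 0.
    * ``square_wave`` with period dividing the span — ``avg_auc_high`` at
      ``tr_high = baseline`` is amplitude / 2 (half the slots sit exactly
      amplitude above it), ``patr`` = 50.
    * ``sawtooth`` whose half-period divides the spanned time
      ``(n_slots - 1) · interval`` and amplitude > me — ``mage_plus`` /
      ``mage_minus`` / ``mage_avg`` = amplitude, ``excursion_frequency`` =
      number of half-cycles.
    """
    if not _is_analytic(spec):
        return None
    kind = Waveform(spec.kind)
    span_min = (spec.n_slots - 1) * spec.interval_min

    if kind is Waveform.CONSTANT:
        if metric in ("conga", "modd", "sd"):
            return 0.0
        if metric == "avg_auc_high":
            return max(spec.baseline - params["tr_high"], 0.0)
        if metric == "avg_auc_low":
            return max(params["tr_low"] - spec.baseline, 0.0)
        if metric == "patr":
            return 100.0 if spec.baseline > params["tr_high"] else 0.0
        if metric == "pbtr":
            return 100.0 if spec.baseline < params["tr_low"] else 0.0
        if metric == "excursion_frequency":
            return 0.0
        return None

    if kind is Waveform.RAMP:
        if metric == "conga":
            return 0.0
        if metric == "modd" and spec.duration_h > 24:
            return spec.amplitude * 1440.0 / spec.period_min
        if metric == "sd":
            # SD of an arithmetic progression of n slots
            n = spec.n_slots
            step = spec.amplitude * spec.interval_min / spec.period_min
            return float(step * np.sqrt(n * (n + 1) / 12.0))
        return None

    if kind in (Waveform.SINUSOID, Waveform.SAWTOOTH, Waveform.SQUARE_WAVE):
        if metric == "modd" and spec.duration_h > 24 and 1440 % spec.period_min == 0:
            return 0.0

    total_min = spec.n_slots * spec.interval_min
    if (
        kind is Waveform.SQUARE_WAVE
        and total_min % spec.period_min == 0
        and (spec.period_min / 2.0) % spec.interval_min == 0
    ):
        if metric == "avg_auc_high" and params.get("tr_high") == spec.baseline:
            return spec.amplitude / 2.0
        if metric == "patr" and params.get("tr_high") == spec.baseline:
            return 50.0

    if kind is Waveform.SAWTOOTH:
        half = spec.period_min / 2.0
        me = params.get("me", 45.0)
        if span_min % half == 0 and spec.amplitude > me:
            if metric in ("mage_plus", "mage_minus", "mage_avg"):
                return spec.amplitude
            if metric == "excursion_frequency":
                return span_min / half
    return None
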