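"""The variability report: every computed metric plus bookkeeping.

Undefined metrics (recording too short, no meaningful excursion, ...) are
carried as ``None`` and serialized as explicit JSON nulls / empty CSV cells,
never as zero.

JSON schema (stable keys)
-------------------------
``avg_auc_high``, ``avg_auc_low`` — mg/dL, time-averaged exceedance.
``patr``, ``pbtr``, ``in_range`` — percent of observed time.
``sd`` — mg/dL, sample SD.  ``conga`` — mg/dL at order ``conga_n`` (hours).
``modd`` — mg/dL.  ``mage_plus``, ``mage_minus``, ``mage_avg`` — mg/dL.
``excursion_frequency`` — count of meaningful excursions.
``alert_visual_analysis`` — bool.
``n_total_points`` — glucose values entering the metrics (measured +
interpolated); ``n_interpolated_points`` — how many of them were filled.
``tr_low``, ``tr_high``, ``me`` — mg/dL thresholds used.
``interval_min``, ``max_gap``, ``conga_n``, ``window_start``,
``window_hours``, ``patient_id`` — echoed configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from typing import Optional

from .exceptions import GlyvarError


def _fmt(value, digits: int = 2) -> str:
    if value is None:
        return "undefined"
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return f"{value:.{digits}f}"
    return str(value)


@dataclass(frozen=True)
class VariabilityReport:
    """All glycemic-variability metrics for one analysis window."""

    avg_auc_high: Optional[float]
    avg_auc_low: Optional[float]
    patr: Optional[float]
    pbtr: Optional[float]
    in_range: Optional[float]
    sd: Optional[float]
    conga: Optional[float]
    modd: Optional[float]
    mage_plus: Optional[float]
    mage_minus: Optional[float]
    mage_avg: Optional[float]
    excursion_frequency: int
    alert_visual_analysis: bool
    n_total_points: int
    n_interpolated_points: int
    tr_low: float
    tr_high: float
    me: float
    conga_n: int
    interval_min: int
    max_gap: int
    window_start: Optional[str] = None
    window_hours: Optional[float] = None
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("patr", "pbtr"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0 + 1e-9):
                raise GlyvarError(f"{name}={v} outside [0, 100]")
        if self.patr is not None and self.pbtr is not None:
            if self.patr + self.pbtr > 100.0 + 1e-9:
                raise GlyvarError("patr + pbtr exceeds 100")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "VariabilityReport":
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in payload.items() if k in names})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def to_csv(self, path) -> None:
        """One header row + one value row; undefined metrics left empty."""
        items = self.to_dict()
        header = ",".join(items)
        row = ",".join("" if v is None else str(v) for v in items.values())
        with open(path, "w") as fh:
            fh.write(header + "\n" + row + "\n")

    def summary(self) -> str:
        """Human-readable result table, grouped the way clinicians read it."""
        lines = [
            "Glycemic variability report",
            "===========================",
            f"points used: {self.n_total_points} "
            f"(interpolated: {self.n_interpolated_points})",
            f"target range: {self.tr_low:g}-{self.tr_high:g} mg/dL, "
            f"ME: {self.me:g} mg/dL, CONGA order: {self.conga_n} h",
            "",
            f"Avg. AUC-H: {_fmt(self.avg_auc_high)} mg/dL",
            f"Avg. AUC-L: {_fmt(self.avg_auc_low)} mg/dL",
            f"PATR:       {_fmt(self.patr)} %",
            f"PBTR:       {_fmt(self.pbtr)} %",
            f"SD:         {_fmt(self.sd)} mg/dL",
            f"CONGA({self.conga_n}):   {_fmt(self.conga)} mg/dL",
            f"MODD:       {_fmt(self.modd)} mg/dL",
            f"MAGE+:      {_fmt(self.mage_plus)} mg/dL",
            f"MAGE-:      {_fmt(self.mage_minus)} mg/dL",
            f"MAGE avg.:  {_fmt(self.mage_avg)} mg/dL",
            f"Excursion frequency: {self.excursion_frequency}",
        ]
        return "\n".join(lines)
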