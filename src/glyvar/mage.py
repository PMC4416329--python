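"""Mean Amplitude of Glycemic Excursions (MAGE), modified Baghurst variant.

The classical MAGE counts glucose swings (nadir-to-peak, peak-to-nadir)
whose amplitude exceeds a *meaningful excursion* threshold (ME, here a fixed
45 mg/dL by default rather than one sample SD).  The procedure is a
three-stage turning-point reduction:

1. identify all turning points of the curve (plateaus collapsed to their
   first slot, endpoints included);
2. delete turning points whose excursions on *both* sides are below ME —
   **unless** the point is the centre of a "W" or "M" pattern (a peak lower
   than both neighbouring peaks, or a nadir higher than both neighbouring
   nadirs), which this variant retains throughout;
3. remove sub-ME excursions bordered on one side only by merging each member
   of the small excursion with its like-kind neighbour across it, keeping
   the more extreme of the two (ties keep the earlier point).

Two further refinements handle the reference-point problem of a sequential
scan: when no meaningful excursion is reachable from the first sample even
though the curve contains some, the start point moves to the global extremum
(maximum or minimum, whichever occurs first); and once the first ME is
found, the stretch between the start point and that ME is re-checked for
missed excursions (:func:`backtrack_recheck`).

Because W/M patterns are never deleted, the final retained curve can contain
excursions at or below ME; those do not enter the MAGE means but raise an
alert asking for visual analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import GlyvarError
from .series import GriddedSeries

#: Default meaningful-excursion threshold, mg/dL.
DEFAULT_ME = 45.0

#: Message emitted when the retained curve contains a sub-ME excursion.
ALERT_MESSAGE = "Visual analysis should be performed, see User Documentation"


class PointKind(enum.Enum):
    PEAK = "peak"
    NADIR = "nadir"


class Direction(enum.Enum):
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class TurningPoint:
    """A local extremum of the gridded glucose curve."""

    slot_index: int
    glucose: float
    kind: PointKind


@dataclass(frozen=True)
class Excursion:
    """A monotone swing between two consecutive retained turning points."""

    from_point: TurningPoint
    to_point: TurningPoint
    amplitude: float
    direction: Direction

    @classmethod
    def between(cls, a: TurningPoint, b: TurningPoint) -> "Excursion":
        direction = Direction.UP if a.kind == PointKind.NADIR else Direction.DOWN
        return cls(a, b, abs(b.glucose - a.glucose), direction)


@dataclass(frozen=True)
class MageResult:
    """MAGE statistics plus the retained curve that produced them.

    ``mage_plus`` / ``mage_minus`` are the mean amplitudes of retained
    upward / downward excursions exceeding ``me``; either is ``None`` when no
    such excursion exists, and ``mage_avg`` is the mean of the defined ones.
    ``excursion_frequency`` counts meaningful excursions in both directions.
    ``alert_visual_analysis`` is set when the retained curve carries an
    excursion at or below ``me`` (possible because W/M patterns are kept).
    """

    mage_plus: Optional[float]
    mage_minus: Optional[float]
    mage_avg: Optional[float]
    excursion_frequency: int
    me: float
    retained_points: list[TurningPoint] = field(default_factory=list)
    excursions: list[Excursion] = field(default_factory=list)
    alert_visual_analysis: bool = False


# ---------------------------------------------------------------------------
# turning-point detection
# ---------------------------------------------------------------------------


def _segment_values(
    gridded: GriddedSeries, start: int, stop: Optional[int]
) -> tuple[np.ndarray, int]:
    stop = gridded.n_slots if stop is None else stop
    values = gridded.values[start:stop]
    if np.any(np.isnan(values)):
        raise GlyvarError(
            "turning-point analysis requires a fully observed window; "
            "interpolate gaps or split on missing runs first"
        )
    return values, start


def _collapse_plateaus(values: np.ndarray, offset: int) -> list[tuple[int, float]]:
    """Keep the first slot of every run of equal values."""
    pts = [(offset, float(values[0]))]
    for k in range(1, len(values)):
        if values[k] != pts[-1][1]:
            pts.append((offset + k, float(values[k])))
    return pts


def find_turning_points(
    gridded: GriddedSeries, *, start: int = 0, stop: Optional[int] = None
) -> list[TurningPoint]:
    """All strict local extrema plus the two endpoints, plateaus collapsed.

    Slot indices refer to the grid of ``gridded``.  Fewer than 3 slots, or a
    constant window (which collapses to a single point), yield an empty
    list.  The output strictly alternates peak/nadir.
    """
    values, offset = _segment_values(gridded, start, stop)
    if len(values) < 3:
        return []
    collapsed = _collapse_plateaus(values, offset)
    if len(collapsed) < 2:
        return []
    points: list[TurningPoint] = []
    m = len(collapsed)
    for j, (slot, value) in enumerate(collapsed):
        if j == 0:
            rising = collapsed[1][1] > value
            kind = PointKind.NADIR if rising else PointKind.PEAK
        elif j == m - 1:
            rising = value > collapsed[m - 2][1]
            kind = PointKind.PEAK if rising else PointKind.NADIR
        else:
            before = collapsed[j - 1][1]
            after = collapsed[j + 1][1]
            if before < value > after:
                kind = PointKind.PEAK
            elif before > value < after:
                kind = PointKind.NADIR
            else:
                continue  # monotone shoulder
        points.append(TurningPoint(slot, value, kind))
    return points


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def _more_extreme(a: TurningPoint, b: TurningPoint) -> TurningPoint:
    """The more extreme of two like-kind points; ties keep the earlier."""
    if a.kind == PointKind.PEAK:
        return b if b.glucose > a.glucose else a
    return b if b.glucose < a.glucose else a


def _normalize(points: list[TurningPoint]) -> list[TurningPoint]:
    """Restore strict peak/nadir alternation by merging like-kind neighbours."""
    out: list[TurningPoint] = []
    for p in points:
        if out and out[-1].kind == p.kind:
            out[-1] = _more_extreme(out[-1], p)
        else:
            out.append(p)
    if len(out) == len(points):
        return out
    return _normalize(out)


def _protected(points: Sequence[TurningPoint]) -> set[int]:
    """Indices of W/M centres: less extreme than both like-kind neighbours."""
    prot: set[int] = set()
    for i in range(2, len(points) - 2):
        p, left, right = points[i], points[i - 2], points[i + 2]
        if p.kind == PointKind.PEAK:
            if p.glucose < left.glucose and p.glucose < right.glucose:
                prot.add(i)
        else:
            if p.glucose > left.glucose and p.glucose > right.glucose:
                prot.add(i)
    return prot


def _amplitudes(points: Sequence[TurningPoint]) -> list[float]:
    return [
        abs(points[i + 1].glucose - points[i].glucose)
        for i in range(len(points) - 1)
    ]


def prune_turning_points(
    points: Sequence[TurningPoint], me: float = DEFAULT_ME
) -> list[TurningPoint]:
    """Iteratively delete turning points bordered by sub-ME excursions.

    Stage one removes any interior point whose excursions on both sides are
    <= ``me``, unless it is a W/M centre; its two like-kind neighbours merge
    to the more extreme.  Stage two removes sub-ME excursions with a
    countable side: each member of the small excursion merges with its
    like-kind neighbour across it, keeping the more extreme (absent
    neighbours leave the member in place; merges never delete a W/M centre).
    Runs to a fixed point; the result strictly alternates.
    """
    pts = _normalize(list(points))
    while True:
        m = len(pts)
        if m < 2:
            return pts
        prot = _protected(pts)
        amps = _amplitudes(pts)

        # stage one: both-sided sub-ME points
        changed = False
        for i in range(1, m - 1):
            if amps[i - 1] <= me and amps[i] <= me and i not in prot:
                winner = _more_extreme(pts[i - 1], pts[i + 1])
                loser_idx = i + 1 if winner is pts[i - 1] else i - 1
                if loser_idx in prot:
                    continue  # merge would delete a retained W/M centre
                del pts[i]
                pts = _normalize(pts)
                changed = True
                break
        if changed:
            continue

        # stage two: one-sided sub-ME excursions, removed by merging
        for i in range(m - 1):
            if amps[i] > me or i in prot or (i + 1) in prot:
                continue
            drop: set[int] = set()
            if i + 2 < m:
                winner = _more_extreme(pts[i], pts[i + 2])
                loser_idx = i + 2 if winner is pts[i] else i
                if loser_idx not in prot:
                    drop.add(loser_idx)
            if i - 1 >= 0:
                winner = _more_extreme(pts[i - 1], pts[i + 1])
                loser_idx = i + 1 if winner is pts[i - 1] else i - 1
                if loser_idx not in prot:
                    drop.add(loser_idx)
            if drop:
                pts = _normalize([p for j, p in enumerate(pts) if j not in drop])
                changed = True
                break
        if not changed:
            return pts


# ---------------------------------------------------------------------------
# start point and backtracking
# ---------------------------------------------------------------------------


def excursions_between(points: Sequence[TurningPoint]) -> list[Excursion]:
    """Excursions between consecutive retained points, in temporal order."""
    return [
        Excursion.between(points[i], points[i + 1])
        for i in range(len(points) - 1)
    ]


def _has_meaningful(points: Sequence[TurningPoint], me: float) -> bool:
    return any(a > me for a in _amplitudes(points))


def select_start_point(
    gridded: GriddedSeries,
    me: float = DEFAULT_ME,
    *,
    start: int = 0,
    stop: Optional[int] = None,
) -> int:
    """Slot index the MAGE scan should start from.

    With the first sample as reference, if neither the global maximum nor the
    global minimum is more than ``me`` away while the pruned curve still
    contains meaningful excursions, the start moves to the global extremum —
    maximum or minimum, whichever occurs first.  Otherwise slot ``start``.
    """
    values, offset = _segment_values(gridded, start, stop)
    if len(values) < 3:
        return offset
    g1 = values[0]
    if (np.max(values) - g1 > me) or (g1 - np.min(values) > me):
        return offset
    pruned = prune_turning_points(
        find_turning_points(gridded, start=start, stop=stop), me
    )
    if not _has_meaningful(pruned, me):
        return offset
    first_max = int(np.argmax(values))
    first_min = int(np.argmin(values))
    return offset + min(first_max, first_min)


def backtrack_recheck(
    gridded: GriddedSeries,
    excursions: Sequence[Excursion],
    me: float = DEFAULT_ME,
    *,
    start: int = 0,
) -> list[Excursion]:
    """Re-scan the stretch before the first meaningful excursion.

    A sequential scan can fix its reference late and miss excursions between
    the start point and the first recognised ME; this pass re-runs
    turning-point detection and pruning on exactly that stretch and prepends
    any meaningful excursion not already in the list, preserving temporal
    order and never duplicating a point pair.
    """
    excursions = list(excursions)
    first = next((e for e in excursions if e.amplitude > me), None)
    if first is None:
        return excursions
    origin = first.from_point.slot_index
    # scan only the stretch the supplied curve does not already cover:
    # re-pruning a truncated prefix of an already-accounted-for region would
    # double-count (and can collapse deliberately retained W/M patterns)
    covered = min(e.from_point.slot_index for e in excursions)
    stop = min(origin, covered)
    if stop - start < 2:
        return excursions
    prefix_points = prune_turning_points(
        find_turning_points(gridded, start=start, stop=stop + 1), me
    )
    seen = {
        (e.from_point.slot_index, e.to_point.slot_index) for e in excursions
    }
    missed = [
        e
        for e in excursions_between(prefix_points)
        if e.amplitude > me
        and e.to_point.slot_index <= origin
        and (e.from_point.slot_index, e.to_point.slot_index) not in seen
    ]
    return missed + excursions


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _observed_segments(gridded: GriddedSeries) -> list[tuple[int, int]]:
    """Maximal runs of observed slots as half-open (start, stop) pairs."""
    obs = gridded.observed
    segments: list[tuple[int, int]] = []
    i, n = 0, len(obs)
    while i < n:
        if obs[i]:
            j = i
            while j < n and obs[j]:
                j += 1
            segments.append((i, j))
            i = j
        else:
            i += 1
    return segments


def _mean(values: list[float]) -> Optional[float]:
    return float(np.mean(values)) if values else None


def compute_mage(gridded: GriddedSeries, me: float = DEFAULT_ME) -> MageResult:
    """Full MAGE pipeline on a gridded series.

    Residual missing runs (gaps too long to interpolate) split the window
    into independent segments; each segment runs start-point selection,
    turning-point detection, pruning and the backtrack re-check, and the
    retained excursions are pooled into one amplitude list.
    """
    if me <= 0:
        raise GlyvarError("meaningful-excursion threshold must be positive")
    retained: list[TurningPoint] = []
    pooled: list[Excursion] = []
    for seg_start, seg_stop in _observed_segments(gridded):
        if seg_stop - seg_start < 3:
            continue
        s = select_start_point(gridded, me, start=seg_start, stop=seg_stop)
        points = prune_turning_points(
            find_turning_points(gridded, start=s, stop=seg_stop), me
        )
        excs = backtrack_recheck(
            gridded, excursions_between(points), me, start=s
        )
        retained.extend(points)
        pooled.extend(excs)

    ups = [e.amplitude for e in pooled if e.direction is Direction.UP and e.amplitude > me]
    downs = [e.amplitude for e in pooled if e.direction is Direction.DOWN and e.amplitude > me]
    mage_plus = _mean(ups)
    mage_minus = _mean(downs)
    defined = [v for v in (mage_plus, mage_minus) if v is not None]
    return MageResult(
        mage_plus=mage_plus,
        mage_minus=mage_minus,
        mage_avg=_mean(defined) if defined else None,
        excursion_frequency=len(ups) + len(downs),
        me=me,
        retained_points=retained,
        excursions=pooled,
        alert_visual_analysis=any(e.amplitude <= me for e in pooled),
    )
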