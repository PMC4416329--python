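"""Independent brute-force oracles for the variability metrics and MAGE.

Everything here is written with plain Python loops and lists, from the
metric definitions themselves, deliberately sharing no code with the
package.  Slow and obvious beats fast and clever: these functions exist to
be trusted, not used.
"""

from __future__ import annotations

import math

PEAK = "peak"
NADIR = "nadir"


# ---------------------------------------------------------------------------
# closed-form metric loops (slot-wise / pair-wise exclusion of missing)
# ---------------------------------------------------------------------------


def _observed(gridded):
    out = []
    for value, flag in zip(gridded.values, gridded.flags):
        if flag != 2:  # not missing
            out.append(float(value))
    return out


def oracle_auc_high(gridded, tr_high):
    values = _observed(gridded)
    if not values:
        return None
    total = 0.0
    for g in values:
        if g > tr_high:
            total += g - tr_high
    return total / len(values)


def oracle_auc_low(gridded, tr_low):
    values = _observed(gridded)
    if not values:
        return None
    total = 0.0
    for g in values:
        if g < tr_low:
            total += tr_low - g
    return total / len(values)


def oracle_time_in_ranges(gridded, tr_low, tr_high):
    values = _observed(gridded)
    if not values:
        return None
    above = sum(1 for g in values if g > tr_high)
    below = sum(1 for g in values if g < tr_low)
    patr = 100.0 * above / len(values)
    pbtr = 100.0 * below / len(values)
    return patr, pbtr, 100.0 - patr - pbtr


def oracle_sd(gridded):
    values = _observed(gridded)
    if len(values) < 2:
        return None
    mean = sum(values) / len(values)
    ss = sum((g - mean) ** 2 for g in values)
    return math.sqrt(ss / (len(values) - 1))


def _lag_diffs(gridded, lag_min):
    lag_slots = lag_min // gridded.interval_min
    diffs = []
    for t in range(lag_slots, len(gridded.values)):
        if gridded.flags[t] != 2 and gridded.flags[t - lag_slots] != 2:
            diffs.append(float(gridded.values[t]) - float(gridded.values[t - lag_slots]))
    return diffs


def oracle_conga(gridded, n_hours=1):
    diffs = _lag_diffs(gridded, n_hours * 60)
    if len(diffs) < 2:
        return None
    dbar = sum(diffs) / len(diffs)
    ss = sum((d - dbar) ** 2 for d in diffs)
    return math.sqrt(ss / (len(diffs) - 1))


def oracle_modd(gridded):
    if len(gridded.values) * gridded.interval_min <= 1440:
        return None
    diffs = _lag_diffs(gridded, 1440)
    if not diffs:
        return None
    return sum(abs(d) for d in diffs) / len(diffs)


# ---------------------------------------------------------------------------
# MAGE: naive transcription of the modified turning-point reduction
# ---------------------------------------------------------------------------
# Points are (slot, value, kind) tuples.  Rules, spelled out:
#   protection: an interior point with like-kind neighbours two steps away on
#     both sides is a W/M centre when it is strictly less extreme than both.
#   stage one: leftmost interior point with both adjacent amplitudes <= ME
#     and not protected is deleted; its like-kind neighbours merge, keeping
#     the more extreme (tie -> earlier); skipped if the merge would delete a
#     protected point.
#   stage two (only when stage one cannot fire): leftmost excursion with
#     amplitude <= ME whose two points are unprotected; each member merges
#     with its like-kind neighbour across the excursion, keeping the more
#     extreme (tie -> earlier, absent neighbour -> member stays); skipped if
#     nothing would be deleted or a protected point would be.


def _turning_points_naive(values, offset):
    collapsed = []
    for k, v in enumerate(values):
        if not collapsed or v != collapsed[-1][1]:
            collapsed.append((offset + k, float(v)))
    if len(collapsed) < 2:
        return []
    pts = []
    last = len(collapsed) - 1
    for j, (slot, v) in enumerate(collapsed):
        if j == 0:
            kind = NADIR if collapsed[1][1] > v else PEAK
        elif j == last:
            kind = PEAK if v > collapsed[j - 1][1] else NADIR
        else:
            if collapsed[j - 1][1] < v and collapsed[j + 1][1] > v:
                continue
            if collapsed[j - 1][1] > v and collapsed[j + 1][1] < v:
                continue
            kind = PEAK if v > collapsed[j - 1][1] else NADIR
        pts.append((slot, v, kind))
    return pts


def _winner(a, b):
    """More extreme of two like-kind points; tie keeps the earlier (a)."""
    if a[2] == PEAK:
        return b if b[1] > a[1] else a
    return b if b[1] < a[1] else a


def _renormalize(pts):
    out = []
    for p in pts:
        while out and out[-1][2] == p[2]:
            p = _winner(out[-1], p)
            out.pop()
        out.append(p)
    return out


def _protected_naive(pts):
    prot = set()
    for i in range(2, len(pts) - 2):
        v, kind = pts[i][1], pts[i][2]
        left, right = pts[i - 2][1], pts[i + 2][1]
        if kind == PEAK and v < left and v < right:
            prot.add(i)
        if kind == NADIR and v > left and v > right:
            prot.add(i)
    return prot


def _amps(pts):
    return [abs(pts[i + 1][1] - pts[i][1]) for i in range(len(pts) - 1)]


def _stage_one_candidates(pts, me, prot):
    amps = _amps(pts)
    out = []
    for i in range(1, len(pts) - 1):
        if amps[i - 1] <= me and amps[i] <= me and i not in prot:
            keep = _winner(pts[i - 1], pts[i + 1])
            lose = i + 1 if keep is pts[i - 1] else i - 1
            if lose not in prot:
                out.append(i)
    return out


def _stage_two_candidates(pts, me, prot):
    amps = _amps(pts)
    out = []
    for i in range(len(pts) - 1):
        if amps[i] > me or i in prot or (i + 1) in prot:
            continue
        drop = _stage_two_drop(pts, i, prot)
        if drop:
            out.append(i)
    return out


def _stage_two_drop(pts, i, prot):
    drop = set()
    if i + 2 < len(pts):
        keep = _winner(pts[i], pts[i + 2])
        lose = i + 2 if keep is pts[i] else i
        if lose not in prot:
            drop.add(lose)
    if i - 1 >= 0:
        keep = _winner(pts[i - 1], pts[i + 1])
        lose = i + 1 if keep is pts[i - 1] else i - 1
        if lose not in prot:
            drop.add(lose)
    return drop


def _apply_stage_one(pts, i):
    return _renormalize(pts[:i] + pts[i + 1 :])


def _apply_stage_two(pts, i, prot):
    drop = _stage_two_drop(pts, i, prot)
    return _renormalize([p for j, p in enumerate(pts) if j not in drop])


def naive_prune(pts, me):
    """Leftmost-first rule application to a fixed point."""
    pts = _renormalize(list(pts))
    while True:
        prot = _protected_naive(pts)
        ones = _stage_one_candidates(pts, me, prot)
        if ones:
            pts = _apply_stage_one(pts, ones[0])
            continue
        twos = _stage_two_candidates(pts, me, prot)
        if twos:
            pts = _apply_stage_two(pts, twos[0], prot)
            continue
        return pts


def reachable_fixpoints(pts, me, limit=20000):
    """Every fixed point reachable by applying the rules in any order.

    Stage-two moves are only legal when no stage-one move exists (the rules
    are staged); within a stage any candidate may fire.  Exhaustive
    enumeration over deletion orders — the candidate retained curves.
    """
    seen = set()
    results = set()
    stack = [tuple(_renormalize(list(pts)))]
    while stack:
        if len(seen) > limit:
            raise RuntimeError("state space too large")
        state = stack.pop()
        if state in seen:
            continue
        seen.add(state)
        pts_l = list(state)
        prot = _protected_naive(pts_l)
        ones = _stage_one_candidates(pts_l, me, prot)
        if ones:
            for i in ones:
                stack.append(tuple(_apply_stage_one(pts_l, i)))
            continue
        twos = _stage_two_candidates(pts_l, me, prot)
        if twos:
            for i in twos:
                stack.append(tuple(_apply_stage_two(pts_l, i, prot)))
            continue
        results.add(state)
    return results


def _start_slot(values, me):
    g1 = values[0]
    if max(values) - g1 > me or g1 - min(values) > me:
        return 0
    pruned = naive_prune(_turning_points_naive(values, 0), me)
    if not any(a > me for a in _amps(pruned)):
        return 0
    first_max = values.index(max(values))
    first_min = values.index(min(values))
    return min(first_max, first_min)


def naive_mage(gridded, me=45.0):
    """Full naive MAGE: segments, start rule, prune, pooled amplitudes.

    Returns (mage_plus, mage_minus, mage_avg, excursion_frequency, alert).
    """
    ups, downs, sub_me = [], [], 0
    n = len(gridded.values)
    seg = []
    segments = []
    for k in range(n):
        if gridded.flags[k] != 2:
            seg.append(k)
        elif seg:
            segments.append(seg)
            seg = []
    if seg:
        segments.append(seg)
    for seg in segments:
        if len(seg) < 3:
            continue
        values = [float(gridded.values[k]) for k in seg]
        s = _start_slot(values, me)
        pts = naive_prune(_turning_points_naive(values[s:], seg[0] + s), me)
        for i in range(len(pts) - 1):
            amp = abs(pts[i + 1][1] - pts[i][1])
            if amp <= me:
                sub_me += 1
            elif pts[i][2] == NADIR:
                ups.append(amp)
            else:
                downs.append(amp)
    mage_plus = sum(ups) / len(ups) if ups else None
    mage_minus = sum(downs) / len(downs) if downs else None
    defined = [v for v in (mage_plus, mage_minus) if v is not None]
    mage_avg = sum(defined) / len(defined) if defined else None
    return mage_plus, mage_minus, mage_avg, len(ups) + len(downs), sub_me > 0
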