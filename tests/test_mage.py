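"""The modified turning-point MAGE algorithm, against oracles and hand traces."""

import numpy as np
import pytest

import glyvar as gv
from glyvar import Direction, PointKind

from conftest import make_gridded
import oracles


def sawtooth(n_half_cycles, amplitude, baseline=100.0, slots_per_half=4):
    """Triangle wave hitting its extremes exactly on grid slots."""
    half = np.linspace(0.0, amplitude, slots_per_half + 1)
    values = [baseline]
    for i in range(n_half_cycles):
        leg = half[1:] if i % 2 == 0 else half[::-1][1:]
        values.extend(baseline + leg)
    return np.array(values)


class TestFindTurningPoints:
    def test_monotone_series_yields_endpoints_only(self):
        points = gv.find_turning_points(make_gridded([100.0, 110.0, 120.0, 130.0]))
        assert [p.kind for p in points] == [PointKind.NADIR, PointKind.PEAK]
        assert [p.slot_index for p in points] == [0, 3]

    def test_sawtooth_four_teeth_has_nine_points(self):
        points = gv.find_turning_points(make_gridded(sawtooth(8, 60.0)))
        assert len(points) == 9
        kinds = [p.kind for p in points]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_plateau_collapses_to_first_slot(self):
        points = gv.find_turning_points(
            make_gridded([100.0, 120.0, 120.0, 120.0, 100.0])
        )
        peaks = [p for p in points if p.kind is PointKind.PEAK]
        assert len(peaks) == 1
        assert peaks[0].slot_index == 1

    def test_too_short_window_is_empty(self):
        assert gv.find_turning_points(make_gridded([100.0, 110.0])) == []

    def test_constant_window_is_empty(self):
        assert gv.find_turning_points(make_gridded([100.0] * 10)) == []


class TestPruneTurningPoints:
    def test_all_countable_input_unchanged(self):
        points = gv.find_turning_points(make_gridded(sawtooth(4, 80.0)))
        assert gv.prune_turning_points(points, me=45.0) == points

    def test_sub_me_dip_merged_into_single_rise(self):
        # up 60, down 20, up 60 with ME 45 -> one 100-up excursion
        gridded = make_gridded([100.0, 130.0, 160.0, 140.0, 170.0, 200.0])
        pruned = gv.prune_turning_points(gv.find_turning_points(gridded), me=45.0)
        excs = gv.mage.excursions_between(pruned)
        assert len(excs) == 1
        assert excs[0].direction is Direction.UP
        assert excs[0].amplitude == pytest.approx(100.0)

    def test_w_pattern_centre_retained(self):
        # high peaks flank a sub-ME middle peak: the W centre survives
        values = [200.0, 150.0, 100.0, 120.0, 95.0, 150.0, 200.0]
        pruned = gv.prune_turning_points(
            gv.find_turning_points(make_gridded(values)), me=45.0
        )
        assert 120.0 in [p.glucose for p in pruned]
        amps = [
            abs(b.glucose - a.glucose) for a, b in zip(pruned, pruned[1:])
        ]
        assert any(a <= 45.0 for a in amps)

    def test_retained_points_alternate(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            values = 140 + np.cumsum(rng.normal(0, 20, size=30))
            pruned = gv.prune_turning_points(
                gv.find_turning_points(make_gridded(values)), me=45.0
            )
            kinds = [p.kind for p in pruned]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestSelectStartPoint:
    def test_reachable_excursion_keeps_slot_zero(self):
        values = np.array([100.0, 120.0, 160.0, 100.0, 150.0])
        assert gv.select_start_point(make_gridded(values), me=45.0) == 0

    def test_start_moves_to_global_extremum(self):
        # neither max-G(t1) nor G(t1)-min exceeds ME, yet the curve holds an
        # ME between its maximum and minimum -> start at the earlier extremum
        values = np.array([140.0, 150.0, 160.0, 150.0, 120.0, 100.0, 130.0, 140.0])
        assert gv.select_start_point(make_gridded(values), me=45.0) == 2

    def test_minimum_first_when_it_precedes_maximum(self):
        values = np.array([140.0, 120.0, 100.0, 130.0, 160.0, 150.0, 140.0])
        assert gv.select_start_point(make_gridded(values), me=45.0) == 2

    def test_flat_series_keeps_slot_zero(self):
        values = np.array([100.0, 110.0, 105.0, 112.0, 100.0])
        assert gv.select_start_point(make_gridded(values), me=45.0) == 0


class TestBacktrackRecheck:
    def test_no_room_before_first_me_is_identity(self):
        gridded = make_gridded([100.0, 130.0, 160.0, 120.0])
        excs = gv.mage.excursions_between(
            gv.prune_turning_points(gv.find_turning_points(gridded), 45.0)
        )
        assert gv.backtrack_recheck(gridded, excs, me=45.0) == excs

    def test_hidden_dip_prepended_as_down_excursion(self):
        # a 50 mg/dL dip sits before the rise the caller detected first
        values = [150.0, 100.0, 140.0, 139.0, 141.0, 140.0, 200.0]
        gridded = make_gridded(values)
        first = gv.Excursion.between(
            gv.TurningPoint(5, 140.0, PointKind.NADIR),
            gv.TurningPoint(6, 200.0, PointKind.PEAK),
        )
        out = gv.backtrack_recheck(gridded, [first], me=45.0)
        assert len(out) == 2
        assert out[0].direction is Direction.DOWN
        assert out[0].amplitude == pytest.approx(50.0)
        assert out[1] == first

    def test_no_duplicate_point_pairs_when_overlapping_origin(self):
        values = [150.0, 100.0, 140.0, 139.0, 141.0, 140.0, 200.0]
        gridded = make_gridded(values)
        first = gv.Excursion.between(
            gv.TurningPoint(5, 140.0, PointKind.NADIR),
            gv.TurningPoint(6, 200.0, PointKind.PEAK),
        )
        out = gv.backtrack_recheck(gridded, [first], me=45.0)
        pairs = [(e.from_point.slot_index, e.to_point.slot_index) for e in out]
        assert len(pairs) == len(set(pairs))
        assert pairs == sorted(pairs)


class TestComputeMage:
    def test_sawtooth_60_six_half_cycles(self):
        result = gv.compute_mage(make_gridded(sawtooth(6, 60.0)), me=45.0)
        assert result.mage_plus == pytest.approx(60.0)
        assert result.mage_minus == pytest.approx(60.0)
        assert result.mage_avg == pytest.approx(60.0)
        assert result.excursion_frequency == 6

    def test_sub_threshold_sawtooth_undefined(self):
        result = gv.compute_mage(make_gridded(sawtooth(6, 40.0)), me=45.0)
        assert result.mage_plus is None
        assert result.mage_minus is None
        assert result.mage_avg is None
        assert result.excursion_frequency == 0

    def test_w_pattern_raises_visual_analysis_alert(self):
        values = [200.0, 150.0, 100.0, 120.0, 95.0, 150.0, 200.0]
        result = gv.compute_mage(make_gridded(values), me=45.0)
        assert result.alert_visual_analysis
        assert result.excursion_frequency == 2

    def test_one_sided_mage_avg_equals_the_defined_side(self):
        result = gv.compute_mage(make_gridded([100.0, 130.0, 160.0, 120.0]), me=45.0)
        assert result.mage_plus == pytest.approx(60.0)
        assert result.mage_minus is None
        assert result.mage_avg == pytest.approx(60.0)

    def test_all_countable_equals_naive_mean_of_amplitudes(self):
        rng = np.random.default_rng(4)
        # large alternating swings: every raw excursion exceeds ME
        peaks = 250 + rng.uniform(0, 40, size=6)
        nadirs = 80 + rng.uniform(0, 40, size=6)
        values = np.empty(12)
        values[0::2], values[1::2] = nadirs, peaks
        result = gv.compute_mage(make_gridded(values), me=45.0)
        ups = peaks - nadirs
        downs = peaks[:-1] - nadirs[1:]
        assert result.mage_plus == pytest.approx(np.mean(ups))
        assert result.mage_minus == pytest.approx(np.mean(downs))
        assert result.excursion_frequency == 11

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        values = 140 + np.cumsum(rng.normal(0, 18, size=60))
        values = np.clip(values, 40, 400)
        a = gv.compute_mage(make_gridded(values))
        b = gv.compute_mage(make_gridded(values + 25.0))
        assert a.mage_avg == b.mage_avg
        assert a.excursion_frequency == b.excursion_frequency

    def test_time_reversal_of_symmetric_sawtooth(self):
        values = sawtooth(6, 60.0)
        a = gv.compute_mage(make_gridded(values))
        b = gv.compute_mage(make_gridded(values[::-1].copy()))
        assert a.mage_avg == b.mage_avg
        assert a.excursion_frequency == b.excursion_frequency

    def test_long_gap_splits_into_pooled_segments(self):
        seg = sawtooth(2, 60.0)  # 9 slots, two 60-excursions
        values = np.concatenate([seg, [np.nan] * 25, seg + 40.0])
        result = gv.compute_mage(make_gridded(values), me=45.0)
        assert result.excursion_frequency == 4
        assert result.mage_avg == pytest.approx(60.0)

    def test_amplitudes_re_measurable_on_original_series(self):
        rng = np.random.default_rng(17)
        values = np.clip(140 + np.cumsum(rng.normal(0, 20, size=80)), 40, 400)
        gridded = make_gridded(values)
        result = gv.compute_mage(gridded)
        for p in result.retained_points:
            assert p.glucose == gridded.values[p.slot_index]
        for e in result.excursions:
            assert e.amplitude == pytest.approx(
                abs(gridded.values[e.to_point.slot_index]
                    - gridded.values[e.from_point.slot_index])
            )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_matches_naive_transcription_on_short_series(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 41))
        values = np.clip(140 + np.cumsum(rng.normal(0, 22, size=n)), 40, 400)
        gridded = make_gridded(values)
        result = gv.compute_mage(gridded, me=45.0)
        plus, minus, avg, ef, alert = oracles.naive_mage(gridded, me=45.0)
        for got, want in (
            (result.mage_plus, plus),
            (result.mage_minus, minus),
            (result.mage_avg, avg),
        ):
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-9)
        assert result.excursion_frequency == ef
        assert result.alert_visual_analysis == alert

    @pytest.mark.parametrize("seed", range(40))
    def test_retained_curve_reachable_by_any_rule_order(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(10, 31))
        values = np.clip(140 + np.cumsum(rng.normal(0, 22, size=n)), 40, 400)
        gridded = make_gridded(values)
        s = gv.select_start_point(gridded, 45.0)
        pruned = gv.prune_turning_points(
            gv.find_turning_points(gridded, start=s), 45.0
        )
        mine = tuple(
            (p.slot_index, p.glucose, p.kind.value) for p in pruned
        )
        raw = oracles._turning_points_naive(list(values[s:]), s)
        fixpoints = oracles.reachable_fixpoints(raw, 45.0)
        assert mine in fixpoints
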