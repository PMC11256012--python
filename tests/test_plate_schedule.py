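"""Scheduler: well addressing, concatenation patterns, timing, volumes."""

import pytest
from hypothesis import given, settings, strategies as st

from nanofrac.plate_schedule import (
    CollectionSchedule,
    PlateSpec,
    ScheduleError,
    ScheduleParams,
    WellAddress,
    assign_well,
    build_schedule,
    per_well_volume,
    well_to_xyz,
    write_schedule_csv,
)


def rotating_pointer_oracle(n_fractions: int, n_wells: int) -> list[int]:
    """Brute-force round-robin: a pointer that advances and wraps per fraction."""
    pointer, offsets = 0, []
    for _ in range(n_fractions):
        offsets.append(pointer)
        pointer = (pointer + 1) % n_wells
    return offsets


class TestAssignWell:
    def test_concatenation_scheme_pools_every_eighth_fraction(self):
        """8 wells x 5 pools: fractions 1,9,17,25,33 all land in the first well."""
        params = ScheduleParams(n_fractions=40, n_wells=8)
        for k in (1, 9, 17, 25, 33):
            assert assign_well(k, params) == WellAddress("A", 1)
        assert assign_well(2, params) == WellAddress("A", 2)
        assert assign_well(8, params) == WellAddress("A", 8)

    @pytest.mark.parametrize("pattern, n_wells", [
        ("roundrobin", 8), ("blocked", 8), ("identity", 40),
    ])
    def test_first_fraction_lands_in_start_well(self, pattern, n_wells):
        params = ScheduleParams(n_fractions=40, n_wells=n_wells, pattern=pattern)
        assert assign_well(1, params) == WellAddress("A", 1)

    def test_blocked_pattern_fills_contiguous_runs(self):
        params = ScheduleParams(n_fractions=40, n_wells=8, pattern="blocked")
        # fractions 1-5 -> well 0, 6-10 -> well 1, ...
        assert assign_well(6, params) == WellAddress("A", 2)
        assert assign_well(5, params) == WellAddress("A", 1)
        assert assign_well(40, params) == WellAddress("A", 8)

    def test_custom_map_followed_and_gaps_rejected(self):
        cmap = {1: WellAddress("B", 2), 2: WellAddress("C", 3)}
        params = ScheduleParams(n_fractions=3, n_wells=3, pattern="custom",
                                custom_map=cmap)
        assert assign_well(1, params) == WellAddress("B", 2)
        with pytest.raises(ScheduleError, match="custom_map"):
            assign_well(3, params)

    def test_out_of_range_fraction_rejected(self):
        params = ScheduleParams(n_fractions=40, n_wells=8)
        for bad in (0, 41, -1):
            with pytest.raises(ScheduleError):
                assign_well(bad, params)

    @settings(max_examples=100, derandomize=True)
    @given(n_fractions=st.integers(1, 500), n_wells=st.integers(1, 96))
    def test_roundrobin_matches_rotating_pointer(self, n_fractions, n_wells):
        n_wells = min(n_wells, n_fractions)
        params = ScheduleParams(n_fractions=n_fractions, n_wells=n_wells)
        plate = PlateSpec(n_rows=26, n_cols=12)  # generous plate for any offset
        oracle = rotating_pointer_oracle(n_fractions, n_wells)
        for k in range(1, n_fractions + 1):
            expected = WellAddress.from_linear(oracle[k - 1], plate)
            assert assign_well(k, params, plate) == expected

    def test_pointer_oracle_agreement_at_large_index(self):
        params = ScheduleParams(n_fractions=10_000, n_wells=7)
        plate = PlateSpec(n_rows=1, n_cols=7)
        oracle = rotating_pointer_oracle(10_000, 7)
        got = [assign_well(k, params, plate).col - 1 for k in range(1, 10_001)]
        assert got == oracle


class TestBuildSchedule:
    def test_default_run_matches_canonical_scheme(self, default_schedule):
        """40 one-minute fractions concatenated 5-deep into 8 wells."""
        assert len(default_schedule.events) == 40
        assert default_schedule.span_s == 2400.0
        counts = default_schedule.per_well_counts
        assert len(counts) == 8
        assert set(counts.values()) == {5}

    def test_single_event_schedule(self):
        sched = build_schedule(ScheduleParams(n_fractions=1, n_wells=1))
        assert len(sched.events) == 1
        ev = sched.events[0]
        assert (ev.t_start_s, ev.t_end_s) == (0.0, 60.0)

    def test_uneven_roundrobin_counts_favor_early_wells(self):
        sched = build_schedule(ScheduleParams(n_fractions=13, n_wells=4))
        counts = [sched.per_well_counts[w] for w in sched.wells_in_order]
        assert counts == [4, 3, 3, 3]

    def test_uneven_blocked_counts_balanced(self):
        sched = build_schedule(
            ScheduleParams(n_fractions=13, n_wells=4, pattern="blocked")
        )
        counts = [sched.per_well_counts[w] for w in sched.wells_in_order]
        assert counts == [4, 3, 3, 3]
        # contiguity: each well's events form one unbroken run
        for well in sched.wells_in_order:
            idx = [ev.index for ev in sched.events if ev.well == well]
            assert idx == list(range(idx[0], idx[0] + len(idx)))

    def test_events_contiguous_and_offset(self):
        sched = build_schedule(
            ScheduleParams(n_fractions=5, n_wells=5, interval_s=30.0,
                           start_offset_s=10.0)
        )
        assert sched.events[0].t_start_s == 10.0
        for a, b in zip(sched.events, sched.events[1:]):
            assert a.t_end_s == b.t_start_s
            assert b.t_end_s - b.t_start_s == 30.0

    def test_capacity_exceeded_raises(self):
        plate = PlateSpec(n_rows=2, n_cols=3)
        with pytest.raises(ScheduleError, match="capacity"):
            build_schedule(ScheduleParams(n_fractions=10, n_wells=7), plate)

    @settings(max_examples=100, derandomize=True)
    @given(
        n_fractions=st.integers(1, 200),
        n_wells=st.integers(1, 96),
        pattern=st.sampled_from(["roundrobin", "blocked"]),
    )
    def test_conservation_and_balance(self, n_fractions, n_wells, pattern):
        """Counts sum to n_fractions and never differ by more than 1."""
        n_wells = min(n_wells, n_fractions)
        plate = PlateSpec(n_rows=26, n_cols=12)
        sched = build_schedule(
            ScheduleParams(n_fractions=n_fractions, n_wells=n_wells, pattern=pattern),
            plate,
        )
        counts = sched.per_well_counts
        assert sum(counts.values()) == n_fractions
        assert len(counts) == n_wells
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ScheduleParams(n_fractions=0)
        with pytest.raises(ValueError):
            ScheduleParams(n_fractions=5, n_wells=6)
        with pytest.raises(ValueError):
            ScheduleParams(n_fractions=5, n_wells=4, pattern="identity")
        with pytest.raises(ValueError):
            ScheduleParams(interval_s=0)


class TestGeometry:
    def test_origin_well_maps_to_origin(self, plate):
        assert well_to_xyz(WellAddress("A", 1), plate) == (
            plate.origin_x_mm, plate.origin_y_mm, plate.liquid_surface_z_mm,
        )

    def test_pitch_offsets(self):
        plate = PlateSpec(origin_x_mm=10.0, origin_y_mm=20.0, pitch_mm=9.0)
        x, y, _ = well_to_xyz(WellAddress("C", 4), plate)
        assert (x, y) == (37.0, 38.0)

    def test_out_of_bounds_well_rejected(self, plate):
        with pytest.raises(ScheduleError):
            well_to_xyz(WellAddress("I", 13), plate)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 26), st.integers(1, 48), st.data())
    def test_linear_index_round_trip(self, n_rows, n_cols, data):
        plate = PlateSpec(n_rows=n_rows, n_cols=n_cols)
        idx = data.draw(st.integers(0, plate.n_wells - 1))
        well = WellAddress.from_linear(idx, plate)
        assert well.linear_index(plate) == idx

    def test_parse_labels(self):
        assert WellAddress.parse("c4") == WellAddress("C", 4)
        with pytest.raises(ValueError):
            WellAddress.parse("44")


class TestVolumes:
    def test_five_minutes_at_500_nl_min(self, default_schedule):
        """5 x 1 min pools at 500 nL/min collect 2.5 uL per well."""
        volumes, overflow = per_well_volume(default_schedule, 500.0)
        assert all(v == pytest.approx(2.5) for v in volumes.values())
        assert not overflow
        with_preload, _ = per_well_volume(
            default_schedule, 500.0, include_preload=True
        )
        assert all(v == pytest.approx(52.5) for v in with_preload.values())

    def test_overflow_flagged(self, default_schedule):
        # 5 min * 40 uL/min = 200 uL collected + 50 preload > 200 capacity
        _, overflow = per_well_volume(default_schedule, 40_000.0)
        assert overflow

    def test_nonpositive_flow_rejected(self, default_schedule):
        with pytest.raises(ValueError):
            per_well_volume(default_schedule, 0.0)


def test_schedule_csv_export(tmp_path, default_schedule):
    path = tmp_path / "schedule.csv"
    write_schedule_csv(default_schedule, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "fraction,row,col,t_start_s,t_end_s"
    assert lines[1] == "1,A,1,0,60"
    assert lines[9] == "9,A,1,480,540"  # fraction 9 pools back into A1
    assert len(lines) == 41
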