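"""Monitor-file parsing, serialization round-trips, and ZT/CT mapping."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circalam.lam_io import (
    ChannelSeries,
    CohortTable,
    LightSchedule,
    MonitorParseError,
    read_monitor_file,
    to_reference_time,
    write_monitor_file,
)

from conftest import START, make_series


def meta_frame(rows):
    return pd.DataFrame(rows, columns=["monitor_id", "channel", "individual_id", "insemination", "meal", "regimen", "is_control_tube"])


def write_raw(path, rows):
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def raw_rows(n, counts_by_channel, start=START):
    rows = []
    for i in range(n):
        ts = start + pd.Timedelta(minutes=i)
        row = [i + 1, f"{ts.day} {ts.strftime('%b %y')}", ts.strftime("%H:%M:%S"), 1]
        row += [counts_by_channel.get(ch, [0] * n)[i] for ch in range(1, 33)]
        rows.append(row)
    return rows


class TestReadMonitorFile:
    def test_known_payload_round_trips_exactly(self, tmp_path, ld_schedule):
        """A hand-written 3-row, 2-channel payload parses to the exact count matrix."""
        payload = {1: [3, 0, 7], 2: [1, 2, 5]}
        path = tmp_path / "Monitor01.txt"
        write_raw(path, raw_rows(3, payload))
        meta = meta_frame(
            [["Monitor01", 1, "a", "virgin", "glucose", "LD", False], ["Monitor01", 2, "b", "virgin", "glucose", "LD", False]]
        )
        cohort = read_monitor_file(path, meta, ld_schedule)
        assert len(cohort) == 2
        assert cohort["a"].counts.tolist() == payload[1]
        assert cohort["b"].counts.tolist() == payload[2]
        assert cohort["a"].start == START
        assert cohort["a"].meta["meal"] == "glucose"

    def test_seven_day_file_has_10080_minute_counts(self, tmp_path, ld_schedule):
        n = 7 * 1440
        path = tmp_path / "Monitor01.txt"
        write_raw(path, raw_rows(n, {1: [1] * n}))
        meta = meta_frame([["Monitor01", 1, "a", "virgin", "glucose", "LD", False]])
        cohort = read_monitor_file(path, meta, ld_schedule)
        assert len(cohort["a"]) == 10080
        assert cohort["a"].n_days == 7

    def test_missing_minute_is_gap_error_naming_timestamp(self, tmp_path, ld_schedule):
        rows = raw_rows(5, {1: [1] * 5})
        del rows[2]  # drop 00:02
        path = tmp_path / "Monitor01.txt"
        write_raw(path, rows)
        meta = meta_frame([["Monitor01", 1, "a", "virgin", "glucose", "LD", False]])
        with pytest.raises(MonitorParseError, match="00:02"):
            read_monitor_file(path, meta, ld_schedule)

    def test_duplicate_timestamp_is_error(self, tmp_path, ld_schedule):
        rows = raw_rows(4, {1: [1] * 4})
        rows[2] = rows[1]
        path = tmp_path / "Monitor01.txt"
        write_raw(path, rows)
        meta = meta_frame([["Monitor01", 1, "a", "virgin", "glucose", "LD", False]])
        with pytest.raises(MonitorParseError, match="duplicate"):
            read_monitor_file(path, meta, ld_schedule)

    def test_malformed_row_error_carries_line_number(self, tmp_path, ld_schedule):
        rows = raw_rows(3, {1: [1, 1, 1]})
        rows[1][5] = "oops"
        path = tmp_path / "Monitor01.txt"
        write_raw(path, rows)
        meta = meta_frame([["Monitor01", 1, "a", "virgin", "glucose", "LD", False]])
        with pytest.raises(MonitorParseError, match=":2:"):
            read_monitor_file(path, meta, ld_schedule)

    def test_unmapped_active_channel_warns_and_skips(self, tmp_path, ld_schedule):
        path = tmp_path / "Monitor01.txt"
        write_raw(path, raw_rows(3, {1: [1, 1, 1], 5: [2, 2, 2]}))
        meta = meta_frame([["Monitor01", 1, "a", "virgin", "glucose", "LD", False]])
        with pytest.warns(UserWarning, match="channel 5"):
            cohort = read_monitor_file(path, meta, ld_schedule)
        assert [s.individual_id for s in cohort] == ["a"]

    def test_control_channel_is_retained_and_flagged(self, tmp_path, ld_schedule):
        path = tmp_path / "Monitor01.txt"
        write_raw(path, raw_rows(3, {1: [1, 1, 1]}))
        meta = meta_frame(
            [["Monitor01", 1, "a", "virgin", "glucose", "LD", False], ["Monitor01", 31, "ctrl", "", "", "LD", True]]
        )
        cohort = read_monitor_file(path, meta, ld_schedule)
        assert cohort["ctrl"].is_control_tube
        assert not cohort["a"].is_control_tube

    def test_column_sums_conserved_by_parsing(self, tmp_path, ld_schedule):
        rng = np.random.default_rng(0)
        payload = {ch: rng.poisson(2, 50).tolist() for ch in (1, 2, 3)}
        path = tmp_path / "Monitor01.txt"
        write_raw(path, raw_rows(50, payload))
        meta = meta_frame([["Monitor01", ch, f"i{ch}", "virgin", "glucose", "LD", False] for ch in (1, 2, 3)])
        cohort = read_monitor_file(path, meta, ld_schedule)
        for ch in (1, 2, 3):
            assert cohort[f"i{ch}"].counts.sum() == sum(payload[ch])


class TestWriteMonitorFile:
    def test_write_then_read_is_identity(self, tmp_path, ld_schedule):
        rng = np.random.default_rng(1)
        series = [make_series(rng.poisson(1, 60), individual_id=f"i{c}", channel=c) for c in (1, 4, 9)]
        path = tmp_path / "M01.txt"
        write_monitor_file(series, path)
        meta = meta_frame([["M01", c, f"i{c}", "virgin", "glucose", "LD", False] for c in (1, 4, 9)])
        back = read_monitor_file(path, meta, ld_schedule)
        for s in series:
            np.testing.assert_array_equal(back[s.individual_id].counts, s.counts)
            assert back[s.individual_id].start == s.start

    def test_reserialization_is_byte_identical(self, tmp_path, ld_schedule):
        rng = np.random.default_rng(2)
        series = [make_series(rng.poisson(1, 30), individual_id=f"i{c}", channel=c) for c in (1, 2)]
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_monitor_file(series, p1)
        meta = meta_frame([["M01", c, f"i{c}", "virgin", "glucose", "LD", False] for c in (1, 2)])
        back = read_monitor_file(p1, meta, ld_schedule, monitor_id="M01")
        write_monitor_file(sorted(back.series, key=lambda s: s.channel), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_cohort_writes_empty_file(self, tmp_path, ld_schedule):
        path = tmp_path / "empty.txt"
        write_monitor_file(CohortTable(series=[], schedule=ld_schedule), path)
        assert path.read_text() == ""

    def test_more_than_32_series_is_error(self, tmp_path):
        series = [make_series([0], individual_id=f"i{k}", channel=(k % 32) + 1) for k in range(33)]
        with pytest.raises(ValueError, match="32"):
            write_monitor_file(series, tmp_path / "x.txt")


class TestReferenceTime:
    @pytest.mark.parametrize(
        "clock,expected",
        [(dt.time(18, 0), 0.0), (dt.time(6, 0), 12.0), (dt.time(19, 30), 1.5), (dt.time(0, 0), 6.0)],
    )
    def test_lights_off_anchor_convention(self, ld_schedule, clock, expected):
        """ZT0 is lights-off at 18:00; lights-on at 06:00 is ZT12."""
        assert to_reference_time(clock, ld_schedule) == pytest.approx(expected)

    def test_anchor_switch_flips_convention(self):
        sch = LightSchedule(zt_anchor="lights_on")
        assert to_reference_time(dt.time(6, 0), sch) == pytest.approx(0.0)
        assert to_reference_time(dt.time(18, 0), sch) == pytest.approx(12.0)

    @given(st.floats(min_value=0.0, max_value=200.0))
    @settings(deadline=None, max_examples=50)
    def test_periodic_modulo_24h(self, clock_h):
        sch = LightSchedule()
        assert to_reference_time(clock_h, sch) == pytest.approx(to_reference_time(clock_h + 24.0, sch), abs=1e-9)

    def test_vectorised_over_datetime_index(self, ld_schedule):
        idx = pd.date_range("2021-01-04 18:00", periods=3, freq="6h")
        np.testing.assert_allclose(to_reference_time(idx, ld_schedule), [0.0, 6.0, 12.0])


class TestInvariants:
    def test_schedule_ramps_must_fit_inside_spans(self):
        # a 30-min photophase cannot hold a 60-min dusk ramp
        with pytest.raises(ValueError, match="24 h"):
            LightSchedule(lights_off=dt.time(6, 30))

    def test_dd_keeps_nominal_anchors(self, dd_schedule):
        assert to_reference_time(dt.time(18, 0), dd_schedule) == 0.0

    def test_duplicate_individual_ids_rejected(self, ld_schedule):
        with pytest.raises(ValueError, match="duplicate"):
            CohortTable(series=[make_series([1]), make_series([1])], schedule=ld_schedule)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_series([1, -1])

    def test_step_must_divide_day(self):
        with pytest.raises(ValueError, match="86400"):
            make_series([1, 2], step=7)
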