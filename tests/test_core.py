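"""Calendar, dosing-window and timezone-policy behavior."""

from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adherekit import (
    Channel,
    DoseEvent,
    StudyConfig,
    TravelInterval,
    TzPolicy,
    classify_timing,
    dosing_window,
    localize,
    phase_of_day,
    study_day,
)
from adherekit.core import (
    ConfigError,
    OutOfStudyError,
    TimingClass,
    clock_distance_minutes,
    is_on_time,
)

from conftest import HOME_TZ, make_event

CFG = StudyConfig(start_date=date(2018, 3, 1), goal_time=time(8, 0),
                  home_timezone=HOME_TZ)


class TestStudyDay:
    def test_first_day(self, config):
        assert study_day(make_event(config, 1, 8, 0), config) == 1

    def test_last_day(self, config):
        assert study_day(make_event(config, 52, 8, 0), config) == 52

    def test_midnight_boundary(self, config):
        assert study_day(make_event(config, 1, 23, 59), config) == 1
        assert study_day(make_event(config, 2, 0, 1), config) == 2

    def test_before_start_raises(self, config):
        early = DoseEvent(
            "P1", Channel.BUTTON,
            datetime(2018, 2, 28, 12, 0, tzinfo=ZoneInfo(HOME_TZ)), "BTN-P1",
        )
        with pytest.raises(OutOfStudyError):
            study_day(early, config)

    def test_after_horizon_flagged_not_dropped(self, config):
        late = localize(make_event(config, 53, 8, 0), config)
        assert late.study_day == 53
        assert not late.in_study


class TestPhases:
    @pytest.mark.parametrize("day,phase", [(1, 1), (14, 1), (15, 2), (45, 2),
                                           (46, 3), (52, 3)])
    def test_boundaries(self, config, day, phase):
        assert phase_of_day(day, config) == phase

    @pytest.mark.parametrize("day", [0, 53, -1])
    def test_out_of_range(self, config, day):
        with pytest.raises(ValueError):
            phase_of_day(day, config)

    @given(st.data())
    @settings(deadline=None, max_examples=50)
    def test_partition_property(self, data):
        """Every day of any valid config belongs to exactly one phase."""
        n_days = data.draw(st.integers(2, 120))
        n_cuts = data.draw(st.integers(0, min(4, n_days - 1)))
        cuts = sorted(data.draw(st.sets(st.integers(1, n_days - 1),
                                        min_size=n_cuts, max_size=n_cuts)))
        bounds, first = [], 1
        for i, c in enumerate(cuts + [n_days]):
            bounds.append((i + 1, first, c))
            first = c + 1
        cfg = StudyConfig(
            start_date=date(2018, 3, 1), goal_time=time(8, 0),
            home_timezone="UTC", n_days=n_days, phase_bounds=tuple(bounds),
        )
        phases = [phase_of_day(d, cfg) for d in range(1, n_days + 1)]
        for pid, lo, hi in bounds:
            assert all(p == pid for p in phases[lo - 1:hi])

    def test_gap_rejected(self):
        with pytest.raises(ConfigError):
            StudyConfig(
                start_date=date(2018, 3, 1), goal_time=time(8, 0),
                home_timezone="UTC", n_days=10,
                phase_bounds=((1, 1, 4), (2, 6, 10)),
            )


class TestDosingWindow:
    def test_quarter_interval_is_three_hours(self, config):
        w = dosing_window(config)
        assert w.half_width_hours == 3.0
        assert (w.lower, w.upper) == (time(5, 0), time(11, 0))

    def test_full_window_degenerate(self, config):
        from dataclasses import replace
        w = dosing_window(replace(config, window_fraction=1.0))
        assert w.half_width_hours == 12.0

    def test_wraps_midnight(self):
        cfg = StudyConfig(start_date=date(2018, 3, 1), goal_time=time(1, 0),
                          home_timezone="UTC")
        w = dosing_window(cfg)
        assert (w.lower, w.upper) == (time(22, 0), time(4, 0))

    def test_minute_enumeration_oracle_wrapped_window(self):
        """Goal 01:00, ±3 h: exactly 361 minute marks classify on-time."""
        cfg = StudyConfig(start_date=date(2018, 3, 1), goal_time=time(1, 0),
                          home_timezone="UTC")
        on = [m for m in range(24 * 60) if is_on_time(time(m // 60, m % 60), cfg)]
        assert len(on) == 361
        # the on-time set is exactly [22:00, 23:59] u [00:00, 04:00]
        assert set(on) == set(range(22 * 60, 24 * 60)) | set(range(0, 4 * 60 + 1))

    @given(frac=st.floats(0.01, 1.0), interval=st.floats(1.0, 48.0))
    @settings(deadline=None, max_examples=100)
    def test_half_width_linear(self, frac, interval):
        cfg = StudyConfig(start_date=date(2018, 3, 1), goal_time=time(8, 0),
                          home_timezone="UTC", dosing_interval_hours=interval,
                          window_fraction=frac)
        assert dosing_window(cfg).half_width_hours == pytest.approx(
            frac * interval / 2
        )

    def test_circular_distance(self):
        assert clock_distance_minutes(time(23, 30), time(1, 0)) == 90.0
        assert clock_distance_minutes(time(8, 0), time(8, 0)) == 0.0


class TestTimingClassification:
    @pytest.mark.parametrize("hh,mm,expected", [
        (10, 59, TimingClass.ON_TIME),
        (11, 0, TimingClass.ON_TIME),   # closed interval: boundary on time
        (11, 1, TimingClass.OUTSIDE_TIME),
        (5, 0, TimingClass.ON_TIME),
        (4, 59, TimingClass.OUTSIDE_TIME),
    ])
    def test_window_edges(self, config, hh, mm, expected):
        ev = localize(make_event(config, 20, hh, mm), config)
        assert classify_timing(ev, config) == expected


class TestLocalize:
    def test_policies_coincide_without_travel(self, config):
        ev = make_event(config, 10, 9, 30)
        a = localize(ev, config, TzPolicy.PARTICIPANT_LOCAL)
        b = localize(ev, config, TzPolicy.FIXED_SERVER)
        assert (a.study_day, a.local_time) == (b.study_day, b.local_time)

    @given(day=st.integers(1, 52), minute=st.integers(0, 24 * 60 - 1))
    @settings(deadline=None, max_examples=100)
    def test_policies_coincide_property(self, day, minute):
        config = CFG
        ev = make_event(config, day, minute // 60, minute % 60)
        a = localize(ev, config, TzPolicy.PARTICIPANT_LOCAL)
        b = localize(ev, config, TzPolicy.FIXED_SERVER)
        assert (a.study_day, a.local_time, a.effective_timezone) == (
            b.study_day, b.local_time, b.effective_timezone)

    def test_travel_failure_mode(self):
        """A goal-time press while travelled 5 h ahead is on-time under the
        participant-local policy but misclassified under the server zone."""
        cfg = StudyConfig(
            start_date=date(2018, 3, 1), goal_time=time(8, 0),
            home_timezone="Etc/GMT+5",  # fixed UTC-5
            travel_log=(TravelInterval(20, 27, "Etc/GMT"),),  # 5 h ahead
        )
        ev = make_event(cfg, 22, 8, 0, tz="Etc/GMT")
        local = localize(ev, cfg, TzPolicy.PARTICIPANT_LOCAL)
        server = localize(ev, cfg, TzPolicy.FIXED_SERVER)
        assert classify_timing(local, cfg) == TimingClass.ON_TIME
        assert classify_timing(server, cfg) == TimingClass.OUTSIDE_TIME
        assert local.effective_timezone == "Etc/GMT"
        assert server.effective_timezone == "Etc/GMT+5"

    def test_override_applies_whole_day(self):
        cfg = StudyConfig(
            start_date=date(2018, 3, 1), goal_time=time(8, 0),
            home_timezone="Etc/GMT+5",
            travel_log=(TravelInterval(20, 27, "Etc/GMT"),),
        )
        # one minute into the first travel day, travel-zone clock
        ev = make_event(cfg, 20, 0, 1, tz="Etc/GMT")
        loc = localize(ev, cfg, TzPolicy.PARTICIPANT_LOCAL)
        assert loc.study_day == 20
        assert loc.effective_timezone == "Etc/GMT"

    @given(day=st.integers(1, 52), minute=st.integers(0, 24 * 60 - 1),
           render_tz=st.sampled_from(["UTC", "Asia/Tokyo", "Etc/GMT-9",
                                      "America/Los_Angeles"]))
    @settings(deadline=None, max_examples=100)
    def test_representation_invariance(self, day, minute, render_tz):
        """Re-expressing the same instant in another offset never changes
        the classification."""
        config = CFG
        ev = make_event(config, day, minute // 60, minute % 60)
        shifted = DoseEvent(
            ev.participant_id, ev.channel,
            ev.timestamp.astimezone(ZoneInfo(render_tz)), ev.device_uid,
        )
        a = localize(ev, config)
        b = localize(shifted, config)
        assert classify_timing(a, config) == classify_timing(b, config)
        assert a.study_day == b.study_day

    def test_unknown_timezone_rejected(self):
        with pytest.raises(ConfigError):
            StudyConfig(start_date=date(2018, 3, 1), goal_time=time(8, 0),
                        home_timezone="Mars/Olympus")


class TestConfigValidation:
    def test_travel_overlap_rejected(self):
        with pytest.raises(ConfigError):
            StudyConfig(
                start_date=date(2018, 3, 1), goal_time=time(8, 0),
                home_timezone="UTC",
                travel_log=(TravelInterval(5, 10, "UTC"),
                            TravelInterval(8, 12, "UTC")),
            )

    def test_travel_outside_horizon_rejected(self):
        with pytest.raises(ConfigError):
            StudyConfig(
                start_date=date(2018, 3, 1), goal_time=time(8, 0),
                home_timezone="UTC",
                travel_log=(TravelInterval(50, 60, "UTC"),),
            )

    def test_naive_timestamp_rejected(self):
        with pytest.raises(ValueError):
            DoseEvent("P1", Channel.BUTTON, datetime(2018, 3, 1, 8, 0), "u")
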