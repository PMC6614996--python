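"""Domain types and calendar/timing arithmetic for a once-daily dosing study.

The study is a fixed horizon of ``n_days`` consecutive local calendar days,
partitioned into consecutive phases. Each participant has a goal clock time
for the daily dose and an on-time window of half-width
``window_fraction * dosing_interval_hours / 2`` centred on it (the classic
"within 25% of the dosing interval" rule: 24 h interval, fraction 0.25 gives
a ±3 h window).

Every timestamp is an absolute instant carrying a UTC offset. A participant's
*effective* timezone on a given study day is the home timezone unless a
travel-log entry covers that day. Day boundaries are participant-local
midnight; timezone overrides apply per whole local calendar day.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

__all__ = [
    "Channel",
    "TzPolicy",
    "TimingClass",
    "TravelInterval",
    "StudyConfig",
    "DoseEvent",
    "LocalizedEvent",
    "DosingWindow",
    "ConfigError",
    "OutOfStudyError",
    "study_day",
    "phase_of_day",
    "phase_first_day",
    "phase_length",
    "dosing_window",
    "clock_distance_minutes",
    "is_on_time",
    "localize",
]

SECONDS_PER_DAY = 86_400.0


class ConfigError(ValueError):
    """Invalid study configuration (bad phases, timezone, window…)."""


class OutOfStudyError(ValueError):
    """Event falls before the study start date."""


class Channel(str, enum.Enum):
    """Which physical device produced an event."""

    BUTTON = "button"
    CAP = "cap"


class TzPolicy(str, enum.Enum):
    """How the server renders an instant into participant clock time.

    ``PARTICIPANT_LOCAL`` uses the travel-aware effective timezone — the
    correct behavior. ``FIXED_SERVER`` always uses the home/server timezone,
    reproducing the deployed system's failure mode when a participant
    travels across timezones (useful for testing that mismatch).
    """

    PARTICIPANT_LOCAL = "participant_local"
    FIXED_SERVER = "fixed_server"


class TimingClass(str, enum.Enum):
    ON_TIME = "on_time"
    OUTSIDE_TIME = "outside_time"
    NOT_APPLICABLE = "not_applicable"


def _check_tz(name: str) -> None:
    try:
        ZoneInfo(name)
    except Exception as exc:  # KeyError or ZoneInfoNotFoundError
        raise ConfigError(f"unknown IANA timezone: {name!r}") from exc


@dataclass(frozen=True)
class TravelInterval:
    """Whole-day timezone override: days ``first_day..last_day`` inclusive."""

    first_day: int
    last_day: int
    timezone: str

    def __post_init__(self) -> None:
        if self.first_day > self.last_day:
            raise ConfigError("travel interval has first_day > last_day")
        _check_tz(self.timezone)

    def covers(self, day: int) -> bool:
        return self.first_day <= day <= self.last_day


DEFAULT_PHASES: tuple[tuple[int, int, int], ...] = ((1, 1, 14), (2, 15, 45), (3, 46, 52))


@dataclass(frozen=True)
class StudyConfig:
    """Study calendar, dosing schedule and timezone information.

    Parameters
    ----------
    start_date:
        Local calendar date of study day 1.
    goal_time:
        Participant's scheduled daily dose time (local clock).
    home_timezone:
        IANA name of the participant's home timezone (also the server zone
        under the ``FIXED_SERVER`` policy).
    n_days:
        Study horizon in days (default 52).
    phase_bounds:
        ``(phase_id, first_day, last_day)`` triples partitioning 1..n_days.
    dosing_interval_hours:
        Scheduled time between doses (24 for once daily).
    window_fraction:
        On-time window width as a fraction of the dosing interval, in (0, 1].
    travel_log:
        Whole-day timezone overrides; intervals must not overlap.
    """

    start_date: date
    goal_time: time
    home_timezone: str
    n_days: int = 52
    phase_bounds: tuple[tuple[int, int, int], ...] = DEFAULT_PHASES
    dosing_interval_hours: float = 24.0
    window_fraction: float = 0.25
    travel_log: tuple[TravelInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigError("n_days must be positive")
        _check_tz(self.home_timezone)
        self._validate_phases()
        if self.dosing_interval_hours <= 0:
            raise ConfigError("dosing_interval_hours must be positive")
        if not (0 < self.window_fraction <= 1):
            raise ConfigError("window_fraction must be in (0, 1]")
        half = self.window_fraction * self.dosing_interval_hours / 2
        if not (0 < half <= self.dosing_interval_hours / 2):
            raise ConfigError("window half-width must be in (0, interval/2]")
        self._validate_travel()

    def _validate_phases(self) -> None:
        if not self.phase_bounds:
            raise ConfigError("phase_bounds must be non-empty")
        expected_first = 1
        seen: set[int] = set()
        for pid, first, last in self.phase_bounds:
            if pid in seen:
                raise ConfigError(f"duplicate phase id {pid}")
            seen.add(pid)
            if first != expected_first:
                raise ConfigError("phase_bounds must partition 1..n_days with no gaps")
            if last < first:
                raise ConfigError("phase with last_day < first_day")
            expected_first = last + 1
        if expected_first != self.n_days + 1:
            raise ConfigError("phase_bounds must end exactly at n_days")

    def _validate_travel(self) -> None:
        intervals = sorted(self.travel_log, key=lambda t: t.first_day)
        prev_last = 0
        for iv in intervals:
            if iv.first_day < 1 or iv.last_day > self.n_days:
                raise ConfigError("travel interval outside 1..n_days")
            if iv.first_day <= prev_last:
                raise ConfigError("travel intervals overlap")
            prev_last = iv.last_day

    def effective_timezone(self, day: int) -> str:
        """Timezone in force on a given study day (travel-aware)."""
        for iv in self.travel_log:
            if iv.covers(day):
                return iv.timezone
        return self.home_timezone

    def with_travel(self, travel_log: tuple[TravelInterval, ...]) -> "StudyConfig":
        return replace(self, travel_log=travel_log)


@dataclass(frozen=True)
class DoseEvent:
    """One timestamped event from one device channel for one participant."""

    participant_id: str
    channel: Channel
    timestamp: datetime
    device_uid: str

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None or self.timestamp.utcoffset() is None:
            raise ValueError("DoseEvent timestamp must carry a UTC offset")


@dataclass(frozen=True)
class LocalizedEvent:
    """A dose event rendered into the participant's effective timezone.

    ``in_study`` is False for events after day ``n_days`` — such events are
    retained but flagged, since participants are known to keep using the
    devices past the formal study end.
    """

    source: DoseEvent
    study_day: int
    local_time: time
    effective_timezone: str
    in_study: bool = True

    @property
    def participant_id(self) -> str:
        return self.source.participant_id

    @property
    def channel(self) -> Channel:
        return self.source.channel

    @property
    def instant(self) -> datetime:
        return self.source.timestamp

    @property
    def local_datetime(self) -> datetime:
        return self.source.timestamp.astimezone(ZoneInfo(self.effective_timezone))


@dataclass(frozen=True)
class DosingWindow:
    half_width_hours: float
    lower: time  # goal - half-width, possibly on the previous local day
    upper: time  # goal + half-width, possibly on the next local day


def _day_in_tz(instant: datetime, tz: str, start: date) -> int:
    local = instant.astimezone(ZoneInfo(tz))
    return (local.date() - start).days + 1


def _resolve_day_and_tz(
    instant: datetime, config: StudyConfig, policy: TzPolicy
) -> tuple[int, str]:
    """Resolve (study_day, effective timezone) for one instant.

    The travel log is keyed by study day while the study day depends on the
    timezone, so near a travel boundary an instant can be consistent with
    two (day, zone) readings. A reading is *consistent* when rendering the
    instant in the zone in force on the candidate day lands on that day.
    Travel-consistent readings win (the override zone governs its whole
    local calendar day); otherwise the home-zone day stands.
    """
    home = config.home_timezone
    d_home = _day_in_tz(instant, home, config.start_date)
    if policy is TzPolicy.FIXED_SERVER:
        return d_home, home
    for cand in (d_home - 1, d_home, d_home + 1):
        tz = config.effective_timezone(cand) if cand >= 1 else home
        if tz != home and _day_in_tz(instant, tz, config.start_date) == cand:
            return cand, tz
    return d_home, home


def study_day(
    event: DoseEvent, config: StudyConfig, policy: TzPolicy = TzPolicy.PARTICIPANT_LOCAL
) -> int:
    """1-based study day of an event; boundary is local midnight.

    Raises :class:`OutOfStudyError` for events before the start date. Events
    after day ``n_days`` return their (valid) day index; callers decide how
    to flag them.
    """
    day, _ = _resolve_day_and_tz(event.timestamp, config, policy)
    if day < 1:
        raise OutOfStudyError(
            f"event at {event.timestamp.isoformat()} precedes study start {config.start_date}"
        )
    return day


def localize(
    event: DoseEvent, config: StudyConfig, policy: TzPolicy = TzPolicy.PARTICIPANT_LOCAL
) -> LocalizedEvent:
    """Render an event into participant clock time under a timezone policy."""
    day, tz = _resolve_day_and_tz(event.timestamp, config, policy)
    if day < 1:
        raise OutOfStudyError(
            f"event at {event.timestamp.isoformat()} precedes study start {config.start_date}"
        )
    local = event.timestamp.astimezone(ZoneInfo(tz))
    return LocalizedEvent(
        source=event,
        study_day=day,
        local_time=local.time(),
        effective_timezone=tz,
        in_study=day <= config.n_days,
    )


def phase_of_day(day: int, config: StudyConfig) -> int:
    """Phase id containing a study day; raises for days outside 1..n_days."""
    if not 1 <= day <= config.n_days:
        raise ValueError(f"day {day} outside 1..{config.n_days}")
    for pid, first, last in config.phase_bounds:
        if first <= day <= last:
            return pid
    raise AssertionError("phase bounds do not cover day despite validation")


def phase_first_day(phase_id: int, config: StudyConfig) -> int:
    for pid, first, _ in config.phase_bounds:
        if pid == phase_id:
            return first
    raise ValueError(f"unknown phase {phase_id}")


def phase_length(phase_id: int, config: StudyConfig) -> int:
    for pid, first, last in config.phase_bounds:
        if pid == phase_id:
            return last - first + 1
    raise ValueError(f"unknown phase {phase_id}")


def dosing_window(config: StudyConfig) -> DosingWindow:
    """On-time window around the goal time, wrapping across midnight."""
    half_hours = config.window_fraction * config.dosing_interval_hours / 2
    half = timedelta(hours=half_hours)
    anchor = datetime(2000, 1, 1, config.goal_time.hour, config.goal_time.minute,
                      config.goal_time.second)
    return DosingWindow(
        half_width_hours=half_hours,
        lower=(anchor - half).time(),
        upper=(anchor + half).time(),
    )


def _seconds_of(t: time) -> float:
    return t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6


def clock_distance_minutes(a: time, b: time) -> float:
    """Minimal circular distance between two clock times, in minutes.

    On a 24 h clock a 23:30 press against a 01:00 goal is 1.5 h early, not
    22.5 h late.
    """
    d = abs(_seconds_of(a) - _seconds_of(b))
    return min(d, SECONDS_PER_DAY - d) / 60.0


def is_on_time(local_time: time, config: StudyConfig) -> bool:
    """Closed-interval on-time test: |t - goal| <= half-width (circular)."""
    half_minutes = config.window_fraction * config.dosing_interval_hours * 60 / 2
    return clock_distance_minutes(local_time, config.goal_time) <= half_minutes


def classify_timing(event: LocalizedEvent, config: StudyConfig) -> TimingClass:
    """On-time / outside-time classification of a localized event."""
    if is_on_time(event.local_time, config):
        return TimingClass.ON_TIME
    return TimingClass.OUTSIDE_TIME
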