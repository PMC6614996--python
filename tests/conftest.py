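from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

import pytest

from adherekit import Channel, DoseEvent, StudyConfig, localize

HOME_TZ = "America/Indiana/Indianapolis"


def make_event(config, day, hh, mm, channel=Channel.BUTTON, pid="P1",
               uid=None, tz=None, second=0):
    """Build a DoseEvent on a given study day at a local wall-clock time."""
    tzname = tz or config.effective_timezone(day)
    d = config.start_date + timedelta(days=day - 1)
    ts = datetime(d.year, d.month, d.day, hh, mm, second,
                  tzinfo=ZoneInfo(tzname))
    if uid is None:
        uid = f"{'BTN' if channel is Channel.BUTTON else 'CAP'}-{pid}"
    return DoseEvent(pid, channel, ts, uid)


def localized(config, day, hh, mm, channel=Channel.BUTTON, pid="P1", tz=None,
              second=0):
    return localize(make_event(config, day, hh, mm, channel, pid, tz=tz,
                               second=second), config)


@pytest.fixture
def config():
    """Default 52-day once-daily study, goal 08:00, no travel."""
    return StudyConfig(
        start_date=date(2018, 3, 1),
        goal_time=time(8, 0),
        home_timezone=HOME_TZ,
    )
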