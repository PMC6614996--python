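"""Synthetic paired button/cap event streams under a stated behavior model.

Each study day, independently: the participant takes the dose with
probability ``p_dose`` at the goal time plus Gaussian jitter (truncated so
the dose instant stays within the local day). A dose always produces a cap
opening. Given a dose, the button is pressed with probability
``p_press_given_dose``, and a press reaches the server with probability
``p_press_received`` (the companion app being closed is the dominant loss
mechanism in this kind of deployment). A received press is logged at the
dose instant plus a lag drawn from a mixture: usually within a couple of
minutes, occasionally a heavy-tailed delay of hours (a participant
remembering to press much later), with a fraction of tail lags negative
(press before opening the bottle).

Default parameters reproduce the completeness rates of a 5-participant,
52-day once-daily feasibility deployment: cap completeness 76.2% and button
completeness 36.5% (press-through 0.479 given a dose).

All randomness flows through an explicit seed; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping
from zoneinfo import ZoneInfo

import numpy as np

from .core import Channel, DoseEvent, StudyConfig, TravelInterval

__all__ = [
    "PressLag",
    "ZERO_LAG",
    "BehaviorParams",
    "DayTruth",
    "SimulatedParticipant",
    "simulate_participant",
    "simulate_cohort",
    "feasibility_cohort_params",
    "DEFAULT_P_DOSE",
    "DEFAULT_PRESS_THROUGH",
]

DEFAULT_P_DOSE = 0.762
DEFAULT_PRESS_THROUGH = 0.479  # p_press_given_dose * p_press_received


@dataclass(frozen=True)
class PressLag:
    """Mixture model for the button-press delay after a cap opening.

    With probability ``short_prob`` the lag is uniform on
    ``[0, short_max_minutes]``; otherwise it is exponential with mean
    ``tail_mean_minutes``, negated with probability ``tail_negative_prob``
    (press before opening).
    """

    short_prob: float = 0.7
    short_max_minutes: float = 2.0
    tail_mean_minutes: float = 60.0
    tail_negative_prob: float = 0.25

    def sample_minutes(self, rng: np.random.Generator) -> float:
        if rng.random() < self.short_prob:
            return float(rng.uniform(0.0, self.short_max_minutes))
        lag = float(rng.exponential(self.tail_mean_minutes))
        if rng.random() < self.tail_negative_prob:
            lag = -lag
        return lag


ZERO_LAG = PressLag(short_prob=1.0, short_max_minutes=0.0)


@dataclass(frozen=True)
class BehaviorParams:
    """Stochastic model of one participant's daily dosing behavior."""

    p_dose: float = DEFAULT_P_DOSE
    jitter_sd_minutes: float = 45.0
    late_shift_minutes: float = 0.0
    p_press_given_dose: float = 0.80
    p_press_received: float = DEFAULT_PRESS_THROUGH / 0.80
    press_lag: PressLag = field(default_factory=PressLag)
    nonuse_days: frozenset[int] = frozenset()
    travel: tuple[TravelInterval, ...] = ()

    def __post_init__(self) -> None:
        for name in ("p_dose", "p_press_given_dose", "p_press_received"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.jitter_sd_minutes < 0:
            raise ValueError("jitter_sd_minutes must be non-negative")


@dataclass(frozen=True)
class DayTruth:
    """Ground truth for one study day (for parameter-recovery tests)."""

    study_day: int
    dose_taken: bool
    dose_instant: datetime | None
    press_attempted: bool
    press_received: bool

    def __post_init__(self) -> None:
        if self.press_received and not self.press_attempted:
            raise ValueError("received implies attempted")
        if self.press_attempted and not self.dose_taken:
            raise ValueError("attempted implies dose taken")


@dataclass(frozen=True)
class SimulatedParticipant:
    participant_id: str
    button_events: tuple[DoseEvent, ...]
    cap_events: tuple[DoseEvent, ...]
    truth: tuple[DayTruth, ...]
    config: StudyConfig  # travel-augmented config used for localization


def _dose_instant(
    config: StudyConfig, day: int, offset_minutes: float
) -> datetime:
    tz = ZoneInfo(config.effective_timezone(day))
    day_date = config.start_date + timedelta(days=day - 1)
    goal_minutes = config.goal_time.hour * 60 + config.goal_time.minute
    total = goal_minutes + offset_minutes
    total = min(max(total, 0.0), 24 * 60 - 1.0)  # truncate to the local day
    naive = datetime(day_date.year, day_date.month, day_date.day) + timedelta(
        minutes=total
    )
    return naive.replace(second=0, microsecond=0, tzinfo=tz)


def simulate_participant(
    params: BehaviorParams,
    config: StudyConfig,
    seed: int | np.random.SeedSequence,
    participant_id: str = "P1",
) -> SimulatedParticipant:
    """Generate one participant's paired event streams and ground truth.

    The participant's travel intervals (if any) replace the config's travel
    log; timestamps carry the UTC offset of the effective timezone of each
    day, so localization is exercised end to end.
    """
    rng = np.random.default_rng(seed)
    sim_config = config.with_travel(params.travel) if params.travel else config
    button: list[DoseEvent] = []
    cap: list[DoseEvent] = []
    truth: list[DayTruth] = []
    btn_uid = f"BTN-{participant_id}"
    cap_uid = f"CAP-{participant_id}"

    for day in range(1, sim_config.n_days + 1):
        if day in params.nonuse_days:
            truth.append(DayTruth(day, False, None, False, False))
            continue
        taken = rng.random() < params.p_dose
        if not taken:
            truth.append(DayTruth(day, False, None, False, False))
            continue
        offset = params.late_shift_minutes
        if params.jitter_sd_minutes > 0:
            offset += float(rng.normal(0.0, params.jitter_sd_minutes))
        instant = _dose_instant(sim_config, day, offset)
        cap.append(DoseEvent(participant_id, Channel.CAP, instant, cap_uid))
        attempted = rng.random() < params.p_press_given_dose
        received = attempted and rng.random() < params.p_press_received
        if received:
            lag = params.press_lag.sample_minutes(rng)
            press_at = (instant + timedelta(minutes=lag)).replace(
                second=0, microsecond=0
            )
            button.append(
                DoseEvent(participant_id, Channel.BUTTON, press_at, btn_uid)
            )
        truth.append(DayTruth(day, True, instant, attempted, received))

    return SimulatedParticipant(
        participant_id=participant_id,
        button_events=tuple(button),
        cap_events=tuple(cap),
        truth=tuple(truth),
        config=sim_config,
    )


def simulate_cohort(
    params_by_participant: Mapping[str, BehaviorParams],
    config: StudyConfig,
    seed: int,
) -> dict[str, SimulatedParticipant]:
    """Simulate several participants with independent, seed-derived streams."""
    if not params_by_participant:
        raise ValueError("cohort must have at least one participant")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(params_by_participant))
    return {
        pid: simulate_participant(params_by_participant[pid], config, child, pid)
        for pid, child in zip(sorted(params_by_participant), children)
    }


def feasibility_cohort_params(
    config: StudyConfig, travel_zone: str = "Europe/London"
) -> dict[str, BehaviorParams]:
    """Bundled 5-participant scenario with heterogeneous behavior.

    Qualitative archetypes: a near-perfect taker, a low-adherence taker, a
    high taker whose presses never reach the server, a traveler who crosses
    timezones mid-study, and a participant who stops using the devices on
    day 48.
    """
    near_perfect = BehaviorParams(
        p_dose=0.98, jitter_sd_minutes=20.0, p_press_given_dose=0.95,
        p_press_received=0.9,
    )
    low_adherence = BehaviorParams(
        p_dose=0.22, jitter_sd_minutes=90.0, p_press_given_dose=0.6,
        p_press_received=0.7,
    )
    zero_button = BehaviorParams(
        p_dose=0.97, jitter_sd_minutes=30.0, p_press_given_dose=0.0,
    )
    traveler = BehaviorParams(
        p_dose=0.92, jitter_sd_minutes=40.0, p_press_given_dose=0.85,
        p_press_received=0.8,
        travel=(TravelInterval(20, 27, travel_zone),),
    )
    stopper = BehaviorParams(
        p_dose=0.88, jitter_sd_minutes=45.0, p_press_given_dose=0.8,
        p_press_received=0.75,
        nonuse_days=frozenset(range(48, config.n_days + 1)),
    )
    return {
        "P1": near_perfect,
        "P2": low_adherence,
        "P3": zero_button,
        "P4": traveler,
        "P5": stopper,
    }
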