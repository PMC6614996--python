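"""Server-side feedback rules for smart-button presses.

Every registered button press gets exactly one reply. During the run-in and
wash-out phases (1 and 3) the reply is the single standard acknowledgement.
During the intervention phase (2) the *first* press of each participant-local
study day gets a tailored message matching the press's timing classification
(on-time vs outside the dosing window); repeat presses on the same day fall
back to the standard acknowledgement. Cap-channel events never trigger
feedback.

The tailored bank holds 30 on-time and 30 outside-time messages; the message
used on a given day cycles deterministically through the bank:
``bank_index = ((study_day - first day of phase 2) mod 30) + 1``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

from .core import (
    Channel,
    DoseEvent,
    LocalizedEvent,
    OutOfStudyError,
    StudyConfig,
    TimingClass,
    TzPolicy,
    classify_timing,
    localize,
    phase_first_day,
    phase_of_day,
)

__all__ = [
    "MessageCategory",
    "FeedbackMessage",
    "MessageBank",
    "default_bank",
    "FeedbackDecision",
    "ParticipantState",
    "Registry",
    "build_registry",
    "resolve_participant",
    "UnregisteredDeviceError",
    "BankError",
    "select_message",
    "process_event_stream",
    "Transport",
    "LogTransport",
    "TAILORED_PHASE",
    "BANK_SIZE",
]

logger = logging.getLogger(__name__)

TAILORED_PHASE = 2
BANK_SIZE = 30  # tailored messages per category
STANDARD_BODY = "Thank you for pressing the button"


class BankError(ValueError):
    """Message bank missing a required category or index."""


class UnregisteredDeviceError(KeyError):
    """Button uid not assigned to any enrolled participant."""


class MessageCategory(str, enum.Enum):
    STANDARD = "standard"
    ON_TIME = "on_time"
    OUTSIDE_TIME = "outside_time"


@dataclass(frozen=True)
class FeedbackMessage:
    message_id: str
    category: MessageCategory
    bank_index: int | None  # 1..30 for tailored categories, None for standard
    body: str


class MessageBank:
    """Indexed store of one standard plus 30+30 tailored messages."""

    def __init__(self, messages: Iterable[FeedbackMessage]):
        self._by_key: dict[tuple[MessageCategory, int | None], FeedbackMessage] = {}
        for msg in messages:
            key = (msg.category, msg.bank_index)
            if key in self._by_key:
                raise BankError(f"duplicate bank entry {key}")
            if msg.category is MessageCategory.STANDARD and msg.bank_index is not None:
                raise BankError("standard message must not carry a bank_index")
            if msg.category is not MessageCategory.STANDARD and not (
                msg.bank_index and 1 <= msg.bank_index <= BANK_SIZE
            ):
                raise BankError(
                    f"tailored message {msg.message_id} needs bank_index in 1..{BANK_SIZE}"
                )
            self._by_key[key] = msg
        for cat in (MessageCategory.ON_TIME, MessageCategory.OUTSIDE_TIME):
            n = sum(1 for c, _ in self._by_key if c is cat)
            if n != BANK_SIZE:
                raise BankError(f"bank has {n} {cat.value} messages, expected {BANK_SIZE}")
        if (MessageCategory.STANDARD, None) not in self._by_key:
            raise BankError("bank is missing the standard message")

    def standard(self) -> FeedbackMessage:
        return self._by_key[(MessageCategory.STANDARD, None)]

    def tailored(self, category: MessageCategory, bank_index: int) -> FeedbackMessage:
        try:
            return self._by_key[(category, bank_index)]
        except KeyError as exc:
            raise BankError(f"no {category.value} message with index {bank_index}") from exc

    def __iter__(self):
        return iter(sorted(
            self._by_key.values(),
            key=lambda m: (m.category.value, m.bank_index or 0),
        ))

    def __len__(self) -> int:
        return len(self._by_key)


def default_bank() -> MessageBank:
    """Bundled bank with placeholder prose (structure and counts only)."""
    msgs = [FeedbackMessage("STD-1", MessageCategory.STANDARD, None, STANDARD_BODY)]
    for i in range(1, BANK_SIZE + 1):
        msgs.append(FeedbackMessage(
            f"ON-{i}", MessageCategory.ON_TIME, i,
            f"On-time message {i}: your routine is working — dose taken on schedule.",
        ))
        msgs.append(FeedbackMessage(
            f"OUT-{i}", MessageCategory.OUTSIDE_TIME, i,
            f"Outside-time message {i}: consider adjusting your routine for the next dose.",
        ))
    return MessageBank(msgs)


class Registry:
    """Injective mapping from button device uid to participant id."""

    def __init__(self, pairs: Mapping[str, str]):
        self._map = dict(pairs)

    def __contains__(self, uid: str) -> bool:
        return uid in self._map

    def __getitem__(self, uid: str) -> str:
        try:
            return self._map[uid]
        except KeyError:
            raise UnregisteredDeviceError(uid) from None

    def items(self):
        return self._map.items()


def build_registry(pairs: Iterable[tuple[str, str]]) -> Registry:
    """Build a registry from (device_uid, participant_id) pairs.

    Rejects a uid assigned to more than one participant.
    """
    mapping: dict[str, str] = {}
    for uid, pid in pairs:
        if uid in mapping and mapping[uid] != pid:
            raise ValueError(f"device uid {uid!r} assigned to multiple participants")
        mapping[uid] = pid
    return Registry(mapping)


def resolve_participant(device_uid: str, registry: Registry) -> str:
    """Look up the participant assigned to a button uid."""
    return registry[device_uid]


@dataclass(frozen=True)
class FeedbackDecision:
    """Outcome of the decision rules for one button press."""

    event: LocalizedEvent
    phase: int | None  # None for presses after the study horizon
    timing_class: TimingClass
    is_first_press_of_day: bool
    message: FeedbackMessage

    @property
    def participant_id(self) -> str:
        return self.event.participant_id


@dataclass
class ParticipantState:
    """Per-participant server state threaded through a press stream."""

    participant_id: str
    presses_by_day: dict[int, int] = field(default_factory=dict)
    history: list[FeedbackDecision] = field(default_factory=list)

    def press_count(self, day: int) -> int:
        return self.presses_by_day.get(day, 0)

    def record(self, decision: FeedbackDecision) -> None:
        day = decision.event.study_day
        self.presses_by_day[day] = self.presses_by_day.get(day, 0) + 1
        self.history.append(decision)


def select_message(
    event: LocalizedEvent,
    state: ParticipantState,
    config: StudyConfig,
    bank: MessageBank,
) -> FeedbackDecision:
    """Apply the decision rules to one localized button press.

    Updates ``state`` (per-day press counter and history) as a side effect.
    """
    day = event.study_day
    is_first = state.press_count(day) == 0
    phase = phase_of_day(day, config) if event.in_study else None

    if phase == TAILORED_PHASE and is_first:
        timing = classify_timing(event, config)
        offset = day - phase_first_day(TAILORED_PHASE, config)
        bank_index = (offset % BANK_SIZE) + 1
        category = (
            MessageCategory.ON_TIME
            if timing is TimingClass.ON_TIME
            else MessageCategory.OUTSIDE_TIME
        )
        message = bank.tailored(category, bank_index)
    else:
        timing = TimingClass.NOT_APPLICABLE
        message = bank.standard()

    decision = FeedbackDecision(
        event=event,
        phase=phase,
        timing_class=timing,
        is_first_press_of_day=is_first,
        message=message,
    )
    state.record(decision)
    return decision


class Transport(Protocol):
    """Pluggable delivery layer; the bundled one is a dry-run log."""

    def send(self, participant_id: str, decision: FeedbackDecision) -> None: ...


class LogTransport:
    """Dry-run transport: records would-be deliveries as log lines."""

    def __init__(self) -> None:
        self.sent: list[tuple[str, str]] = []

    def send(self, participant_id: str, decision: FeedbackDecision) -> None:
        self.sent.append((participant_id, decision.message.message_id))
        logger.info(
            "send %s -> %s (%s)",
            decision.message.message_id, participant_id, decision.timing_class.value,
        )


def process_event_stream(
    events: Sequence[DoseEvent],
    config: StudyConfig,
    registry: Registry,
    bank: MessageBank,
    policy: TzPolicy = TzPolicy.PARTICIPANT_LOCAL,
    transport: Transport | None = None,
) -> tuple[list[FeedbackDecision], list[tuple[DoseEvent, str]]]:
    """Run the decision rules over a stream of raw device events.

    Events arrive in arbitrary order (webhook delivery order is not
    guaranteed); they are sorted by timestamp before processing so replays
    are deterministic. Cap events never generate feedback. Unregistered or
    pre-study events are skipped and reported, never abort the stream.

    Returns ``(decisions, skipped)`` where each skipped entry carries the
    offending event and a reason string.
    """
    states: dict[str, ParticipantState] = {}
    decisions: list[FeedbackDecision] = []
    skipped: list[tuple[DoseEvent, str]] = []

    ordered = sorted(
        events, key=lambda e: (e.timestamp, e.participant_id, e.device_uid)
    )
    for event in ordered:
        if event.channel is not Channel.BUTTON:
            continue
        try:
            pid = resolve_participant(event.device_uid, registry)
        except UnregisteredDeviceError:
            logger.warning("unregistered device uid %s; event skipped", event.device_uid)
            skipped.append((event, "unregistered-device"))
            continue
        try:
            localized = localize(event, config, policy)
        except OutOfStudyError:
            logger.warning("event before study start from %s; skipped", pid)
            skipped.append((event, "before-study-start"))
            continue
        state = states.setdefault(pid, ParticipantState(pid))
        decision = select_message(localized, state, config, bank)
        decisions.append(decision)
        if transport is not None:
            transport.send(pid, decision)
    return decisions, skipped
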