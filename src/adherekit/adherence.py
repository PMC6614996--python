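"""MEMS-style taking-adherence scores and completeness statistics.

Adherence here is *taking* adherence for a once-daily regimen: a day counts
as adherent if at least one event was recorded on that participant-local
day. Scores are the percentage of non-excluded days in a period with at
least one event, rounded half-up to an integer percent (the precision used
for per-participant scores). Completeness — recorded events against the
expected one-per-day yield — is reported to one decimal.

Exclusion days are days the participant reported not using the device
(e.g. stopped for travel); they are removed from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .core import LocalizedEvent, StudyConfig

__all__ = [
    "AdherenceReport",
    "CompletenessStat",
    "CohortSummary",
    "UndefinedScoreError",
    "adherence_score",
    "participant_reports",
    "completeness",
    "cohort_summary",
    "OVERALL",
]

OVERALL = "overall"


class UndefinedScoreError(ValueError):
    """Score requested over an empty effective period."""


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AdherenceReport:
    participant_id: str
    period: str  # "overall" or "phase <id>"
    channel: str
    days_expected: int
    days_with_event: int
    adherence_pct: int

    def __post_init__(self) -> None:
        if not 0 <= self.days_with_event <= self.days_expected:
            raise ValueError("days_with_event outside 0..days_expected")


@dataclass(frozen=True)
class CompletenessStat:
    n_recorded: int
    n_expected: int
    pct: float  # one decimal


@dataclass(frozen=True)
class CohortSummary:
    mean_pct: float  # one decimal
    min_pct: int
    max_pct: int
    n: int


def adherence_score(
    events: Sequence[LocalizedEvent],
    config: StudyConfig,
    period: Iterable[int] | None = None,
    exclusions: frozenset[int] | set[int] = frozenset(),
    *,
    participant_id: str = "",
    channel: str = "",
    label: str = OVERALL,
) -> AdherenceReport:
    """Taking-adherence score for one participant and channel over a period.

    Parameters
    ----------
    events:
        Localized events for a single participant and channel.
    period:
        Study days included (default: the whole study, 1..n_days).
    exclusions:
        Reported non-use days, removed from the denominator.
    """
    days = set(period) if period is not None else set(range(1, config.n_days + 1))
    effective = days - set(exclusions)
    if not effective:
        raise UndefinedScoreError("no scoreable days after exclusions")
    event_days = {e.study_day for e in events}
    taken = len(effective & event_days)
    pid = participant_id or (events[0].participant_id if events else "")
    chan = channel or (events[0].channel.value if events else "")
    return AdherenceReport(
        participant_id=pid,
        period=label,
        channel=chan,
        days_expected=len(effective),
        days_with_event=taken,
        adherence_pct=int(_round_half_up(100.0 * taken / len(effective))),
    )


def participant_reports(
    events: Sequence[LocalizedEvent],
    config: StudyConfig,
    exclusions: frozenset[int] | set[int] = frozenset(),
    *,
    participant_id: str = "",
    channel: str = "",
) -> list[AdherenceReport]:
    """Overall report plus one per phase, in phase order."""
    reports = [
        adherence_score(
            events, config, None, exclusions,
            participant_id=participant_id, channel=channel, label=OVERALL,
        )
    ]
    for pid_, first, last in config.phase_bounds:
        reports.append(
            adherence_score(
                events, config, range(first, last + 1), exclusions,
                participant_id=participant_id, channel=channel,
                label=f"phase {pid_}",
            )
        )
    return reports


def completeness(n_recorded: int, n_expected: int) -> CompletenessStat:
    """Recorded-vs-expected event completeness, one-decimal percent."""
    if n_expected <= 0:
        raise ValueError("n_expected must be positive")
    pct = _round_half_up(100.0 * n_recorded / n_expected, 1)
    return CompletenessStat(n_recorded=n_recorded, n_expected=n_expected, pct=pct)


def cohort_summary(reports: Sequence[AdherenceReport]) -> CohortSummary:
    """Mean (one decimal) and min-max range of adherence percentages."""
    if not reports:
        raise ValueError("cohort_summary requires at least one report")
    scores = [r.adherence_pct for r in reports]
    return CohortSummary(
        mean_pct=_round_half_up(sum(scores) / len(scores), 1),
        min_pct=min(scores),
        max_pct=max(scores),
        n=len(scores),
    )
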