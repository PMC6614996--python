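"""Readers and writers for event CSV, study config JSON, registries,
message banks, exclusion lists and report tables, plus the run manifest.

Events travel as CSV with columns ``participant_id, channel, timestamp,
device_uid``; timestamps are ISO-8601 with a UTC offset
(``2018-03-01T08:05:00-05:00``). The study config and device registry are
JSON. The message bank is a tab-separated text file with one record per
message. Schema errors (missing column) fail fast; row errors (bad
timestamp, bad channel) are collected with line numbers and reported
together.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import date, datetime, time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._version import __version__
from .adherence import AdherenceReport
from .concordance import ConcordanceSummary, PairOrder
from .core import Channel, DoseEvent, StudyConfig, TravelInterval
from .feedback import (
    FeedbackDecision,
    FeedbackMessage,
    MessageBank,
    MessageCategory,
    Registry,
    build_registry,
)

__all__ = [
    "SchemaError",
    "RowErrors",
    "read_events",
    "write_events",
    "read_config",
    "write_config",
    "read_registry",
    "write_registry",
    "read_bank",
    "write_bank",
    "read_exclusions",
    "write_decisions",
    "write_adherence_reports",
    "write_concordance_summaries",
    "RunManifest",
    "make_manifest",
    "write_manifest",
]

EVENT_COLUMNS = ["participant_id", "channel", "timestamp", "device_uid"]


class SchemaError(ValueError):
    """Input file lacks a required column or field."""


class RowErrors(ValueError):
    """One or more rows failed to parse; carries (line, message) pairs."""

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors)
        super().__init__(f"{len(self.errors)} bad row(s): {lines}")


# ---------------------------------------------------------------- events


def read_events(path: str | Path) -> list[DoseEvent]:
    """Read an event CSV; collect row errors, then fail if any occurred."""
    path = Path(path)
    events: list[DoseEvent] = []
    errors: list[tuple[int, str]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in EVENT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                ts = datetime.fromisoformat(row["timestamp"].strip())
                if ts.tzinfo is None:
                    raise ValueError("timestamp lacks a UTC offset")
                events.append(
                    DoseEvent(
                        participant_id=row["participant_id"].strip(),
                        channel=Channel(row["channel"].strip()),
                        timestamp=ts,
                        device_uid=row["device_uid"].strip(),
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append((lineno, str(exc)))
    if errors:
        raise RowErrors(errors)
    return events


def write_events(events: Iterable[DoseEvent], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow(
                [e.participant_id, e.channel.value, e.timestamp.isoformat(), e.device_uid]
            )


# ---------------------------------------------------------------- config


def config_to_dict(config: StudyConfig) -> dict:
    return {
        "start_date": config.start_date.isoformat(),
        "goal_time": config.goal_time.strftime("%H:%M"),
        "home_timezone": config.home_timezone,
        "n_days": config.n_days,
        "phase_bounds": [list(p) for p in config.phase_bounds],
        "dosing_interval_hours": config.dosing_interval_hours,
        "window_fraction": config.window_fraction,
        "travel_log": [
            [iv.first_day, iv.last_day, iv.timezone] for iv in config.travel_log
        ],
    }


def config_from_dict(data: Mapping) -> StudyConfig:
    required = ["start_date", "goal_time", "home_timezone"]
    missing = [k for k in required if k not in data]
    if missing:
        raise SchemaError(f"config missing field(s) {missing}")
    hh, mm = data["goal_time"].split(":")
    kwargs = dict(
        start_date=date.fromisoformat(data["start_date"]),
        goal_time=time(int(hh), int(mm)),
        home_timezone=data["home_timezone"],
    )
    if "n_days" in data:
        kwargs["n_days"] = int(data["n_days"])
    if "phase_bounds" in data:
        kwargs["phase_bounds"] = tuple(tuple(p) for p in data["phase_bounds"])
    if "dosing_interval_hours" in data:
        kwargs["dosing_interval_hours"] = float(data["dosing_interval_hours"])
    if "window_fraction" in data:
        kwargs["window_fraction"] = float(data["window_fraction"])
    if "travel_log" in data:
        kwargs["travel_log"] = tuple(
            TravelInterval(int(a), int(b), tz) for a, b, tz in data["travel_log"]
        )
    return StudyConfig(**kwargs)


def read_config(path: str | Path) -> StudyConfig:
    with Path(path).open() as fh:
        return config_from_dict(json.load(fh))


def write_config(config: StudyConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(config_to_dict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------- registry


def read_registry(path: str | Path) -> Registry:
    """Registry JSON: an object {device_uid: participant_id} or a pair list."""
    with Path(path).open() as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        pairs = list(data.items())
    else:
        pairs = [(uid, pid) for uid, pid in data]
    return build_registry(pairs)


def write_registry(registry: Registry, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(dict(registry.items()), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------- bank


def read_bank(path: str | Path) -> MessageBank:
    """Message bank TSV: message_id, category, bank_index (blank for standard), body."""
    path = Path(path)
    messages: list[FeedbackMessage] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = ["message_id", "category", "bank_index", "body"]
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) {missing}")
        for row in reader:
            idx = row["bank_index"].strip()
            messages.append(
                FeedbackMessage(
                    message_id=row["message_id"].strip(),
                    category=MessageCategory(row["category"].strip()),
                    bank_index=int(idx) if idx else None,
                    body=row["body"],
                )
            )
    return MessageBank(messages)


def write_bank(bank: MessageBank, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["message_id", "category", "bank_index", "body"])
        for m in bank:
            writer.writerow(
                [m.message_id, m.category.value,
                 m.bank_index if m.bank_index is not None else "", m.body]
            )


# ---------------------------------------------------------------- exclusions


def read_exclusions(path: str | Path) -> dict[str, set[int]]:
    """Exclusion CSV (participant_id, day): reported device non-use days."""
    path = Path(path)
    out: dict[str, set[int]] = {}
    errors: list[tuple[int, str]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ("participant_id", "day") if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.setdefault(row["participant_id"].strip(), set()).add(int(row["day"]))
            except ValueError as exc:
                errors.append((lineno, str(exc)))
    if errors:
        raise RowErrors(errors)
    return out


# ---------------------------------------------------------------- reports


def write_decisions(decisions: Sequence[FeedbackDecision], path: str | Path) -> None:
    """Decision log CSV in stable column order (byte-identical on rerun)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["participant_id", "timestamp", "study_day", "phase",
             "timing_class", "first_press", "message_id"]
        )
        for d in decisions:
            writer.writerow(
                [
                    d.participant_id,
                    d.event.instant.isoformat(),
                    d.event.study_day,
                    d.phase if d.phase is not None else "",
                    d.timing_class.value,
                    int(d.is_first_press_of_day),
                    d.message.message_id,
                ]
            )


def adherence_frame(reports: Sequence[AdherenceReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in reports],
        columns=["participant_id", "period", "channel",
                 "days_expected", "days_with_event", "adherence_pct"],
    )


def write_adherence_reports(
    reports: Sequence[AdherenceReport], path: str | Path
) -> None:
    adherence_frame(reports).to_csv(path, index=False)


def concordance_frame(summaries: Sequence[ConcordanceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "participant_id": s.participant_id or "pooled",
            "n_days_monitored": s.n_days_monitored,
            "n_button_days": s.n_button_days,
            "n_cap_days": s.n_cap_days,
            "n_concordant_days": s.n_concordant_days,
            "pct_concordant": s.pct_concordant,
            "n_pairs": s.n_pairs,
            "n_within_window": s.n_within_window,
            "pct_within_window": s.pct_within_window,
            "window_minutes": s.window_minutes,
        }
        for order in PairOrder:
            st = s.order_stats[order]
            row[f"n_{order.value}"] = st.count
            row[f"mean_abs_delta_{order.value}"] = st.mean_abs_delta
            row[f"median_abs_delta_{order.value}"] = st.median_abs_delta
        rows.append(row)
    return pd.DataFrame(rows)


def write_concordance_summaries(
    summaries: Sequence[ConcordanceSummary], path: str | Path
) -> None:
    concordance_frame(summaries).to_csv(path, index=False)


# ---------------------------------------------------------------- manifest


@dataclass(frozen=True)
class RunManifest:
    """Provenance record for one CLI run.

    Two runs with equal :meth:`key` (everything but the wall-clock
    timestamp) must produce byte-identical outputs.
    """

    command: str
    input_digests: tuple[tuple[str, str], ...]  # (filename, sha256)
    config_snapshot: str  # canonical JSON of the StudyConfig, "" if none
    seed: int | None
    tool_version: str
    timestamp: str

    def key(self) -> tuple:
        return (self.command, self.input_digests, self.config_snapshot,
                self.seed, self.tool_version)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def make_manifest(
    command: str,
    inputs: Sequence[str | Path],
    config: StudyConfig | None = None,
    seed: int | None = None,
    now: datetime | None = None,
) -> RunManifest:
    digests = tuple(
        (Path(p).name, _digest(p)) for p in sorted(inputs, key=lambda p: str(p))
    )
    snapshot = (
        json.dumps(config_to_dict(config), sort_keys=True) if config is not None else ""
    )
    stamp = (now if now is not None else datetime.now().astimezone()).isoformat()
    return RunManifest(
        command=command,
        input_digests=digests,
        config_snapshot=snapshot,
        seed=seed,
        tool_version=__version__,
        timestamp=stamp,
    )


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
        fh.write("\n")
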