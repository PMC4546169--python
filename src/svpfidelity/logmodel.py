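"""Domain model and tabular IO for systematic voiding programme clinical logs.

A *clinical log* is the per-patient per-day form on which ward staff record
delivery of a systematic voiding programme (SVP): the prescribed voiding
interval for the day, the schedule of proposed voiding times derived from it,
the actual voiding times achieved, and yes/no answers to best-practice
questions (giving encouragement; for prompted voiding, asking whether the
patient was wet).

All clock times are stored as integer minutes since midnight and exchanged as
24-hour ``"HH:MM"`` text; the SVP day runs from 07:30 (:data:`DAY_START`) to
21:30 (:data:`DAY_END`).

Missingness is first-class throughout: a blank best-practice answer is
``missing``, never coerced to ``no`` — staff frequently leave an answer blank
rather than record a negative, and the distinction must survive IO.

On-disk format: UTF-8 CSV, one row per voiding event, grouped by ``log_id``
(see :func:`read_logs` / :func:`write_logs`). A blank cell means missing.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import functools
import json
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

#: Start of the SVP day, 07:30, in minutes since midnight.
DAY_START = 450
#: End of the SVP day, 21:30, in minutes since midnight.
DAY_END = 1290


# ---------------------------------------------------------------------------
# Clock times
# ---------------------------------------------------------------------------

@functools.total_ordering
@dataclasses.dataclass(frozen=True)
class TimeOfDay:
    """A clock time, stored as integer minutes since midnight (0–1439)."""

    minutes: int

    def __post_init__(self) -> None:
        if not (0 <= int(self.minutes) <= 1439):
            raise ValueError(f"minutes since midnight out of range: {self.minutes}")
        object.__setattr__(self, "minutes", int(self.minutes))

    @classmethod
    def parse(cls, text: str) -> "TimeOfDay":
        """Parse 24-hour ``"HH:MM"`` text. Raises ``ValueError`` if malformed."""
        m = re.fullmatch(r"\s*(\d{1,2}):(\d{2})\s*", text)
        if m is None:
            raise ValueError(f"not a HH:MM time: {text!r}")
        hh, mm = int(m.group(1)), int(m.group(2))
        if hh > 23 or mm > 59:
            raise ValueError(f"not a valid clock time: {text!r}")
        return cls(hh * 60 + mm)

    def __str__(self) -> str:
        return f"{self.minutes // 60:02d}:{self.minutes % 60:02d}"

    def __int__(self) -> int:
        return self.minutes

    def __lt__(self, other: "TimeOfDay") -> bool:
        return self.minutes < other.minutes

    def __sub__(self, other: "TimeOfDay") -> int:
        """Difference in minutes (may be negative)."""
        return self.minutes - other.minutes


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Arm(str, enum.Enum):
    """Trial arm delivering the SVP."""

    INTERVENTION = "intervention"
    SUPPORTED_IMPLEMENTATION = "supported_implementation"


class Regime(str, enum.Enum):
    """SVP regime; only prompted voiding carries the "asked if wet" item."""

    PROMPTED_VOIDING = "prompted_voiding"
    BLADDER_TRAINING = "bladder_training"


class Answer(str, enum.Enum):
    """A best-practice answer as documented (missing is not "no")."""

    YES = "yes"
    NO = "no"
    MISSING = "missing"
    NOT_APPLICABLE = "not_applicable"


class IntervalStatus(str, enum.Enum):
    """Classification of the voiding-interval text on a log."""

    SINGLE = "single"
    RANGE = "range"
    MISSING = "missing"
    UNPARSEABLE = "unparseable"


# ---------------------------------------------------------------------------
# Voiding interval
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class VoidingIntervalSpec:
    """Parsed voiding-interval text.

    ``value_minutes`` is present iff ``status`` is ``single``: only an
    individual interval such as "2-hourly" defines a usable schedule; a range
    such as "2 – 3 hourly" does not.
    """

    raw_text: str
    status: IntervalStatus
    value_minutes: Optional[int] = None

    def __post_init__(self) -> None:
        if self.status is IntervalStatus.SINGLE:
            if self.value_minutes is None or self.value_minutes <= 0:
                raise ValueError("single interval requires positive value_minutes")
        elif self.value_minutes is not None:
            raise ValueError(f"{self.status.value} interval must not carry value_minutes")
        if (self.status is IntervalStatus.MISSING) != (self.raw_text.strip() == ""):
            raise ValueError("status=missing iff raw_text is blank")


# number limited to integers or half-hours ("2", "2.5"); separator before
# "hourly" may be hyphen, en dash or whitespace
_NUM = r"\d+(?:\.5)?"
_SINGLE_RE = re.compile(rf"^\s*({_NUM})\s*(?:[-–]|\s)\s*hourly\s*$", re.IGNORECASE)
_RANGE_RE = re.compile(
    rf"^\s*({_NUM})\s*[-–]\s*({_NUM})\s*(?:[-–]|\s)\s*hourly\s*$", re.IGNORECASE
)


def parse_interval(raw_text: str) -> VoidingIntervalSpec:
    """Classify voiding-interval text.

    Total and deterministic: blank text is ``missing``, one number + "hourly"
    is ``single`` (converted to minutes; half-hours supported, "2.5-hourly"
    → 150), two dash-separated numbers + "hourly" is ``range``, anything else
    is ``unparseable``. Never raises.
    """
    if raw_text is None or raw_text.strip() == "":
        return VoidingIntervalSpec(raw_text or "", IntervalStatus.MISSING)
    m = _RANGE_RE.match(raw_text)
    if m is not None:
        return VoidingIntervalSpec(raw_text, IntervalStatus.RANGE)
    m = _SINGLE_RE.match(raw_text)
    if m is not None:
        minutes = round(float(m.group(1)) * 60)
        if minutes > 0:
            return VoidingIntervalSpec(raw_text, IntervalStatus.SINGLE, minutes)
    return VoidingIntervalSpec(raw_text, IntervalStatus.UNPARSEABLE)


def format_interval(minutes: int) -> str:
    """Canonical interval text for a single interval, e.g. 150 → "2.5-hourly"."""
    hours = minutes / 60
    text = f"{hours:g}"
    return f"{text}-hourly"


# ---------------------------------------------------------------------------
# Events and logs
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class VoidingEvent:
    """One row of a clinical log: a proposed slot and/or an actual void.

    A row may lack a proposed time (a gap in the written schedule) or an
    actual time (the patient was not toileted), but never both.
    ``justification_code`` carries a clinically-justifiable explanation (e.g.
    patient off the ward) used to exempt the occasion from timing assessment.
    """

    proposed_time: Optional[TimeOfDay] = None
    actual_time: Optional[TimeOfDay] = None
    encouragement: Answer = Answer.MISSING
    wet_asked: Answer = Answer.MISSING
    comment: str = ""
    justification_code: Optional[str] = None

    def __post_init__(self) -> None:
        if self.proposed_time is None and self.actual_time is None:
            raise ValueError("event needs a proposed or an actual time")


@dataclasses.dataclass(frozen=True)
class ClinicalLog:
    """One patient-day of SVP documentation, the unit of fidelity assessment."""

    log_id: str
    patient_id: str
    site_id: str
    arm: Arm
    date: datetime.date
    regime: Regime
    interval: VoidingIntervalSpec
    events: tuple[VoidingEvent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        proposed = [e.proposed_time for e in self.events if e.proposed_time is not None]
        if any(b - a <= 0 for a, b in zip(proposed, proposed[1:])):
            raise ValueError(f"log {self.log_id}: proposed times not strictly increasing")
        for e in self.events:
            is_na = e.wet_asked is Answer.NOT_APPLICABLE
            if is_na != (self.regime is Regime.BLADDER_TRAINING):
                raise ValueError(
                    f"log {self.log_id}: wet_asked must be not_applicable "
                    "exactly for bladder-training logs"
                )

    @property
    def proposed_times(self) -> list[TimeOfDay]:
        return [e.proposed_time for e in self.events if e.proposed_time is not None]

    @property
    def actual_times(self) -> list[TimeOfDay]:
        return [e.actual_time for e in self.events if e.actual_time is not None]


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "log_id", "patient_id", "site_id", "arm", "date", "regime", "interval_text",
    "proposed_time", "actual_time", "encouragement", "wet_asked", "comment",
    "justification_code",
]


class LogSchemaError(ValueError):
    """A required column is absent from the input file."""


@dataclasses.dataclass
class LoadResult:
    """Outcome of :func:`read_logs`: parsed logs plus per-row warnings."""

    logs: list[ClinicalLog]
    warnings: list[str]

    def write_report(self, path: str | Path) -> None:
        """Write the companion JSON load report listing all warnings."""
        report = {"n_logs": len(self.logs), "n_warnings": len(self.warnings),
                  "warnings": self.warnings}
        Path(path).write_text(json.dumps(report, indent=2), encoding="utf-8")


def _parse_time_cell(cell: str, field: str, row: int, warnings: list[str]) -> Optional[TimeOfDay]:
    if cell == "":
        return None
    try:
        return TimeOfDay.parse(cell)
    except ValueError:
        warnings.append(f"row {row}: unparseable {field} {cell!r}; treated as missing")
        return None


def _parse_answer_cell(cell: str, field: str, row: int, warnings: list[str]) -> Answer:
    if cell == "":
        return Answer.MISSING
    try:
        return Answer(cell.strip().lower())
    except ValueError:
        warnings.append(f"row {row}: unknown {field} value {cell!r}; treated as missing")
        return Answer.MISSING


def read_logs(path: str | Path, report_path: str | Path | None = None) -> LoadResult:
    """Read clinical logs from CSV (one row per voiding event).

    Malformed time strings degrade to missing with a warning; rows with no
    usable time, and logs violating structural invariants, are dropped with a
    warning. Missing required columns raise :class:`LogSchemaError` naming
    the column. If ``report_path`` is given, the JSON load report is written
    there as well.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise LogSchemaError(f"missing required column(s): {', '.join(missing_cols)}")

    warnings: list[str] = []
    logs: list[ClinicalLog] = []
    seen_patient_days: set[tuple[str, datetime.date]] = set()

    # group rows by log_id in order of first appearance
    order: dict[str, list[int]] = {}
    for i in df.index:
        order.setdefault(df.at[i, "log_id"], []).append(i)

    for log_id, rows in order.items():
        first = df.loc[rows[0]]
        try:
            arm = Arm(first["arm"].strip().lower())
            regime = Regime(first["regime"].strip().lower())
            date = datetime.date.fromisoformat(first["date"].strip())
        except ValueError as exc:
            warnings.append(f"log {log_id!r}: bad metadata ({exc}); log skipped")
            continue

        events: list[VoidingEvent] = []
        for i in rows:
            row = df.loc[i]
            proposed = _parse_time_cell(row["proposed_time"], "proposed_time", i, warnings)
            actual = _parse_time_cell(row["actual_time"], "actual_time", i, warnings)
            if proposed is None and actual is None:
                warnings.append(f"row {i}: no proposed or actual time; row skipped")
                continue
            wet = _parse_answer_cell(row["wet_asked"], "wet_asked", i, warnings)
            if regime is Regime.BLADDER_TRAINING and wet is Answer.MISSING:
                wet = Answer.NOT_APPLICABLE
            events.append(VoidingEvent(
                proposed_time=proposed,
                actual_time=actual,
                encouragement=_parse_answer_cell(row["encouragement"], "encouragement", i, warnings),
                wet_asked=wet,
                comment=row["comment"],
                justification_code=row["justification_code"] or None,
            ))

        try:
            log = ClinicalLog(
                log_id=log_id,
                patient_id=first["patient_id"],
                site_id=first["site_id"],
                arm=arm,
                date=date,
                regime=regime,
                interval=parse_interval(first["interval_text"]),
                events=tuple(events),
            )
        except ValueError as exc:
            warnings.append(f"log {log_id!r}: invalid ({exc}); log skipped")
            continue

        key = (log.patient_id, log.date)
        if key in seen_patient_days:
            warnings.append(f"log {log_id!r}: duplicate patient-day {key}")
        seen_patient_days.add(key)
        logs.append(log)

    result = LoadResult(logs=logs, warnings=warnings)
    if report_path is not None:
        result.write_report(report_path)
    return result


def write_logs(logs: Iterable[ClinicalLog], path: str | Path) -> None:
    """Write clinical logs to CSV, one row per event; blank cell = missing.

    ``read_logs(write_logs(x))`` reproduces ``x`` field-for-field for any
    fleet of logs that all carry at least one event (a zero-event log emits
    no rows). An empty input produces a header-only file.
    """
    records = []
    for log in logs:
        for e in log.events:
            records.append({
                "log_id": log.log_id,
                "patient_id": log.patient_id,
                "site_id": log.site_id,
                "arm": log.arm.value,
                "date": log.date.isoformat(),
                "regime": log.regime.value,
                "interval_text": log.interval.raw_text,
                "proposed_time": "" if e.proposed_time is None else str(e.proposed_time),
                "actual_time": "" if e.actual_time is None else str(e.actual_time),
                "encouragement": "" if e.encouragement is Answer.MISSING else e.encouragement.value,
                "wet_asked": "" if e.wet_asked is Answer.MISSING else e.wet_asked.value,
                "comment": e.comment,
                "justification_code": e.justification_code or "",
            })
    pd.DataFrame.from_records(records, columns=CSV_COLUMNS).to_csv(path, index=False)
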