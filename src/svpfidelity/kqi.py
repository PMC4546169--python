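"""Staged key-quality-indicator (KQI) assessment of a single clinical log.

Fidelity to SVP delivery is scored in four stages, each a prerequisite for
the next:

* **Stage 1** — is the voiding interval present and documented as a single
  value (e.g. "2-hourly"), not a range and not missing?
* **Stage 2** — is the schedule of proposed voiding times complete (no blank
  entries between the first and last proposed time) and arithmetically
  consistent with the interval (every consecutive gap equal to it)?
* **Stage 3** — on how many proposed occasions was an actual voiding time
  documented within the leeway window (default ±30 minutes)? Occasions with
  a clinically justifiable explanation are exempted from both numerator and
  denominator.
* **Stage 4** — on how many proposed occasions was "yes" documented for the
  best-practice questions (4a encouragement, always; 4b asked-if-wet,
  prompted voiding only)?

Assessment of a log terminates at Stage 1 or Stage 2 when that stage's
indicator is not achieved: without a valid interval and schedule, comparing
actual to proposed times is meaningless.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .logmodel import (
    DAY_END,
    DAY_START,
    Answer,
    ClinicalLog,
    IntervalStatus,
    Regime,
    TimeOfDay,
)

#: Codes accepted by default as clinically justifiable explanations for an
#: early/late/missing actual void (the occasion is exempted from Stage 3).
DEFAULT_EXEMPTION_CODES = ("OFF_WARD", "ASLEEP", "REFUSED", "MEDICALLY_UNSTABLE")


class ContractError(RuntimeError):
    """A stage was invoked on a log terminated at an earlier stage."""


class Stage2Failure(str, enum.Enum):
    GAP_IN_SCHEDULE = "gap_in_schedule"
    INTERVAL_MISMATCH = "interval_mismatch"
    NO_PROPOSED_TIMES = "no_proposed_times"


class TerminalStage(enum.Enum):
    STAGE1 = 1
    STAGE2 = 2
    COMPLETE = "complete"


@dataclasses.dataclass(frozen=True)
class Stage2Result:
    failure_reasons: frozenset[Stage2Failure]

    @property
    def passed(self) -> bool:
        return not self.failure_reasons


@dataclasses.dataclass(frozen=True)
class Stage3Result:
    """Occasion counts for schedule-adherence timing on one log."""

    n_proposed: int
    n_exempted: int
    n_assessed: int
    n_met: int

    def __post_init__(self) -> None:
        if self.n_assessed != self.n_proposed - self.n_exempted:
            raise ValueError("n_assessed must equal n_proposed - n_exempted")
        if not (0 <= self.n_met <= self.n_assessed):
            raise ValueError("n_met out of range")


@dataclasses.dataclass(frozen=True)
class KQIResult:
    """Per-log staged outcome; fields beyond the terminal stage are absent."""

    log_id: str
    stage1_pass: bool
    stage2: Optional[Stage2Result] = None
    stage3: Optional[Stage3Result] = None
    stage4a_yes: Optional[int] = None
    stage4a_n: Optional[int] = None
    stage4b_yes: Optional[int] = None
    stage4b_n: Optional[int] = None
    terminal_stage: TerminalStage = TerminalStage.STAGE1

    def __post_init__(self) -> None:
        later = (self.stage3, self.stage4a_yes, self.stage4a_n,
                 self.stage4b_yes, self.stage4b_n)
        if not self.stage1_pass:
            if self.stage2 is not None or any(f is not None for f in later):
                raise ValueError("Stage-1 failure must leave later stages absent")
            if self.terminal_stage is not TerminalStage.STAGE1:
                raise ValueError("Stage-1 failure must terminate at stage 1")
        elif self.stage2 is not None and not self.stage2.passed:
            if any(f is not None for f in later):
                raise ValueError("Stage-2 failure must leave later stages absent")
            if self.terminal_stage is not TerminalStage.STAGE2:
                raise ValueError("Stage-2 failure must terminate at stage 2")

    @property
    def passed_stages_1_and_2(self) -> bool:
        return self.terminal_stage is TerminalStage.COMPLETE


@dataclasses.dataclass(frozen=True)
class KQIConfig:
    """Assessment parameters.

    ``window_minutes`` is the leeway for an actual void around its proposed
    time (inclusive: |actual − proposed| ≤ window). ``tolerance_minutes``
    relaxes the Stage-2 requirement that consecutive schedule gaps equal the
    interval exactly (default 0: exact to the minute). ``exemption_codes``
    lists the justification codes honoured at Stage 3.
    """

    window_minutes: int = 30
    tolerance_minutes: int = 0
    exemption_codes: frozenset[str] = frozenset(DEFAULT_EXEMPTION_CODES)
    day_start: int = DAY_START
    day_end: int = DAY_END

    def __post_init__(self) -> None:
        if self.window_minutes < 0 or self.tolerance_minutes < 0:
            raise ValueError("window/tolerance must be nonnegative")
        object.__setattr__(self, "exemption_codes", frozenset(self.exemption_codes))

    @classmethod
    def from_file(cls, path: str | Path) -> "KQIConfig":
        """Load from YAML or JSON (keys matching the field names)."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "window_minutes": self.window_minutes,
            "tolerance_minutes": self.tolerance_minutes,
            "exemption_codes": sorted(self.exemption_codes),
            "day_start": self.day_start,
            "day_end": self.day_end,
        }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def assess_stage1(log: ClinicalLog) -> bool:
    """True iff the voiding interval is a documented single value."""
    return log.interval.status is IntervalStatus.SINGLE


def assess_stage2(log: ClinicalLog, tolerance_minutes: int = 0) -> Stage2Result:
    """Check schedule completeness and arithmetic consistency.

    Requires Stage 1 to have passed (the interval value is the reference for
    the gap check). A schedule needs at least two proposed times to exhibit
    an interval at all; rows between the first and last proposed time with a
    blank proposed slot are gaps; consecutive proposed times must differ by
    the interval, to within ``tolerance_minutes``.

    Schedules that start after 07:30 or stop before 21:30 are not failed
    here: the indicator demands completeness between its own endpoints, not
    full-day span.
    """
    if not assess_stage1(log):
        raise ContractError("assess_stage2 requires a Stage-1 pass")
    reasons: set[Stage2Failure] = set()
    idx = [i for i, e in enumerate(log.events) if e.proposed_time is not None]
    if len(idx) < 2:
        return Stage2Result(frozenset({Stage2Failure.NO_PROPOSED_TIMES}))
    if any(log.events[i].proposed_time is None for i in range(idx[0], idx[-1] + 1)):
        reasons.add(Stage2Failure.GAP_IN_SCHEDULE)
    interval = log.interval.value_minutes
    proposed = [log.events[i].proposed_time for i in idx]
    if any(abs((b - a) - interval) > tolerance_minutes
           for a, b in zip(proposed, proposed[1:])):
        reasons.add(Stage2Failure.INTERVAL_MISMATCH)
    return Stage2Result(frozenset(reasons))


def _minutes(t: TimeOfDay | int) -> int:
    return int(t)


def match_voids(
    proposed: Sequence[TimeOfDay | int],
    actual: Sequence[TimeOfDay | int],
    window_minutes: int,
) -> set[int]:
    """Maximum one-to-one matching of actual voids to proposed slots.

    A pair is admissible iff |actual − proposed| ≤ ``window_minutes``
    (inclusive boundary). Both inputs must be sorted ascending. Returns the
    set of matched proposed indices.

    The greedy rule — walk proposed slots in order, take the earliest unused
    admissible actual — achieves maximum cardinality because admissibility
    windows are symmetric intervals on a line; this is verified against an
    exhaustive matching oracle in the test suite.
    """
    p = [_minutes(t) for t in proposed]
    a = [_minutes(t) for t in actual]
    matched: set[int] = set()
    used = [False] * len(a)
    j = 0
    for i, pt in enumerate(p):
        # skip actuals too early for this and all later proposed slots
        while j < len(a) and a[j] < pt - window_minutes:
            j += 1
        for k in range(j, len(a)):
            if used[k]:
                continue
            if a[k] > pt + window_minutes:
                break
            used[k] = True
            matched.add(i)
            break
    return matched


def assess_stage3(
    log: ClinicalLog,
    window_minutes: int = 30,
    exemption_codes: Iterable[str] = DEFAULT_EXEMPTION_CODES,
    tolerance_minutes: int = 0,
) -> Stage3Result:
    """Count proposed occasions met within the leeway window.

    Slots carrying an accepted justification code are exempted (removed from
    numerator and denominator). All documented actual voids — including any
    on exempted rows — remain available for matching: the patient did void
    then, and a neighbouring slot may legitimately claim it.
    """
    stage2 = assess_stage2(log, tolerance_minutes=tolerance_minutes)
    if not stage2.passed:
        raise ContractError("assess_stage3 requires Stages 1 and 2 to have passed")
    codes = frozenset(exemption_codes)
    slots = [e for e in log.events if e.proposed_time is not None]
    exempt = [e for e in slots if e.justification_code in codes]
    assessed = [e for e in slots if e.justification_code not in codes]
    proposed = sorted(e.proposed_time for e in assessed)
    actual = sorted(log.actual_times)
    n_met = len(match_voids(proposed, actual, window_minutes))
    return Stage3Result(
        n_proposed=len(slots),
        n_exempted=len(exempt),
        n_assessed=len(assessed),
        n_met=n_met,
    )


def assess_stage4(log: ClinicalLog) -> tuple[int, int, Optional[int], Optional[int]]:
    """Count literal "yes" answers over proposed occasions.

    Returns ``(stage4a_yes, stage4a_n, stage4b_yes, stage4b_n)``; the 4b
    pair is ``None`` for bladder-training logs. Missing and "no" both count
    as not-yes.
    """
    slots = [e for e in log.events if e.proposed_time is not None]
    n = len(slots)
    yes_4a = sum(1 for e in slots if e.encouragement is Answer.YES)
    if log.regime is Regime.PROMPTED_VOIDING:
        yes_4b = sum(1 for e in slots if e.wet_asked is Answer.YES)
        return yes_4a, n, yes_4b, n
    return yes_4a, n, None, None


def assess_log(log: ClinicalLog, config: KQIConfig = KQIConfig()) -> KQIResult:
    """Run the full staged assessment with early termination.

    A Stage-1 failure (missing/range/unparseable interval) terminates the
    log at Stage 1; a Stage-2 failure (incomplete or miscalculated schedule)
    terminates it at Stage 2; otherwise Stages 3 and 4 are scored.
    """
    if not assess_stage1(log):
        return KQIResult(log_id=log.log_id, stage1_pass=False,
                         terminal_stage=TerminalStage.STAGE1)
    stage2 = assess_stage2(log, tolerance_minutes=config.tolerance_minutes)
    if not stage2.passed:
        return KQIResult(log_id=log.log_id, stage1_pass=True, stage2=stage2,
                         terminal_stage=TerminalStage.STAGE2)
    stage3 = assess_stage3(log, window_minutes=config.window_minutes,
                           exemption_codes=config.exemption_codes,
                           tolerance_minutes=config.tolerance_minutes)
    yes_4a, n_4a, yes_4b, n_4b = assess_stage4(log)
    return KQIResult(
        log_id=log.log_id,
        stage1_pass=True,
        stage2=stage2,
        stage3=stage3,
        stage4a_yes=yes_4a,
        stage4a_n=n_4a,
        stage4b_yes=yes_4b,
        stage4b_n=n_4b,
        terminal_stage=TerminalStage.COMPLETE,
    )


def assess_fleet(
    logs: Iterable[ClinicalLog], config: KQIConfig = KQIConfig()
) -> list[KQIResult]:
    """Assess every log in a fleet."""
    return [assess_log(log, config) for log in logs]
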