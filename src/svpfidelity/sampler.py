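"""Stratified sampling of 14-day audit periods from a site's recruitment window.

The audit design splits each site's planned recruitment period into three
near-equal contiguous strata and draws two non-overlapping 14-day periods
from each; sites that extended recruitment gain additional strata covering
the extension (each at most one planned-stratum long), sampled the same way.
Three strata thus yield six periods, and extensions take a site plan up to
the observed range of six to nine periods. All clinical logs dated inside a
sampled period form the fidelity-audit sample.

Date ranges are half-open ``[start, end)``; a 14-day period covers exactly
14 calendar days. Periods within a stratum are drawn uniformly at random
over all valid ordered non-overlapping start-day pairs, which makes the
scheme reproducible for a fixed seed and testable against enumeration.
"""

from __future__ import annotations

import dataclasses
import datetime
import functools
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .logmodel import ClinicalLog

PERIOD_DAYS = 14
PERIODS_PER_STRATUM = 2
#: Site samples observed in practice span six to nine 14-day periods.
OBSERVED_PERIOD_RANGE = (6, 9)


class StratificationError(ValueError):
    """A stratum is too short to host a 14-day period."""


class SamplingError(ValueError):
    """A stratum cannot host two non-overlapping 14-day periods."""


@dataclasses.dataclass(frozen=True)
class DateRange:
    """Half-open calendar range [start, end)."""

    start: datetime.date
    end: datetime.date

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be after start")

    @property
    def days(self) -> int:
        return (self.end - self.start).days

    def contains(self, date: datetime.date) -> bool:
        return self.start <= date < self.end

    def overlaps(self, other: "DateRange") -> bool:
        return self.start < other.end and other.start < self.end


@dataclasses.dataclass(frozen=True)
class Period:
    """A sampled 14-day audit period and the stratum it came from."""

    range: DateRange
    stratum_index: int


@dataclasses.dataclass(frozen=True)
class SamplingPlan:
    site_id: str
    strata: tuple[DateRange, ...]
    periods: tuple[Period, ...]

    def __post_init__(self) -> None:
        for p in self.periods:
            if p.range.days != PERIOD_DAYS:
                raise ValueError("every period must be exactly 14 days")
            stratum = self.strata[p.stratum_index]
            if not (stratum.start <= p.range.start and p.range.end <= stratum.end):
                raise ValueError("period must lie wholly inside its stratum")
        for i, p in enumerate(self.periods):
            for q in self.periods[i + 1:]:
                if p.range.overlaps(q.range):
                    raise ValueError("periods must not overlap")

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def in_observed_range(self) -> bool:
        """Flags (does not enforce) the 6–9 periods seen across real sites."""
        lo, hi = OBSERVED_PERIOD_RANGE
        return lo <= self.n_periods <= hi

    def to_json(self, path: str | Path) -> None:
        payload = {
            "site_id": self.site_id,
            "strata": [[r.start.isoformat(), r.end.isoformat()] for r in self.strata],
            "periods": [
                {"start": p.range.start.isoformat(),
                 "end": p.range.end.isoformat(),
                 "stratum_index": p.stratum_index}
                for p in self.periods
            ],
            "in_observed_range": self.in_observed_range,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def build_strata(
    recruitment_start: datetime.date,
    planned_end: datetime.date,
    actual_end: datetime.date,
) -> list[DateRange]:
    """Split a recruitment window into sampling strata.

    The planned window is split into three near-equal contiguous strata
    (remainder days go to the last); recruitment extension beyond the
    planned end forms additional strata of at most one planned-stratum
    length each. Raises :class:`StratificationError` if any stratum is
    shorter than 14 days.
    """
    if not (recruitment_start < planned_end <= actual_end):
        raise ValueError("need recruitment_start < planned_end <= actual_end")
    planned_days = (planned_end - recruitment_start).days
    base = planned_days // 3
    lengths = [base, base, planned_days - 2 * base]

    extension_days = (actual_end - planned_end).days
    n_ext = math.ceil(extension_days / base) if extension_days else 0
    for k in range(n_ext):
        lengths.append(min(base, extension_days - k * base))

    strata: list[DateRange] = []
    cursor = recruitment_start
    for i, n in enumerate(lengths):
        if n < PERIOD_DAYS:
            raise StratificationError(
                f"stratum {i} spans {n} days; cannot host a {PERIOD_DAYS}-day period"
            )
        strata.append(DateRange(cursor, cursor + datetime.timedelta(days=n)))
        cursor = strata[-1].end
    return strata


@functools.lru_cache(maxsize=64)
def enumerate_start_pairs(stratum_days: int) -> tuple[tuple[int, int], ...]:
    """All ordered non-overlapping 14-day start-offset pairs in a stratum.

    Offsets are days from the stratum start; a pair ``(s1, s2)`` is valid
    when ``s2 >= s1 + 14`` and ``s2 + 14 <= stratum_days``. This enumeration
    is the sampling frame for :func:`sample_periods` and the oracle for its
    uniformity test.
    """
    last = stratum_days - PERIOD_DAYS
    return tuple((s1, s2)
                 for s1 in range(last + 1)
                 for s2 in range(s1 + PERIOD_DAYS, last + 1))


def sample_periods(
    strata: Sequence[DateRange], seed: int, site_id: str = ""
) -> SamplingPlan:
    """Draw two non-overlapping 14-day periods per stratum, uniformly.

    Within each stratum the pair of period start days is drawn uniformly
    over every valid non-overlapping pair (see
    :func:`enumerate_start_pairs`). Reproducible for a fixed seed. Raises
    :class:`SamplingError` for a stratum shorter than 28 days.
    """
    rng = np.random.default_rng(seed)
    periods: list[Period] = []
    for i, stratum in enumerate(strata):
        pairs = enumerate_start_pairs(stratum.days)
        if not pairs:
            raise SamplingError(
                f"stratum {i} spans {stratum.days} days; cannot host "
                f"{PERIODS_PER_STRATUM} non-overlapping {PERIOD_DAYS}-day periods"
            )
        s1, s2 = pairs[int(rng.integers(len(pairs)))]
        for s in (s1, s2):
            start = stratum.start + datetime.timedelta(days=s)
            periods.append(Period(
                range=DateRange(start, start + datetime.timedelta(days=PERIOD_DAYS)),
                stratum_index=i,
            ))
    return SamplingPlan(site_id=site_id, strata=tuple(strata), periods=tuple(periods))


def select_logs(
    logs: Sequence[ClinicalLog], plan: SamplingPlan
) -> list[ClinicalLog]:
    """Keep exactly the logs dated inside any sampled period, in input order."""
    return [log for log in logs
            if any(p.range.contains(log.date) for p in plan.periods)]
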