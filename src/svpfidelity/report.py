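"""Pooled per-arm summaries of staged KQI results.

Per-log results are grouped per site and then per trial arm and presented
pooled, with no adjustment for clustering by site or patient and no
inferential statistics — deliberately a simple descriptive summary.

Denominator conventions: Stage-1 and Stage-2 percentages are of *all* logs
in the arm; Stage-3 and Stage-4 percentages are computed only over logs that
passed Stages 1 and 2. "On average, how often…" is ambiguous between an
unweighted mean of per-log proportions and a pooled ratio of occasions; both
modes are provided (``stage_mode="per_log"``, the default, weights each
patient-day equally; ``"pooled"`` weights each occasion equally).

Percentages are rounded half-up to one decimal at presentation only;
aggregation is carried out at full precision. An undefined value (zero
denominator) is reported as ``None`` and rendered as an em dash, never as 0.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .kqi import KQIResult
from .logmodel import Arm, ClinicalLog, Regime


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int) -> Optional[float]:
    """100·numerator/denominator, rounded half-up to one decimal.

    Returns ``None`` (the undefined-value marker) when the denominator is
    zero; never raises a division error.
    """
    if denominator == 0:
        return None
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class ArmSummary:
    """One arm's row set of the fidelity results table."""

    arm: Arm
    n_logs: int
    n_patients: int
    pct_of_total_patients: Optional[float]
    pct_pv: Optional[float]
    pct_bt: Optional[float]
    stage1_pct: Optional[float]
    stage2_pct: Optional[float]
    n_pass12: int
    stage3_pct: Optional[float]
    stage4a_pct: Optional[float]
    stage4b_pct: Optional[float]
    mean_interval_hours: Optional[float]
    mean_n_proposed: Optional[float]
    n_stage3_undefined: int = 0  # passers with every occasion exempted
    stage_mode: str = "per_log"


@dataclasses.dataclass(frozen=True)
class IntervalDistribution:
    """Histogram of voiding intervals among Stage-1&2 passers."""

    arm: Arm
    counts: dict[int, int]  # interval minutes -> number of logs
    n_pass12: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_pass12:
            raise ValueError("interval counts must sum to n_pass12")


def _align(results: Sequence[KQIResult], logs: Sequence[ClinicalLog]):
    by_id = {r.log_id: r for r in results}
    missing = [log.log_id for log in logs if log.log_id not in by_id]
    if missing:
        raise ValueError(f"no KQI result for log(s): {missing[:5]}")
    return [(by_id[log.log_id], log) for log in logs]


def summarise_arm(
    results: Sequence[KQIResult],
    logs: Sequence[ClinicalLog],
    total_enrolled: int,
    stage_mode: str = "per_log",
) -> Optional[ArmSummary]:
    """Pool per-log results for one arm into a summary row set.

    ``total_enrolled`` is the arm's total patient enrolment, the denominator
    of the percent-of-patients row. Stage-3 averaging excludes passers whose
    every occasion was exempted (their proportion is undefined); their count
    is reported in ``n_stage3_undefined``. Returns ``None`` for empty input
    (the empty-summary marker).
    """
    if stage_mode not in ("per_log", "pooled"):
        raise ValueError(f"unknown stage_mode: {stage_mode!r}")
    if not logs:
        return None
    pairs = _align(results, logs)
    arms = {log.arm for _, log in pairs}
    if len(arms) > 1:
        raise ValueError("summarise_arm expects logs from a single arm")
    (arm,) = arms

    n_logs = len(pairs)
    patients = {log.patient_id for _, log in pairs}
    n_pv = sum(1 for _, log in pairs if log.regime is Regime.PROMPTED_VOIDING)
    n_s1 = sum(1 for r, _ in pairs if r.stage1_pass)
    passers = [(r, log) for r, log in pairs if r.passed_stages_1_and_2]
    n_pass12 = len(passers)

    def stage_pct(numers_denoms: list[tuple[int, int]]) -> Optional[float]:
        defined = [(a, b) for a, b in numers_denoms if b > 0]
        if not defined:
            return None
        if stage_mode == "pooled":
            return percent(sum(a for a, _ in defined), sum(b for _, b in defined))
        return _round_half_up(100 * sum(a / b for a, b in defined) / len(defined))

    s3_pairs = [(r.stage3.n_met, r.stage3.n_assessed) for r, _ in passers]
    s4a_pairs = [(r.stage4a_yes, r.stage4a_n) for r, _ in passers]
    s4b_pairs = [(r.stage4b_yes, r.stage4b_n) for r, _ in passers
                 if r.stage4b_n is not None]

    mean_interval = mean_proposed = None
    if passers:
        mean_interval = _round_half_up(
            sum(log.interval.value_minutes for _, log in passers) / n_pass12 / 60, 2)
        mean_proposed = _round_half_up(
            sum(len(log.proposed_times) for _, log in passers) / n_pass12, 2)

    return ArmSummary(
        arm=arm,
        n_logs=n_logs,
        n_patients=len(patients),
        pct_of_total_patients=percent(len(patients), total_enrolled),
        pct_pv=percent(n_pv, n_logs),
        pct_bt=percent(n_logs - n_pv, n_logs),
        stage1_pct=percent(n_s1, n_logs),
        stage2_pct=percent(n_pass12, n_logs),
        n_pass12=n_pass12,
        stage3_pct=stage_pct(s3_pairs),
        stage4a_pct=stage_pct(s4a_pairs),
        stage4b_pct=stage_pct(s4b_pairs),
        mean_interval_hours=mean_interval,
        mean_n_proposed=mean_proposed,
        n_stage3_undefined=sum(1 for _, b in s3_pairs if b == 0),
        stage_mode=stage_mode,
    )


def interval_distribution(
    results: Sequence[KQIResult], logs: Sequence[ClinicalLog]
) -> IntervalDistribution:
    """Histogram of interval values (minutes) among Stage-1&2 passers."""
    pairs = _align(results, logs)
    arms = {log.arm for _, log in pairs} or {Arm.INTERVENTION}
    if len(arms) > 1:
        raise ValueError("interval_distribution expects logs from a single arm")
    counts = Counter(
        log.interval.value_minutes
        for r, log in pairs if r.passed_stages_1_and_2
    )
    return IntervalDistribution(
        arm=next(iter(arms)),
        counts=dict(sorted(counts.items())),
        n_pass12=sum(counts.values()),
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

_TABLE_ROWS = [
    ("Number of clinical logs analysed", "n_logs", 0),
    ("Number of patients", "n_patients", 0),
    ("Percentage of total number of patients", "pct_of_total_patients", 1),
    ("% Prompted Voiding (PV)", "pct_pv", 1),
    ("% Bladder Training (BT)", "pct_bt", 1),
    ("STAGE 1: % with voiding interval present and correctly documented",
     "stage1_pct", 1),
    ("STAGE 2: % with interval and schedule present and correctly documented",
     "stage2_pct", 1),
    ("No. of clinical logs that achieved both Stage 1 and Stage 2", "n_pass12", 0),
    ("STAGE 3: % of occasions with actual void within the leeway window",
     "stage3_pct", 1),
    ("STAGE 4a: % of occasions with encouragement documented as given",
     "stage4a_pct", 1),
    ("STAGE 4b: % of occasions patient documented as asked if wet (PV only)",
     "stage4b_pct", 1),
    ("Mean voiding interval (hours)", "mean_interval_hours", 2),
    ("Mean number of proposed voiding times per log", "mean_n_proposed", 2),
]


def _cell(value, ndigits: int) -> str:
    if value is None:
        return "—"
    if ndigits == 0:
        return str(value)
    return f"{value:.{ndigits}f}"


def render_table(summaries: Sequence[ArmSummary]) -> str:
    """Human-readable results table, one column per arm."""
    headers = ["Trial arm"] + [s.arm.value for s in summaries]
    rows = [[label] + [_cell(getattr(s, field), nd) for s in summaries]
            for label, field, nd in _TABLE_ROWS]
    widths = [max(len(r[i]) for r in [headers] + rows) for i in range(len(headers))]
    def fmt(row):
        return "  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip()
    lines = [fmt(headers), fmt(["-" * w for w in widths])]
    lines += [fmt(r) for r in rows]
    return "\n".join(lines) + "\n"


def write_report(
    summaries: Sequence[ArmSummary],
    distributions: Sequence[IntervalDistribution],
    path: str | Path,
    table_path: str | Path | None = None,
) -> None:
    """Write the machine-readable JSON report and the human-readable table.

    ``path`` receives JSON; the table goes to ``table_path`` (default:
    ``path`` with a ``.txt`` suffix). Undefined values serialise as JSON
    ``null`` and render as an em dash.
    """
    path = Path(path)
    if table_path is None:
        table_path = path.with_suffix(".txt")
    payload = {
        "arms": [
            {**dataclasses.asdict(s), "arm": s.arm.value} for s in summaries
        ],
        "interval_distribution": {
            d.arm.value: {str(k): v for k, v in d.counts.items()}
            for d in distributions
        },
    }
    path.write_text(json.dumps(payload, indent=2, ensure_ascii=False),
                    encoding="utf-8")
    Path(table_path).write_text(render_table(summaries), encoding="utf-8")


def plot_interval_distribution(
    distributions: Sequence[IntervalDistribution], path: str | Path
) -> None:
    """Optional bar chart of the voiding-interval distribution per arm."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    all_intervals = sorted({k for d in distributions for k in d.counts})
    width = 0.8 / max(len(distributions), 1)
    for i, d in enumerate(distributions):
        xs = [j + i * width for j in range(len(all_intervals))]
        ys = [d.counts.get(k, 0) for k in all_intervals]
        ax.bar(xs, ys, width=width, label=d.arm.value)
    ax.set_xticks([j + width * (len(distributions) - 1) / 2
                   for j in range(len(all_intervals))])
    ax.set_xticklabels([f"{k / 60:g} h" for k in all_intervals])
    ax.set_xlabel("Voiding interval")
    ax.set_ylabel("Clinical logs (Stage 1 & 2 passers)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
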