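"""Pooled per-arm summaries: percent arithmetic, denominators, output."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svpfidelity import (
    Answer,
    assess_fleet,
    interval_distribution,
    percent,
    render_table,
    summarise_arm,
    write_report,
)
from conftest import make_log

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


class TestPercent:
    @pytest.mark.parametrize("num, den, expected", [
        (40, 164, 24.4),
        (31, 125, 24.8),
        (154, 396, 38.9),
        (102, 320, 31.9),   # 31.875 rounds half-up
        (0, 10, 0.0),
        (1, 8, 12.5),
    ])
    def test_rounds_half_up_to_one_decimal(self, num, den, expected):
        assert percent(num, den) == expected

    def test_zero_denominator_yields_undefined_marker(self):
        assert percent(5, 0) is None

    @given(b=st.integers(1, 10_000), a=st.integers(0, 10_000))
    def test_complement_sums_to_100_within_an_ulp(self, a, b):
        a = min(a, b)
        assert abs(percent(a, b) + percent(b - a, b) - 100.0) <= 0.1 + 1e-9


def _four_log_arm():
    """2 Stage-1 failures, 1 Stage-2 failure, 1 complete log with 3/4 met."""
    logs = [
        make_log("", [("08:00", None), ("10:00", None)],
                 log_id="L1", patient_id="P1"),
        make_log("2 – 3 hourly", [("08:00", None), ("10:00", None)],
                 log_id="L2", patient_id="P2"),
        make_log("3-hourly", [("08:00", None), ("10:00", None), ("12:00", None)],
                 log_id="L3", patient_id="P3"),
        make_log("2-hourly",
                 [("08:00", "08:05", {"encouragement": Answer.YES}),
                  ("10:00", "10:10", {"encouragement": Answer.YES}),
                  ("12:00", None),
                  ("14:00", "14:20", {"encouragement": Answer.NO})],
                 log_id="L4", patient_id="P4"),
    ]
    return assess_fleet(logs), logs


class TestSummariseArm:
    def test_worked_example_stage_percentages(self):
        results, logs = _four_log_arm()
        s = summarise_arm(results, logs, total_enrolled=8)
        assert s.stage1_pct == 50.0
        assert s.stage2_pct == 25.0
        assert s.n_pass12 == 1
        assert s.stage3_pct == 75.0
        assert s.stage4a_pct == 50.0
        assert s.pct_of_total_patients == 50.0
        assert s.mean_interval_hours == 2.0
        assert s.mean_n_proposed == 4.0

    def test_per_log_and_pooled_modes_diverge(self):
        logs = [
            make_log("2-hourly", [("08:00", "08:00"), ("10:00", "10:00")],
                     log_id="A", patient_id="P1"),     # 2/2
            make_log("2-hourly", [("08:00", "08:00"), ("10:00", "10:00"),
                                  ("12:00", None), ("14:00", None)],
                     log_id="B", patient_id="P2"),     # 2/4
        ]
        results = assess_fleet(logs)
        per_log = summarise_arm(results, logs, 2, stage_mode="per_log")
        pooled = summarise_arm(results, logs, 2, stage_mode="pooled")
        assert per_log.stage3_pct == 75.0
        assert pooled.stage3_pct == 66.7

    def test_fully_exempted_passer_excluded_from_stage3_average(self):
        logs = [
            make_log("2-hourly", [("08:00", "08:00"), ("10:00", "10:00")],
                     log_id="A", patient_id="P1"),
            make_log("2-hourly", [("08:00", None, {"code": "OFF_WARD"}),
                                  ("10:00", None, {"code": "OFF_WARD"})],
                     log_id="B", patient_id="P2"),
        ]
        s = summarise_arm(assess_fleet(logs), logs, 2)
        assert s.stage3_pct == 100.0
        assert s.n_stage3_undefined == 1

    def test_empty_input_yields_empty_marker(self):
        assert summarise_arm([], [], 10) is None

    def test_pv_bt_split_sums_to_100(self, small_fleet):
        _, fleet = small_fleet
        from svpfidelity import Arm
        arm_logs = [log for log in fleet if log.arm is Arm.INTERVENTION]
        s = summarise_arm(assess_fleet(arm_logs), arm_logs, 100)
        assert abs(s.pct_pv + s.pct_bt - 100.0) <= 0.1

    def test_per_log_mean_lies_between_extremes(self, small_fleet):
        _, fleet = small_fleet
        from svpfidelity import Arm
        arm_logs = [log for log in fleet if log.arm is Arm.INTERVENTION]
        results = assess_fleet(arm_logs)
        props = [100 * r.stage3.n_met / r.stage3.n_assessed for r in results
                 if r.stage3 is not None and r.stage3.n_assessed > 0]
        s = summarise_arm(results, arm_logs, 100)
        assert min(props) - 0.1 <= s.stage3_pct <= max(props) + 0.1


class TestIntervalDistribution:
    def test_mass_equals_pass12(self, small_fleet):
        _, fleet = small_fleet
        from svpfidelity import Arm
        arm_logs = [log for log in fleet if log.arm is Arm.INTERVENTION]
        results = assess_fleet(arm_logs)
        s = summarise_arm(results, arm_logs, 100)
        d = interval_distribution(results, arm_logs)
        assert sum(d.counts.values()) == d.n_pass12 == s.n_pass12

    def test_bars_count_passers_by_interval(self):
        logs = [make_log("2-hourly", [("08:00", None), ("10:00", None)],
                         log_id=f"A{i}", patient_id=f"P{i}") for i in range(3)]
        logs += [make_log("3-hourly", [("08:00", None), ("11:00", None)],
                          log_id="B", patient_id="PB")]
        d = interval_distribution(assess_fleet(logs), logs)
        assert d.counts == {120: 3, 180: 1}


class TestOutput:
    def test_json_round_trips_and_table_renders_dash(self, tmp_path):
        results, logs = _four_log_arm()
        s = summarise_arm(results, logs, total_enrolled=8)
        d = interval_distribution(results, logs)
        out = tmp_path / "report.json"
        write_report([s], [d], out)
        payload = json.loads(out.read_text())
        assert payload["arms"][0]["stage1_pct"] == 50.0
        assert payload["arms"][0]["stage4b_pct"] == s.stage4b_pct
        assert payload["interval_distribution"]["intervention"] == {"120": 1}
        table = (tmp_path / "report.txt").read_text()
        assert "intervention" in table

    def test_undefined_rendered_as_dash_not_zero(self):
        logs = [make_log("2 – 3 hourly", [("08:00", None), ("10:00", None)])]
        results = assess_fleet(logs)
        s = summarise_arm(results, logs, 10)
        table = render_table([s])
        row = next(line for line in table.splitlines() if "STAGE 3" in line)
        assert "—" in row and " 0.0" not in row
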