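"""Staged KQI assessment: stages 1–4, matching, termination, invariants."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svpfidelity import (
    Answer,
    ContractError,
    KQIConfig,
    Regime,
    Stage2Failure,
    TerminalStage,
    assess_fleet,
    assess_log,
    assess_stage1,
    assess_stage2,
    assess_stage3,
    assess_stage4,
    match_voids,
)
from conftest import make_log

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


FULL_2H = [(f"{h:02d}:30", None) for h in range(7, 22, 2)]  # 07:30 … 21:30


def brute_force_max_matching(proposed, actual, window):
    """Oracle: exhaustive maximum one-to-one matching cardinality."""
    for k in range(min(len(proposed), len(actual)), 0, -1):
        for ps in itertools.combinations(range(len(proposed)), k):
            for perm in itertools.permutations(range(len(actual)), k):
                if all(abs(actual[a] - proposed[p]) <= window
                       for p, a in zip(ps, perm)):
                    return k
    return 0


class TestStage1:
    @pytest.mark.parametrize("text, expected", [
        ("2-hourly", True),
        ("2 – 3 hourly", False),
        ("", False),
        ("whenever needed", False),
    ])
    def test_single_interval_required(self, text, expected):
        assert assess_stage1(make_log(text, FULL_2H)) is expected


class TestStage2:
    def test_miscalculated_schedule_fails_interval_mismatch(self):
        # 3-hourly prescribed but times written every 2 hours
        log = make_log("3-hourly", [("08:00", None), ("10:00", None), ("12:00", None)])
        result = assess_stage2(log)
        assert result.failure_reasons == {Stage2Failure.INTERVAL_MISMATCH}
        assert not result.passed

    def test_exact_schedule_passes(self):
        log = make_log("2-hourly", FULL_2H)
        assert assess_stage2(log).passed

    def test_blank_row_between_endpoints_is_a_gap(self):
        slots = [("09:30", None), (None, "11:35"), ("13:30", None), ("15:30", None)]
        result = assess_stage2(make_log("2-hourly", slots))
        assert Stage2Failure.GAP_IN_SCHEDULE in result.failure_reasons

    def test_single_proposed_time_fails(self):
        result = assess_stage2(make_log("2-hourly", [("08:00", None)]))
        assert result.failure_reasons == {Stage2Failure.NO_PROPOSED_TIMES}

    def test_short_day_span_alone_does_not_fail(self):
        # starts late and ends early, but complete and consistent
        log = make_log("2-hourly", [("10:00", None), ("12:00", None), ("14:00", None)])
        assert assess_stage2(log).passed

    def test_tolerance_parameter_relaxes_gap_equality(self):
        log = make_log("2-hourly", [("08:00", None), ("10:02", None), ("12:02", None)])
        assert not assess_stage2(log).passed
        assert assess_stage2(log, tolerance_minutes=2).passed

    def test_contract_violation_on_stage1_failure(self):
        with pytest.raises(ContractError):
            assess_stage2(make_log("2 – 3 hourly", FULL_2H))


class TestMatchVoids:
    def test_boundary_is_inclusive(self):
        assert match_voids([480], [510], 30) == {0}

    def test_no_admissible_pair(self):
        assert match_voids([480, 600], [540], 30) == set()

    def test_one_actual_cannot_satisfy_two_slots(self):
        assert len(match_voids([480, 530], [500], 30)) == 1

    @given(
        proposed=st.lists(st.integers(0, 600), max_size=5).map(sorted),
        actual=st.lists(st.integers(0, 600), max_size=5).map(sorted),
        window=st.sampled_from([0, 10, 30]),
    )
    def test_cardinality_equals_exhaustive_oracle(self, proposed, actual, window):
        got = len(match_voids(proposed, actual, window))
        assert got == brute_force_max_matching(proposed, actual, window)


class TestStage3:
    def test_exemption_arithmetic(self):
        slots = [
            ("07:30", "07:40"),
            ("09:30", "09:45"),
            ("11:30", None, {"code": "OFF_WARD"}),   # exempted
            ("13:30", "13:50"),
            ("15:30", None),                          # missed, not justified
        ]
        r = assess_stage3(make_log("2-hourly", slots))
        assert (r.n_proposed, r.n_exempted, r.n_assessed, r.n_met) == (5, 1, 4, 3)

    def test_all_slots_exempted_degenerates_to_zero_assessed(self):
        slots = [("07:30", None, {"code": "ASLEEP"}),
                 ("09:30", None, {"code": "ASLEEP"})]
        r = assess_stage3(make_log("2-hourly", slots))
        assert (r.n_assessed, r.n_met) == (0, 0)

    def test_unknown_code_is_not_exempted(self):
        slots = [("07:30", None, {"code": "NO_REASON"}), ("09:30", "09:31")]
        r = assess_stage3(make_log("2-hourly", slots))
        assert r.n_exempted == 0 and r.n_assessed == 2

    def test_contract_violation_on_terminated_log(self):
        log = make_log("3-hourly", [("08:00", None), ("10:00", None)])
        with pytest.raises(ContractError):
            assess_stage3(log)


class TestStage4:
    def test_counts_literal_yes_only(self):
        answers = [Answer.YES, Answer.YES, Answer.MISSING,
                   Answer.NO, Answer.YES, Answer.YES]
        slots = [(f"{7 + 2 * i:02d}:30", None, {"encouragement": a})
                 for i, a in enumerate(answers)]
        yes_a, n_a, yes_b, n_b = assess_stage4(make_log("2-hourly", slots))
        assert (yes_a, n_a) == (4, 6)
        assert (yes_b, n_b) == (0, 6)

    def test_bladder_training_has_no_wet_question(self):
        log = make_log("2-hourly", FULL_2H, regime=Regime.BLADDER_TRAINING)
        _, _, yes_b, n_b = assess_stage4(log)
        assert yes_b is None and n_b is None

    def test_all_yes_saturates(self):
        slots = [(p, a, {"encouragement": Answer.YES, "wet": Answer.YES})
                 for p, a in FULL_2H]
        yes_a, n_a, yes_b, n_b = assess_stage4(make_log("2-hourly", slots))
        assert yes_a == n_a == yes_b == n_b == len(FULL_2H)


class TestAssessLog:
    def test_range_interval_terminates_at_stage1(self):
        r = assess_log(make_log("2 – 3 hourly", FULL_2H))
        assert r.terminal_stage is TerminalStage.STAGE1
        assert r.stage2 is None and r.stage3 is None and r.stage4a_n is None

    def test_miscalculated_schedule_terminates_at_stage2(self):
        log = make_log("3-hourly", [("08:00", None), ("10:00", None), ("12:00", None)])
        r = assess_log(log)
        assert r.terminal_stage is TerminalStage.STAGE2
        assert r.stage2.failure_reasons == {Stage2Failure.INTERVAL_MISMATCH}
        assert r.stage3 is None

    def test_fully_correct_log_completes(self):
        slots = [(p, p.replace(":30", ":40"), {"encouragement": Answer.YES})
                 for p, _ in FULL_2H]
        r = assess_log(make_log("2-hourly", slots))
        assert r.terminal_stage is TerminalStage.COMPLETE
        assert r.stage3.n_met == r.stage3.n_assessed == len(FULL_2H)
        assert r.stage4a_yes == len(FULL_2H)

    def test_determinism(self):
        log = make_log("2-hourly", FULL_2H)
        assert assess_log(log) == assess_log(log)


class TestFleetInvariants:
    def test_monotone_filtration_and_exemption_conservation(self, small_fleet):
        _, fleet = small_fleet
        results = assess_fleet(fleet)
        n_all = len(results)
        n_s1 = sum(r.stage1_pass for r in results)
        n_s2_assessed = sum(r.stage2 is not None for r in results)
        n_s2_passed = sum(r.stage2 is not None and r.stage2.passed for r in results)
        n_s3_assessed = sum(r.stage3 is not None for r in results)
        assert n_s2_assessed <= n_s1 <= n_all
        assert n_s3_assessed == n_s2_passed
        for r in results:
            if r.stage3 is not None:
                assert r.stage3.n_exempted + r.stage3.n_assessed == r.stage3.n_proposed


def test_config_loads_from_yaml(tmp_path):
    path = tmp_path / "kqi.yaml"
    path.write_text(
        "window_minutes: 20\ntolerance_minutes: 1\nexemption_codes: [X1, X2]\n")
    cfg = KQIConfig.from_file(path)
    assert cfg.window_minutes == 20
    assert cfg.tolerance_minutes == 1
    assert cfg.exemption_codes == frozenset({"X1", "X2"})
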