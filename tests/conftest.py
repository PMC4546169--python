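import datetime

import pytest

from svpfidelity import (
    Answer,
    Arm,
    ClinicalLog,
    Regime,
    SimulationConfig,
    TimeOfDay,
    VoidingEvent,
    generate_fleet,
    parse_interval,
)


def make_event(proposed=None, actual=None, encouragement=Answer.MISSING,
               wet=Answer.MISSING, code=None, regime=Regime.PROMPTED_VOIDING):
    if regime is Regime.BLADDER_TRAINING:
        wet = Answer.NOT_APPLICABLE
    return VoidingEvent(
        proposed_time=TimeOfDay.parse(proposed) if proposed else None,
        actual_time=TimeOfDay.parse(actual) if actual else None,
        encouragement=encouragement,
        wet_asked=wet,
        justification_code=code,
    )


def make_log(interval_text="2-hourly", slots=(), regime=Regime.PROMPTED_VOIDING,
             log_id="L1", patient_id="P1", site_id="I1", arm=Arm.INTERVENTION,
             date=datetime.date(2011, 3, 1)):
    """Build a clinical log from (proposed, actual[, kwargs]) slot tuples."""
    events = []
    for slot in slots:
        proposed, actual, *rest = slot
        kwargs = rest[0] if rest else {}
        events.append(make_event(proposed, actual, regime=regime, **kwargs))
    return ClinicalLog(
        log_id=log_id, patient_id=patient_id, site_id=site_id, arm=arm,
        date=date, regime=regime, interval=parse_interval(interval_text),
        events=tuple(events),
    )


@pytest.fixture(scope="session")
def small_fleet():
    """A 160-log fleet under the default documentation-error conditions."""
    cfg = SimulationConfig(n_sites_per_arm=2, n_patients_per_site=4,
                           days_per_patient=10, seed=7)
    return cfg, generate_fleet(cfg)
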