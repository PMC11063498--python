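import numpy as np
import pytest
from hypothesis import settings

from ipreface import (
    BloodGasPanel,
    DecelerationEvent,
    FiveTierRuleTable,
    LaborCase,
    solve_blood_gas,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table() -> FiveTierRuleTable:
    return FiveTierRuleTable.default()


def make_event(onset=100.0, duration=60.0, decel_type="variable", severity="mild",
               baseline_rate="normal", variability="moderate", level=None,
               level_override=None) -> DecelerationEvent:
    return DecelerationEvent(
        onset=onset, duration=duration, decel_type=decel_type, severity=severity,
        baseline_rate=baseline_rate, variability=variability, level=level,
        level_override=level_override,
    )


def make_case(case_id="C1", events=(), recording_end=7200.0, decision_time=5400.0,
              removal_time=6600.0, delivery_time=9600.0, ph=7.30, **kw) -> LaborCase:
    pco2 = kw.pop("pco2", 48.0)
    hco3 = 0.03 * pco2 * 10 ** (ph - 6.1)
    bg = BloodGasPanel(ph=ph, pco2=pco2, po2=16.0, hco3=hco3,
                       be=hco3 - 24.4 + 14.83 * (ph - 7.4), lactate=2.5)
    fields = dict(
        case_id=case_id, events=tuple(events), recording_start=0.0,
        recording_end=recording_end, decision_time=decision_time,
        removal_time=removal_time, delivery_time=delivery_time,
        maternal_age=33.0, parity=0, gestational_week=40.0, induction=True,
        vacuum=False, blood_gas=bg, apgar1=8, apgar5=9, nicu_asphyxia=False,
    )
    fields.update(kw)
    return LaborCase(**fields)


@pytest.fixture
def three_case_cohort(table):
    from ipreface import classify_level
    evs1 = [classify_level(make_event(onset=4000 + 300 * i), table) for i in range(3)]
    evs2 = [classify_level(make_event(onset=5000, decel_type="late", severity="severe"),
                           table)]
    return [
        make_case("A", evs1),
        make_case("B", evs2, ph=7.12, pco2=62.0),
        make_case("C", (), ph=7.35),
    ]


def pair_count_auc(scores, outcomes) -> float:
    """O(n^2) Mann-Whitney AUC oracle: ties count one half."""
    pos = [s for s, y in zip(scores, outcomes) if y]
    neg = [s for s, y in zip(scores, outcomes) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
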