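import itertools

import pytest

from pona_tdm.classification import MolecularResponseBand as MR
from pona_tdm.dosing import (
    Action,
    CVRisk,
    DoseRecommendation,
    Mutation,
    PatientState,
    evaluate_policy_on_cohort,
    recommend,
    recommend_adjustment,
    recommend_starting_dose,
    starting_dose_mg,
)
from pona_tdm.exceptions import DomainError

RISKS = list(CVRisk)
MUTATIONS = list(Mutation)
BANDS = list(MR)


def state(**kw):
    defaults = dict(cv_risk=CVRisk.LOW, current_dose_mg=None)
    defaults.update(kw)
    return PatientState(**defaults)


@pytest.mark.parametrize(
    "risk, mutation, mr, expected",
    [
        (CVRisk.HIGH, Mutation.NONE_DETECTED, MR.MR3, Action.START_15),
        (CVRisk.VERY_HIGH, Mutation.NONE_DETECTED, MR.DMR, Action.START_15),
        (CVRisk.HIGH, Mutation.NONE_DETECTED, MR.MR2, Action.START_30),
        (CVRisk.LOW, Mutation.T315I, MR.BELOW_MR2, Action.START_45),
        (CVRisk.MODERATE, Mutation.COMPOUND, MR.MR3, Action.START_45),
        (CVRisk.MODERATE, Mutation.NONE_DETECTED, MR.MR2, Action.START_30),
        (CVRisk.LOW, Mutation.NONE_DETECTED, MR.DMR, Action.START_30),
    ],
)
def test_starting_dose_rules(risk, mutation, mr, expected):
    rec = recommend_starting_dose(state(cv_risk=risk, mutation=mutation, current_mr=mr))
    assert rec.action is expected
    assert rec.rationale


def test_missing_risk_gives_insufficient_information():
    rec = recommend_starting_dose(state(cv_risk=None))
    assert rec.action is Action.INSUFFICIENT_INFORMATION


def test_t315i_in_high_risk_is_flagged_not_escalated():
    rec = recommend_starting_dose(
        state(cv_risk=CVRisk.HIGH, mutation=Mutation.T315I, current_mr=MR.BELOW_MR2)
    )
    assert rec.action is Action.START_30
    assert any("WARN" in r for r in rec.rationale)


def test_starting_dose_requires_no_current_dose():
    with pytest.raises(DomainError):
        recommend_starting_dose(state(current_dose_mg=30))


@pytest.mark.parametrize(
    "kw, expected, strict",
    [
        (dict(cv_risk=CVRisk.HIGH, current_dose_mg=30, months_on_current_dose=6,
              current_mr=MR.MR3, cmin_ng_per_ml=12.0), Action.REDUCE_TO_15, True),
        (dict(cv_risk=CVRisk.LOW, current_dose_mg=30, months_on_current_dose=8,
              current_mr=MR.MR3, cmin_ng_per_ml=15.0), Action.REDUCE_TO_15, True),
        (dict(cv_risk=CVRisk.LOW, current_dose_mg=45, months_on_current_dose=3,
              current_mr=MR.DMR, cmin_ng_per_ml=15.0), Action.REDUCE_TO_15, False),
        (dict(cv_risk=CVRisk.LOW, current_dose_mg=30, months_on_current_dose=8,
              current_mr=MR.MR3, cmin_ng_per_ml=None), Action.MAINTAIN, False),
        (dict(cv_risk=CVRisk.HIGH, current_dose_mg=45, months_on_current_dose=2,
              current_mr=MR.BELOW_MR2, worst_active_ae_grade=3),
         Action.INTERRUPT_THEN_RESTART_REDUCED, False),
    ],
)
def test_adjustment_rules(kw, expected, strict):
    rec = recommend_adjustment(state(**kw))
    assert rec.action is expected
    if expected is Action.REDUCE_TO_15:
        assert rec.strict_molecular_monitoring is strict


def test_grade3_ae_steps_one_rung_down_the_ladder():
    for dose, restart in ((45, 30), (30, 15), (15, 15)):
        rec = recommend_adjustment(
            state(current_dose_mg=dose, worst_active_ae_grade=4)
        )
        assert rec.action is Action.INTERRUPT_THEN_RESTART_REDUCED
        assert rec.restart_dose_mg == restart


def test_cmin_threshold_is_strictly_greater_than():
    base = dict(cv_risk=CVRisk.LOW, current_dose_mg=30, months_on_current_dose=8, current_mr=MR.MR3)
    assert recommend_adjustment(state(cmin_ng_per_ml=10.71, **base)).action is Action.REDUCE_TO_15
    assert recommend_adjustment(state(cmin_ng_per_ml=10.7, **base)).action is Action.MAINTAIN
    assert recommend_adjustment(state(cmin_ng_per_ml=10.69, **base)).action is Action.MAINTAIN


def test_low_trough_on_15mg_flagged_without_escalation():
    rec = recommend_adjustment(
        state(current_dose_mg=15, current_mr=MR.MR3, cmin_ng_per_ml=8.0)
    )
    assert rec.action is Action.MAINTAIN
    assert any("NO_ESCALATION" in r for r in rec.rationale)


def test_adjustment_requires_valid_dose():
    with pytest.raises(DomainError):
        recommend_adjustment(state(current_dose_mg=None))
    with pytest.raises(DomainError):
        recommend_adjustment(state(current_dose_mg="interrupted"))


def _starting_lattice():
    for risk, mutation, mr in itertools.product(RISKS, MUTATIONS, BANDS):
        yield state(cv_risk=risk, mutation=mutation, current_mr=mr)


def test_starting_lattice_total_and_deterministic():
    """48 categorical combinations: every one yields a definite recommendation."""
    recs = [recommend_starting_dose(s) for s in _starting_lattice()]
    assert len(recs) == 48
    assert all(r.action is not Action.INSUFFICIENT_INFORMATION for r in recs)
    again = [recommend_starting_dose(s) for s in _starting_lattice()]
    assert recs == again


def test_starting_dose_monotone_in_cv_risk():
    """With everything else fixed, higher cardiovascular risk never yields a
    higher starting dose."""
    order = {CVRisk.LOW: 0, CVRisk.MODERATE: 1, CVRisk.HIGH: 2, CVRisk.VERY_HIGH: 3}
    for mutation, mr in itertools.product(MUTATIONS, BANDS):
        doses = [
            starting_dose_mg(recommend_starting_dose(state(cv_risk=r, mutation=mutation, current_mr=mr)))
            for r in sorted(RISKS, key=order.get)
        ]
        assert all(b <= a for a, b in zip(doses, doses[1:]))


def test_adjustment_lattice_total_and_audit_trace():
    """Every combination of dose, risk, response, toxicity grade, time on dose
    and boundary trough values yields exactly one action, re-derivable from
    the final rationale code."""
    final_code_to_action = {
        "ADJUST_GRADE3PLUS_AE_INTERRUPT_RESTART_REDUCED": Action.INTERRUPT_THEN_RESTART_REDUCED,
        "ADJUST_30MG_6MO_MR3_CMIN_ABOVE_REDUCE_15": Action.REDUCE_TO_15,
        "ADJUST_LOW_MOD_RISK_MR3_CMIN_ABOVE_REDUCE_15": Action.REDUCE_TO_15,
        "ADJUST_NO_RULE_FIRED_MAINTAIN": Action.MAINTAIN,
    }
    n = 0
    for risk, dose, mr, months, cmin, grade in itertools.product(
        RISKS, (45, 30, 15), BANDS, (0.0, 5.9, 6.0, 12.0),
        (None, 10.69, 10.7, 10.71), (0, 2, 3)
    ):
        rec = recommend_adjustment(
            state(cv_risk=risk, current_dose_mg=dose, current_mr=mr,
                  months_on_current_dose=months, cmin_ng_per_ml=cmin,
                  worst_active_ae_grade=grade)
        )
        assert isinstance(rec, DoseRecommendation)
        assert final_code_to_action[rec.rationale[-1]] is rec.action
        n += 1
    assert n == 4 * 3 * 4 * 4 * 4 * 3


def test_evaluate_policy_on_cohort_collects_errors():
    states = [
        state(cv_risk=CVRisk.HIGH, current_mr=MR.MR3),
        state(cv_risk=CVRisk.LOW, current_dose_mg="interrupted"),
        state(cv_risk=CVRisk.LOW, current_dose_mg=30, current_mr=MR.MR3,
              months_on_current_dose=8, cmin_ng_per_ml=15.0),
    ]
    recs, summary, errors = evaluate_policy_on_cohort(states)
    assert len(recs) == 3 and recs[1] is None
    assert summary["start_15"] == 1 and summary["reduce_to_15"] == 1
    assert len(errors) == 1 and errors[0][0] == 1


def test_evaluate_policy_on_empty_cohort():
    recs, summary, errors = evaluate_policy_on_cohort([])
    assert recs == [] and not summary and not errors


def test_dispatch_by_dose_state():
    assert recommend(state(cv_risk=CVRisk.HIGH, current_mr=MR.MR3)).action is Action.START_15
    assert recommend(state(current_dose_mg=45, worst_active_ae_grade=0)).action is Action.MAINTAIN
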