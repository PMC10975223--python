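"""Cardiovascular-risk-stratified ponatinib dose-choice rule engine.

Starting dose is chosen from the patient's SCORE2/SCORE2-OP cardiovascular
risk category, BCR::ABL1 mutation status, and current molecular response;
on-treatment adjustment combines toxicity (CTCAE grade), response depth,
time on dose, and the measured/predicted trough.  Every recommendation
carries an ordered trace of fired-rule identifiers so the action can be
audited and re-derived from the trace alone.

The trough cut-off used by the reduction rules is the rounded clinical value
10.7 ng/mL (20 nM at 532.56 g/mol is 10.65 ng/mL unrounded) compared with a
strict ``>``, unlike the inclusive banding used for attainment statistics;
both conventions are deliberate and documented.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .classification import MolecularResponseBand
from .exceptions import DomainError

#: strict-comparison trough threshold for dose-reduction rules, ng/mL
CMIN_REDUCTION_THRESHOLD_NG_ML = 10.7

#: descending dose ladder used for "restart at reduced dose"
DOSE_LADDER_MG = (45, 30, 15)


class CVRisk(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    VERY_HIGH = "very_high"


class Mutation(str, Enum):
    NONE_DETECTED = "none_detected"
    T315I = "T315I"
    COMPOUND = "compound"


class SwitchReason(str, Enum):
    RESISTANCE = "resistance"
    INTOLERANCE = "intolerance"


class Action(str, Enum):
    START_15 = "start_15"
    START_30 = "start_30"
    START_45 = "start_45"
    REDUCE_TO_15 = "reduce_to_15"
    MAINTAIN = "maintain"
    INTERRUPT_THEN_RESTART_REDUCED = "interrupt_then_restart_reduced"
    INSUFFICIENT_INFORMATION = "insufficient_information"


_START_DOSE_MG = {Action.START_15: 15, Action.START_30: 30, Action.START_45: 45}


@dataclass(frozen=True)
class PatientState:
    """Snapshot of one patient at a decision point."""

    cv_risk: Optional[CVRisk]
    mutation: Mutation = Mutation.NONE_DETECTED
    current_mr: MolecularResponseBand = MolecularResponseBand.BELOW_MR2
    months_on_current_dose: float = 0.0
    current_dose_mg: Optional[int | str] = None  # 45 | 30 | 15 | "interrupted" | None
    cmin_ng_per_ml: Optional[float] = None
    worst_active_ae_grade: int = 0
    switch_reason: SwitchReason = SwitchReason.RESISTANCE

    def __post_init__(self):
        if self.months_on_current_dose < 0:
            raise DomainError("months_on_current_dose must be >= 0")
        if not (0 <= self.worst_active_ae_grade <= 5):
            raise DomainError("worst_active_ae_grade must lie in [0, 5]")
        if self.cmin_ng_per_ml is not None and (
            not math.isfinite(self.cmin_ng_per_ml) or self.cmin_ng_per_ml < 0
        ):
            raise DomainError("cmin_ng_per_ml must be finite and >= 0 when present")
        if self.current_dose_mg not in (None, "interrupted", 45, 30, 15):
            raise DomainError(f"current_dose_mg must be 45/30/15/'interrupted'/None, got {self.current_dose_mg!r}")


@dataclass(frozen=True)
class DoseRecommendation:
    action: Action
    strict_molecular_monitoring: bool = False
    rationale: tuple[str, ...] = ()
    restart_dose_mg: Optional[int] = None

    def __post_init__(self):
        if self.action is not Action.INSUFFICIENT_INFORMATION and not self.rationale:
            raise DomainError("rationale must be non-empty unless insufficient_information")


def recommend_starting_dose(state: PatientState) -> DoseRecommendation:
    """Starting-dose choice for a patient not yet on ponatinib.

    High / very-high cardiovascular risk: 15 mg/day if molecular response is
    at least MR3, otherwise 30 mg/day.  Low / moderate risk: 30 mg/day, or
    45 mg/day when a T315I or compound mutation is demonstrated.
    """
    if state.current_dose_mg is not None:
        raise DomainError("recommend_starting_dose requires current_dose_mg = None")
    if state.cv_risk is None:
        return DoseRecommendation(action=Action.INSUFFICIENT_INFORMATION)

    trace: list[str] = [f"EVAL_CV_RISK:{state.cv_risk.value}", f"EVAL_MUTATION:{state.mutation.value}",
                        f"EVAL_MR:{state.current_mr.name}"]
    if state.cv_risk in (CVRisk.HIGH, CVRisk.VERY_HIGH):
        if state.mutation in (Mutation.T315I, Mutation.COMPOUND):
            # the 45 mg option is restricted to the low/moderate branch;
            # flag the tension rather than escalate in a high-risk patient
            trace.append("WARN_RESISTANT_MUTATION_IN_HIGH_CV_RISK")
        if state.current_mr >= MolecularResponseBand.MR3:
            trace.append("START_HIGH_RISK_MR3_OR_BETTER_15MG")
            return DoseRecommendation(Action.START_15, rationale=tuple(trace))
        trace.append("START_HIGH_RISK_BELOW_MR3_30MG")
        return DoseRecommendation(Action.START_30, rationale=tuple(trace))
    if state.mutation in (Mutation.T315I, Mutation.COMPOUND):
        trace.append("START_LOW_MOD_RISK_RESISTANT_MUTATION_45MG")
        return DoseRecommendation(Action.START_45, rationale=tuple(trace))
    trace.append("START_LOW_MOD_RISK_30MG")
    return DoseRecommendation(Action.START_30, rationale=tuple(trace))


def recommend_adjustment(state: PatientState) -> DoseRecommendation:
    """On-treatment adjustment; first matching rule wins.

    1. Active grade >= 3 toxicity: interrupt, then restart one step down the
       45/30/15 ladder.
    2. 30 mg/day for >= 6 months with at least MR3 and trough > 10.7 ng/mL:
       reduce to 15 mg/day with strict molecular monitoring.
    3. Low/moderate risk on 45 or 30 mg/day with at least MR3 and trough
       > 10.7 ng/mL: reduce to 15 mg/day.
    4. Otherwise maintain.  An absent trough disables rules 2-3; a patient on
       15 mg/day with trough <= 10.7 is flagged, not escalated (no escalation
       rule is defined).
    """
    if state.current_dose_mg not in (45, 30, 15):
        raise DomainError(
            f"recommend_adjustment requires current_dose_mg in {{45, 30, 15}}, got {state.current_dose_mg!r}"
        )
    trace: list[str] = [f"EVAL_AE_GRADE:{state.worst_active_ae_grade}"]
    if state.worst_active_ae_grade >= 3:
        idx = DOSE_LADDER_MG.index(state.current_dose_mg)
        restart = DOSE_LADDER_MG[min(idx + 1, len(DOSE_LADDER_MG) - 1)]
        trace.append("ADJUST_GRADE3PLUS_AE_INTERRUPT_RESTART_REDUCED")
        return DoseRecommendation(
            Action.INTERRUPT_THEN_RESTART_REDUCED,
            rationale=tuple(trace),
            restart_dose_mg=restart,
        )
    trace += [f"EVAL_DOSE:{state.current_dose_mg}", f"EVAL_MR:{state.current_mr.name}",
              f"EVAL_CMIN:{'absent' if state.cmin_ng_per_ml is None else state.cmin_ng_per_ml}"]
    cmin_above = (
        state.cmin_ng_per_ml is not None
        and state.cmin_ng_per_ml > CMIN_REDUCTION_THRESHOLD_NG_ML
    )
    mr3_plus = state.current_mr >= MolecularResponseBand.MR3
    if (
        state.current_dose_mg == 30
        and state.months_on_current_dose >= 6
        and mr3_plus
        and cmin_above
    ):
        trace.append("ADJUST_30MG_6MO_MR3_CMIN_ABOVE_REDUCE_15")
        return DoseRecommendation(
            Action.REDUCE_TO_15, strict_molecular_monitoring=True, rationale=tuple(trace)
        )
    if (
        state.cv_risk in (CVRisk.LOW, CVRisk.MODERATE)
        and state.current_dose_mg in (45, 30)
        and mr3_plus
        and cmin_above
    ):
        trace.append("ADJUST_LOW_MOD_RISK_MR3_CMIN_ABOVE_REDUCE_15")
        return DoseRecommendation(Action.REDUCE_TO_15, rationale=tuple(trace))
    if (
        state.current_dose_mg == 15
        and state.cmin_ng_per_ml is not None
        and not cmin_above
    ):
        trace.append("FLAG_15MG_TROUGH_AT_OR_BELOW_THRESHOLD_NO_ESCALATION_RULE")
    trace.append("ADJUST_NO_RULE_FIRED_MAINTAIN")
    return DoseRecommendation(Action.MAINTAIN, rationale=tuple(trace))


def recommend(state: PatientState) -> DoseRecommendation:
    """Dispatch: starting-dose choice when off drug, adjustment when on drug."""
    if state.current_dose_mg is None:
        return recommend_starting_dose(state)
    return recommend_adjustment(state)


def starting_dose_mg(rec: DoseRecommendation) -> Optional[int]:
    """Numeric starting dose implied by a recommendation, if any."""
    return _START_DOSE_MG.get(rec.action)


def evaluate_policy_on_cohort(
    states: Iterable[PatientState],
) -> tuple[list[DoseRecommendation | None], Counter, list[tuple[int, str]]]:
    """Row-wise application of :func:`recommend`.

    Returns (recommendations, action frequency counter, collected per-row
    errors as (row index, message)); rows that fail validation yield ``None``
    in the recommendation list rather than being silently dropped.
    """
    recs: list[DoseRecommendation | None] = []
    errors: list[tuple[int, str]] = []
    summary: Counter = Counter()
    for i, state in enumerate(states):
        try:
            rec = recommend(state)
        except DomainError as exc:
            errors.append((i, str(exc)))
            recs.append(None)
            continue
        recs.append(rec)
        summary[rec.action.value] += 1
    return recs, summary, errors
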