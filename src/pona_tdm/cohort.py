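"""Synthetic assessment cohorts for ponatinib TDM analyses.

Two generators:

* :func:`generate_cohort` draws stochastic cohorts with the study's
  statistical structure — dose-occasion allocation over 45/30/15 mg/day,
  log-normal between-subject PK variability, random outpatient sampling
  times, combined residual assay error with LLOQ flagging at 5 ng/mL,
  logistic molecular-response models on log trough (slope 0 by default,
  mirroring the observed null association), and per-dose adverse-event
  models.  Fully reproducible from the seed.

* :func:`counts_matched_fixture` builds a deterministic 38-row table whose
  marginal and cross counts reproduce the published cohort exactly (dose
  groups 9/17/12; threshold attainment 8/14/5 at 10.7 ng/mL and 4/6/0 at
  21.3 ng/mL; MR3 per dose 3/12/10; DMR per dose 2/6/7; MR3 16/27 vs 9/11
  and DMR 10/27 vs 5/11 across the 10.7 ng/mL split; MR3 6/10 and DMR 5/10
  above 21.3 ng/mL; 13 adverse events in 9 patients split 7/4/2 by dose,
  5 haematological / 8 extra-haematological, 6 of grade >= 3).  The joint
  3-way allocation is under-determined by the printed margins; the fixture
  takes the lexicographic minimum over the allocation vector found by an
  exhaustive integer-feasibility search, so it is unique and stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import classify_cmin, classify_molecular_response
from .exceptions import FixtureInfeasibleError, SchemaError
from .map_estimation import LLOQ_NG_PER_ML, DEFAULT_PRIOR, PopulationPrior
from .pk import DosingRegimen, steady_state_pre_dose_state

#: column schema shared with the estimation input (plus outcome columns)
ASSESSMENT_COLUMNS = (
    "patient_id",
    "dose_mg",
    "tau_h",
    "t_since_dose_h",
    "conc_ng_ml",
    "bloq_flag",
    "true_cmin",
    "predicted_cmin",
    "is_percent",
    "mr_band",
    "ae_grades",
    "ae_categories",
)

#: representative IS% value per response stratum used by the generators
IS_PERCENT_BY_STRATUM = {"below_mr3": 0.5, "mr3": 0.05, "dmr": 0.005}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the stochastic generator.

    Defaults reproduce the study's structure: allocation over 45/30/15
    mg/day proportional to the published 9/17/12 dose occasions, sampling
    time uniform on [0, 24] h, molecular-response probabilities matching the
    published marginal rates (MR3 25/38, DMR 15/25 of MR3) with zero slope
    on log trough, and per-dose adverse-event rates echoing the published
    7/9, 4/17, 2/12 event tallies.
    """

    n_patients: int = 38
    dose_allocation: Mapping[int, float] = field(
        default_factory=lambda: {45: 9 / 38, 30: 17 / 38, 15: 12 / 38}
    )
    prior: PopulationPrior = DEFAULT_PRIOR
    sampling_time_range_h: tuple[float, float] = (0.0, 24.0)
    tau_h: float = 24.0
    mr3_intercept: float = float(np.log((25 / 38) / (1 - 25 / 38)))
    mr3_slope_per_log_cmin: float = 0.0
    dmr_given_mr3_intercept: float = float(np.log(0.6 / 0.4))
    dmr_given_mr3_slope_per_log_cmin: float = 0.0
    ae_prob_by_dose: Mapping[int, float] = field(
        default_factory=lambda: {45: 7 / 9, 30: 4 / 17, 15: 2 / 12}
    )
    ae_grade3plus_prob: float = 6 / 13
    ae_hematological_prob: float = 5 / 13
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_patients < 1:
            problems.append(f"n_patients must be >= 1, got {self.n_patients}")
        alloc = dict(self.dose_allocation)
        if any(not (0 <= p <= 1) for p in alloc.values()):
            problems.append(f"dose_allocation probabilities must lie in [0, 1]: {alloc}")
        if abs(sum(alloc.values()) - 1.0) > 1e-9:
            problems.append(f"dose_allocation must sum to 1, got {sum(alloc.values())}")
        lo, hi = self.sampling_time_range_h
        if not (0 <= lo < hi <= self.tau_h):
            problems.append(
                f"sampling_time_range_h must satisfy 0 <= lo < hi <= tau_h, got {(lo, hi)}"
            )
        for name in ("ae_grade3plus_prob", "ae_hematological_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                problems.append(f"{name} must lie in [0, 1], got {v}")
        if any(not (0 <= p <= 1) for p in dict(self.ae_prob_by_dose).values()):
            problems.append(f"ae_prob_by_dose probabilities must lie in [0, 1]")
        if problems:
            raise SchemaError(problems)


def _true_cmin(params, dose_mg: float, tau_h: float) -> float:
    """Exact steady-state trough (linear fixed point) for a subject's parameters."""
    x = steady_state_pre_dose_state(params, DosingRegimen(dose_mg, tau_h), iterate=False)
    return float(x[params.n_transit + 1] / params.Vc * 1000.0)


def _conc_at(params, dose_mg: float, tau_h: float, t: float) -> float:
    from .pk import concentration_at

    return concentration_at(params, DosingRegimen(dose_mg, tau_h), t)


def generate_cohort(config: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """Draw a stochastic cohort of dose-occasion assessments."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    prior = config.prior
    names = prior.eta_names
    cov = prior.covariance()
    doses = sorted(config.dose_allocation)
    probs = [config.dose_allocation[d] for d in doses]
    lo, hi = config.sampling_time_range_h

    rows = []
    for i in range(config.n_patients):
        dose = int(rng.choice(doses, p=probs))
        eta_vec = rng.multivariate_normal(np.zeros(len(names)), cov) if names else np.zeros(0)
        eta = dict(zip(names, eta_vec))
        params = prior.theta.with_log_deviations(eta)
        true_cmin = _true_cmin(params, dose, config.tau_h)
        t = float(rng.uniform(lo, hi))
        f = _conc_at(params, dose, config.tau_h, t)
        measured = f * (1.0 + prior.sigma_prop * rng.standard_normal()) + (
            prior.sigma_add * rng.standard_normal()
        )
        measured = max(measured, 0.0)
        bloq = measured < LLOQ_NG_PER_ML

        log_cmin = math.log(max(true_cmin, 1e-12))
        p_mr3 = 1.0 / (1.0 + math.exp(-(config.mr3_intercept + config.mr3_slope_per_log_cmin * log_cmin)))
        mr3 = rng.random() < p_mr3
        if mr3:
            p_dmr = 1.0 / (
                1.0
                + math.exp(
                    -(config.dmr_given_mr3_intercept + config.dmr_given_mr3_slope_per_log_cmin * log_cmin)
                )
            )
            stratum = "dmr" if rng.random() < p_dmr else "mr3"
        else:
            stratum = "below_mr3"
        is_percent = IS_PERCENT_BY_STRATUM[stratum]

        grades: list[int] = []
        categories: list[str] = []
        if rng.random() < config.ae_prob_by_dose.get(dose, 0.0):
            grades.append(3 if rng.random() < config.ae_grade3plus_prob else 2)
            categories.append(
                "hematological" if rng.random() < config.ae_hematological_prob else "extra_hematological"
            )
        rows.append(
            {
                "patient_id": f"S{i + 1:04d}",
                "dose_mg": dose,
                "tau_h": config.tau_h,
                "t_since_dose_h": t,
                "conc_ng_ml": measured,
                "bloq_flag": bloq,
                "true_cmin": true_cmin,
                "predicted_cmin": np.nan,
                "is_percent": is_percent,
                "mr_band": classify_molecular_response(is_percent).name,
                "ae_grades": ";".join(map(str, grades)),
                "ae_categories": ";".join(categories),
            }
        )
    return pd.DataFrame(rows, columns=list(ASSESSMENT_COLUMNS))


# ---------------------------------------------------------------------------
# Counts-matched fixture
# ---------------------------------------------------------------------------

_DOSES = (45, 30, 15)
# trough bands: L < 10.7 <= M < 21.3 <= H (ng/mL); cell totals per dose from
# the published per-dose attainment counts (8/14/5 at 10.7; 4/6/0 at 21.3)
_BAND_TOTALS = {45: {"L": 1, "M": 4, "H": 4}, 30: {"L": 3, "M": 8, "H": 6}, 15: {"L": 7, "M": 5, "H": 0}}
# representative trough per band: midpoints of the display thresholds, and
# 25.0 for the open top band (statistics depend only on band membership)
_BAND_VALUE = {"L": 8.0, "M": 16.0, "H": 25.0}
_MR3_BY_DOSE = {45: 3, 30: 12, 15: 10}   # MR3 or deeper
_DMR_BY_DOSE = {45: 2, 30: 6, 15: 7}
_MR3_LOW, _MR3_HIGHMID = 9, 16          # MR3 split across the 10.7 ng/mL attainment margin
_DMR_LOW, _DMR_HIGHMID = 5, 10
_MR3_TOP, _DMR_TOP = 6, 5               # above 21.3 ng/mL
# 13 adverse events in 9 patients: per-dose event totals and per-patient
# grouping (45 mg: 2+2+2+1, 30 mg: 2+1+1, 15 mg: 1+1)
_AE_EVENTS_BY_DOSE = {45: (2, 2, 2, 1), 30: (2, 1, 1), 15: (1, 1)}
_AE_TOTAL, _AE_GRADE3PLUS, _AE_HEMATOLOGICAL = 13, 6, 5


def _solve_allocation() -> dict[tuple[int, str], tuple[int, int]]:
    """Exhaustive search for the joint dose x band x response allocation.

    Returns per (dose, band) a pair (n_mr3_only, n_dmr); the remainder of the
    cell is below MR3.  Depth-first in increasing cell order yields the
    lexicographic minimum over the flattened allocation vector.  Raises
    :class:`FixtureInfeasibleError` listing the constraint set if the printed
    margins were jointly infeasible.
    """
    # per dose, enumerate (L, M, H) cell assignments consistent with the
    # per-dose MR3 and DMR totals, in lexicographic order of the flattened
    # (m3, dm) vector; then combine doses under the global margin splits
    def dose_options(d: int):
        caps = [_BAND_TOTALS[d][b] for b in ("L", "M", "H")]
        opts = []
        for m3L in range(caps[0] + 1):
            for dmL in range(caps[0] - m3L + 1):
                for m3M in range(caps[1] + 1):
                    for dmM in range(caps[1] - m3M + 1):
                        for m3H in range(caps[2] + 1):
                            for dmH in range(caps[2] - m3H + 1):
                                m3 = m3L + m3M + m3H
                                dm = dmL + dmM + dmH
                                if m3 + dm == _MR3_BY_DOSE[d] and dm == _DMR_BY_DOSE[d]:
                                    opts.append(((m3L, dmL), (m3M, dmM), (m3H, dmH)))
        return opts

    solution: dict[tuple[int, str], tuple[int, int]] = {}

    options = {d: dose_options(d) for d in _DOSES}

    def combine() -> bool:
        for o45 in options[45]:
            for o30 in options[30]:
                for o15 in options[15]:
                    chosen = {45: o45, 30: o30, 15: o15}
                    mr3_low = sum(chosen[d][0][0] + chosen[d][0][1] for d in _DOSES)
                    dmr_low = sum(chosen[d][0][1] for d in _DOSES)
                    mr3_top = sum(chosen[d][2][0] + chosen[d][2][1] for d in _DOSES)
                    dmr_top = sum(chosen[d][2][1] for d in _DOSES)
                    if (
                        mr3_low == _MR3_LOW
                        and dmr_low == _DMR_LOW
                        and mr3_top == _MR3_TOP
                        and dmr_top == _DMR_TOP
                    ):
                        for d in _DOSES:
                            for b, pair in zip(("L", "M", "H"), chosen[d]):
                                solution[(d, b)] = pair
                        return True
        return False

    if not combine():
        raise FixtureInfeasibleError(
            "published margins jointly infeasible: "
            f"band totals {_BAND_TOTALS}, MR3 by dose {_MR3_BY_DOSE}, DMR by dose {_DMR_BY_DOSE}, "
            f"MR3 split {_MR3_LOW}/{_MR3_HIGHMID}, DMR split {_DMR_LOW}/{_DMR_HIGHMID}, "
            f"top-band MR3 {_MR3_TOP}, DMR {_DMR_TOP}"
        )
    return solution


def counts_matched_fixture() -> pd.DataFrame:
    """Deterministic 38-row assessment table reproducing the published counts."""
    alloc = _solve_allocation()
    rows = []
    for d in _DOSES:
        for b in ("L", "M", "H"):
            total = _BAND_TOTALS[d][b]
            m3, dm = alloc[(d, b)]
            below = total - m3 - dm
            cmin = _BAND_VALUE[b]
            for stratum, count in (("dmr", dm), ("mr3", m3), ("below_mr3", below)):
                for _ in range(count):
                    is_pct = IS_PERCENT_BY_STRATUM[stratum]
                    rows.append(
                        {
                            "dose_mg": d,
                            "tau_h": 24.0,
                            "t_since_dose_h": 24.0,
                            "conc_ng_ml": cmin,
                            "bloq_flag": cmin < LLOQ_NG_PER_ML,
                            "true_cmin": cmin,
                            "predicted_cmin": cmin,
                            "is_percent": is_pct,
                            "mr_band": classify_molecular_response(is_pct).name,
                            "ae_grades": "",
                            "ae_categories": "",
                        }
                    )
    df = pd.DataFrame(rows)

    # 32 patients over 38 occasions: six IDs recur at a second dose level.
    # Rows are in canonical (dose, band, response) order; the first 32 rows
    # get fresh IDs and the last six reuse P01..P06 (which fall in the 45/30
    # mg groups, so each recurrence is at a different dose).
    ids = [f"P{i + 1:02d}" for i in range(32)] + [f"P{i + 1:02d}" for i in range(6)]
    df.insert(0, "patient_id", ids)

    # 13 adverse events in 9 patients (7/4/2 by dose); events are numbered in
    # a fixed order: the first 6 are grade 3, the rest grade 2; the first 5
    # are haematological, the rest extra-haematological.
    event_idx = 0
    for d in _DOSES:
        dose_rows = df.index[df["dose_mg"] == d].tolist()
        for p, n_events in enumerate(_AE_EVENTS_BY_DOSE[d]):
            grades, cats = [], []
            for _ in range(n_events):
                grades.append("3" if event_idx < _AE_GRADE3PLUS else "2")
                cats.append("hematological" if event_idx < _AE_HEMATOLOGICAL else "extra_hematological")
                event_idx += 1
            df.loc[dose_rows[p], "ae_grades"] = ";".join(grades)
            df.loc[dose_rows[p], "ae_categories"] = ";".join(cats)
    assert event_idx == _AE_TOTAL

    return df[list(ASSESSMENT_COLUMNS)]


def validate_assessments(df: pd.DataFrame) -> None:
    """Schema validation for an assessment table; raises :class:`SchemaError`."""
    problems = []
    missing = [c for c in ASSESSMENT_COLUMNS if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
        raise SchemaError(problems)
    if (pd.to_numeric(df["conc_ng_ml"], errors="coerce") < 0).any():
        problems.append("conc_ng_ml contains negative values")
    if df["conc_ng_ml"].isna().any():
        problems.append("conc_ng_ml contains missing values")
    for idx, row in df.iterrows():
        expected = classify_molecular_response(float(row["is_percent"])).name
        if row["mr_band"] != expected:
            problems.append(
                f"row {idx}: mr_band {row['mr_band']!r} inconsistent with is_percent {row['is_percent']}"
            )
    if problems:
        raise SchemaError(problems)


def write_assessments_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_assessments_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    df["ae_grades"] = df["ae_grades"].fillna("").astype(str)
    df["ae_categories"] = df["ae_categories"].fillna("").astype(str)
    validate_assessments(df)
    return df
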