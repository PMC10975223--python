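"""End-to-end cohort analysis: classification, cross-tabulation, exact tests.

Ingests an assessment table (one row per dose-occasion, the study's unit of
analysis), bands trough concentrations and molecular response, builds the
dose x attainment and response x attainment contingency tables, runs the
exact tests (reporting the Pearson chi-squared alongside, since published
r x c p-values may follow either convention), and emits a structured report
in which every rendered number is traceable to a stored table.

Percentages are rendered to 1 decimal place, round-half-up, with the raw
fractions always carried alongside.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classification import MolecularResponseBand, display_round
from .cohort import validate_assessments
from .exact_stats import (
    ContingencyTable,
    fisher_exact_two_sided,
    freeman_halton_exact,
    pearson_chi2,
)
from .exceptions import DomainError

#: trough column used for attainment; the fixture and MAP pathways fill both
CMIN_COLUMN = "true_cmin"


@dataclass(frozen=True)
class Fraction:
    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator if self.denominator else float("nan")

    @property
    def percent(self) -> float:
        return display_round(100.0 * self.value, 1)


@dataclass(frozen=True)
class TableTestResult:
    """A stored contingency table with every p-value derived from it."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]
    fractions: tuple[Fraction, ...]
    test: str
    p_exact: Optional[float]
    chi2_statistic: Optional[float]
    chi2_df: Optional[int]
    p_chi2: Optional[float]
    note: str = ""

    def table(self) -> ContingencyTable:
        return ContingencyTable(np.array(self.counts), self.rows, self.cols)


def _mr_reached(df: pd.DataFrame, level: str) -> pd.Series:
    bands = df["mr_band"].map(lambda b: MolecularResponseBand[b])
    if level == "MR3":
        return bands >= MolecularResponseBand.MR3
    if level == "DMR":
        return bands == MolecularResponseBand.DMR
    raise DomainError(f"level must be 'MR3' or 'DMR', got {level!r}")


def _cmin(df: pd.DataFrame) -> pd.Series:
    return pd.to_numeric(df[CMIN_COLUMN])


def attainment_by_dose(df: pd.DataFrame, threshold_ng_ml: float) -> TableTestResult:
    """Dose-group x (attained, not attained) table with exact test.

    Attainment is inclusive (trough >= threshold).  With a single dose group
    only descriptives are returned (test marked not applicable).
    """
    doses = sorted(df["dose_mg"].unique(), reverse=True)
    attained = _cmin(df) >= threshold_ng_ml
    counts, fracs = [], []
    for d in doses:
        sub = df["dose_mg"] == d
        n_att = int((sub & attained).sum())
        n_tot = int(sub.sum())
        counts.append((n_att, n_tot - n_att))
        fracs.append(Fraction(n_att, n_tot))
    rows = tuple(f"{d} mg" for d in doses)
    cols = (f">= {threshold_ng_ml} ng/mL", f"< {threshold_ng_ml} ng/mL")
    if len(doses) < 2:
        return TableTestResult(rows, cols, tuple(counts), tuple(fracs),
                               test="not_applicable", p_exact=None,
                               chi2_statistic=None, chi2_df=None, p_chi2=None,
                               note="single dose group: descriptives only")
    arr = np.array(counts)
    if (arr.sum(axis=0) == 0).any():
        # degenerate column (e.g. threshold 0): all tables equally extreme
        return TableTestResult(rows, cols, tuple(counts), tuple(fracs),
                               test="freeman_halton_exact", p_exact=1.0,
                               chi2_statistic=0.0, chi2_df=len(doses) - 1, p_chi2=1.0,
                               note="degenerate margin: p = 1 by convention")
    t = ContingencyTable(arr, rows, cols)
    chi2 = pearson_chi2(t)
    return TableTestResult(rows, cols, tuple(map(tuple, counts)), tuple(fracs),
                           test="freeman_halton_exact",
                           p_exact=freeman_halton_exact(t),
                           chi2_statistic=chi2.statistic, chi2_df=chi2.df, p_chi2=chi2.p)


def mr_by_threshold(df: pd.DataFrame, threshold_ng_ml: float, level: str) -> TableTestResult:
    """2 x 2 attainment x response table with two-sided Fisher exact test."""
    attained = _cmin(df) >= threshold_ng_ml
    if attained.all() or (~attained).all():
        raise DomainError(
            f"both sides of the {threshold_ng_ml} ng/mL split must be non-empty"
        )
    reached = _mr_reached(df, level)
    counts, fracs = [], []
    for side in (attained, ~attained):
        n_r = int((side & reached).sum())
        n_tot = int(side.sum())
        counts.append((n_r, n_tot - n_r))
        fracs.append(Fraction(n_r, n_tot))
    rows = (f">= {threshold_ng_ml} ng/mL", f"< {threshold_ng_ml} ng/mL")
    cols = (f"{level} reached", f"{level} not reached")
    t = ContingencyTable(np.array(counts), rows, cols)
    chi2 = pearson_chi2(t)
    return TableTestResult(rows, cols, tuple(map(tuple, counts)), tuple(fracs),
                           test="fisher_exact_two_sided",
                           p_exact=fisher_exact_two_sided(t),
                           chi2_statistic=chi2.statistic, chi2_df=chi2.df, p_chi2=chi2.p)


def mr_by_dose(df: pd.DataFrame, level: str) -> TableTestResult:
    """Dose-group x response table with exact test."""
    doses = sorted(df["dose_mg"].unique(), reverse=True)
    reached = _mr_reached(df, level)
    counts, fracs = [], []
    for d in doses:
        sub = df["dose_mg"] == d
        n_r = int((sub & reached).sum())
        n_tot = int(sub.sum())
        counts.append((n_r, n_tot - n_r))
        fracs.append(Fraction(n_r, n_tot))
    rows = tuple(f"{d} mg" for d in doses)
    cols = (f"{level} reached", f"{level} not reached")
    if len(doses) < 2:
        return TableTestResult(rows, cols, tuple(counts), tuple(fracs),
                               test="not_applicable", p_exact=None,
                               chi2_statistic=None, chi2_df=None, p_chi2=None,
                               note="single dose group: descriptives only")
    arr = np.array(counts)
    if (arr.sum(axis=0) == 0).any():
        return TableTestResult(rows, cols, tuple(map(tuple, counts)), tuple(fracs),
                               test="freeman_halton_exact", p_exact=1.0,
                               chi2_statistic=0.0, chi2_df=len(doses) - 1, p_chi2=1.0,
                               note="degenerate margin: p = 1 by convention")
    t = ContingencyTable(arr, rows, cols)
    chi2 = pearson_chi2(t)
    return TableTestResult(rows, cols, tuple(map(tuple, counts)), tuple(fracs),
                           test="freeman_halton_exact",
                           p_exact=freeman_halton_exact(t),
                           chi2_statistic=chi2.statistic, chi2_df=chi2.df, p_chi2=chi2.p)


def _parse_events(df: pd.DataFrame) -> tuple[list[int], list[str]]:
    grades, cats = [], []
    for g, c in zip(df["ae_grades"].fillna(""), df["ae_categories"].fillna("")):
        gl = [int(x) for x in str(g).split(";") if x]
        cl = [x for x in str(c).split(";") if x]
        grades += gl
        cats += cl
    return grades, cats


def summarize_cohort(df: pd.DataFrame) -> dict:
    """Descriptive block: dose-group sizes, concentration summaries, AE tallies."""
    if df.empty:
        raise DomainError("summarize_cohort requires a non-empty table")
    conc = _cmin(df)
    out: dict = {"n_assessments": int(len(df)), "n_patients": int(df["patient_id"].nunique())}
    per_dose = {}
    for d in sorted(df["dose_mg"].unique(), reverse=True):
        sub = conc[df["dose_mg"] == d]
        frac = Fraction(int(len(sub)), int(len(df)))
        per_dose[f"{int(d)} mg"] = {
            "n": int(len(sub)),
            "share_percent": frac.percent,
            "mean": float(sub.mean()),
            "sd": float(sub.std(ddof=1)) if len(sub) > 1 else None,
            "median": float(sub.median()),
            "range": [float(sub.min()), float(sub.max())],
        }
    out["per_dose"] = per_dose
    out["overall"] = {
        "mean": float(conc.mean()),
        "sd": float(conc.std(ddof=1)) if len(conc) > 1 else None,
        "sd_undefined": len(conc) <= 1,
        "median": float(conc.median()),
        "range": [float(conc.min()), float(conc.max())],
    }
    grades, cats = _parse_events(df)
    out["adverse_events"] = {
        "n_events": len(grades),
        "n_patients_with_events": int(
            (df["ae_grades"].fillna("").astype(str).str.len() > 0).sum()
        ),
        "by_grade": {str(g): grades.count(g) for g in sorted(set(grades))},
        "grade_3_plus": sum(1 for g in grades if g >= 3),
        "by_category": {c: cats.count(c) for c in sorted(set(cats))},
    }
    return out


@dataclass(frozen=True)
class AnalysisReport:
    descriptives: dict
    attainment: dict[str, TableTestResult]
    mr_by_threshold_tables: dict[str, TableTestResult]
    mr_by_dose_tables: dict[str, TableTestResult]
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def conv(o):
            if isinstance(o, TableTestResult):
                d = asdict(o)
                d["fractions"] = [
                    {"numerator": f.numerator, "denominator": f.denominator,
                     "percent": f.percent} for f in o.fractions
                ]
                return d
            return o

        return {
            "descriptives": self.descriptives,
            "attainment": {k: conv(v) for k, v in self.attainment.items()},
            "mr_by_threshold": {k: conv(v) for k, v in self.mr_by_threshold_tables.items()},
            "mr_by_dose": {k: conv(v) for k, v in self.mr_by_dose_tables.items()},
            "provenance": self.provenance,
        }

    def render_markdown(self) -> str:
        j = self.to_json_dict()
        lines = ["# Cohort analysis report", "",
                 f"Assessments: {j['descriptives']['n_assessments']}, "
                 f"patients: {j['descriptives']['n_patients']}", ""]
        for section, title in (("attainment", "Threshold attainment by dose"),
                               ("mr_by_threshold", "Molecular response by threshold"),
                               ("mr_by_dose", "Molecular response by dose")):
            lines.append(f"## {title}")
            for key, res in j[section].items():
                fr = ", ".join(
                    f"{r}: {f['numerator']}/{f['denominator']} ({f['percent']}%)"
                    for r, f in zip(res["rows"], res["fractions"])
                )
                p = res["p_exact"]
                p_txt = "n/a" if p is None else f"{p:.3f}"
                chi_txt = "" if res["p_chi2"] is None else f" (Pearson chi2 p = {res['p_chi2']:.3f})"
                lines.append(f"- {key}: {fr}; exact p = {p_txt}{chi_txt}")
            lines.append("")
        return "\n".join(lines)


def run_report(
    assessments: pd.DataFrame | str,
    *,
    thresholds_ng_ml: tuple[float, float] = (10.7, 21.3),
    seed: Optional[int] = None,
) -> AnalysisReport:
    """Full deterministic analysis of an assessment table (path or DataFrame)."""
    if isinstance(assessments, (str, bytes)) or hasattr(assessments, "__fspath__"):
        from .cohort import read_assessments_csv

        df = read_assessments_csv(assessments)
    else:
        df = assessments.copy()
        validate_assessments(df)
    # canonical row order: the report (including float summations and the
    # provenance hash) is exactly invariant to input row order
    df = df.sort_values(by=list(df.columns)).reset_index(drop=True)

    attainment = {
        f"{thr} ng/mL": attainment_by_dose(df, thr) for thr in thresholds_ng_ml
    }
    mr_thr = {}
    for thr in thresholds_ng_ml:
        for level in ("MR3", "DMR"):
            mr_thr[f"{level} x {thr} ng/mL"] = mr_by_threshold(df, thr, level)
    mr_dose = {level: mr_by_dose(df, level) for level in ("MR3", "DMR")}

    digest = hashlib.sha256(
        pd.util.hash_pandas_object(df.reset_index(drop=True), index=False).values.tobytes()
    ).hexdigest()[:16]
    provenance = {
        "software_version": __version__,
        "input_hash": digest,
        "thresholds_ng_ml": list(thresholds_ng_ml),
        "seed": seed,
        "cmin_column": CMIN_COLUMN,
    }
    return AnalysisReport(
        descriptives=summarize_cohort(df),
        attainment=attainment,
        mr_by_threshold_tables=mr_thr,
        mr_by_dose_tables=mr_dose,
        provenance=provenance,
    )


def write_report(report: AnalysisReport, json_path, markdown_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2)
    if markdown_path is not None:
        with open(markdown_path, "w") as fh:
            fh.write(report.render_markdown())
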