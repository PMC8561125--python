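"""Clinical cardiovascular-health (CVH) scoring.

Converts clinical measurements into per-factor poor/intermediate/ideal
categories and a summed clinical CVH score in 0-8 (0 points for poor, 1 for
intermediate, 2 for ideal across BMI, blood pressure, total cholesterol and
fasting glucose measured at the same examination), following the American
Heart Association criteria.  Pediatric rules apply age- and sex-specific
percentiles: BMI below age 20, blood pressure below age 18.  Percentiles are
accepted as inputs through a pluggable provider — computing them from CDC /
pediatric-guideline reference tables is out of scope; the default provider
simply requires them to be present on the record (as the synthetic generator
supplies).

An exam contributes a score only when all four factors are categorizable
("complete"); subjects with no complete exam are excluded from modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ExamRecord",
    "ScoredExam",
    "InclusionReport",
    "POOR",
    "INTERMEDIATE",
    "IDEAL",
    "categorize_bmi",
    "categorize_bp",
    "categorize_cholesterol",
    "categorize_glucose",
    "clinical_cvh_score",
    "score_dataset",
    "apply_completeness_filter",
]

POOR, INTERMEDIATE, IDEAL = 0, 1, 2
_CATEGORY_NAMES = {POOR: "poor", INTERMEDIATE: "intermediate", IDEAL: "ideal"}

#: ages below which the pediatric (percentile) rules apply
BMI_PEDIATRIC_AGE = 20.0
BP_PEDIATRIC_AGE = 18.0


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


@dataclass(frozen=True)
class ExamRecord:
    """One subject-visit with clinical measurements and medication flags."""

    subject_id: str
    age: float
    cohort: str = ""
    sex: str = ""
    race: str = ""
    bmi: float | None = None
    bmi_pct: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    bp_pct: float | None = None
    total_chol: float | None = None
    glucose: float | None = None
    bp_med: bool = False
    lipid_med: bool = False
    glucose_med: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.age < 120.0:
            raise ValueError(f"age {self.age} outside [0, 120)")
        for name in ("bmi_pct", "bp_pct"):
            v = getattr(self, name)
            if not _missing(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        for name in ("bmi", "sbp", "dbp", "total_chol", "glucose"):
            v = getattr(self, name)
            if not _missing(v) and v < 0:
                raise ValueError(f"{name}={v} must be nonnegative")


@dataclass(frozen=True)
class ScoredExam:
    """Per-factor categories and the summed clinical CVH score.

    ``categories`` maps factor name to 0/1/2 points (absent when the factor
    could not be categorized); ``score`` is their sum, present only when the
    exam is complete (all four factors categorized).
    """

    categories: dict[str, int | None]
    complete: bool = field(init=False)
    score: int | None = field(init=False)

    def __post_init__(self) -> None:
        vals = [self.categories.get(f) for f in ("bmi", "bp", "total_chol", "glucose")]
        complete = all(v is not None for v in vals)
        object.__setattr__(self, "complete", complete)
        object.__setattr__(self, "score", int(sum(vals)) if complete else None)


# ---------------------------------------------------------------------------
# per-factor categorization
# ---------------------------------------------------------------------------


def categorize_bmi(age: float, bmi: float | None, bmi_pct: float | None = None) -> int | None:
    """BMI category: adult thresholds at 25/30 kg/m^2; pediatric (<20 y)
    percentile thresholds at the 85th/95th.  Returns None if the required
    input is missing."""
    if age < BMI_PEDIATRIC_AGE:
        if _missing(bmi_pct):
            return None
        if bmi_pct > 95.0:
            return POOR
        return INTERMEDIATE if bmi_pct >= 85.0 else IDEAL
    if _missing(bmi):
        return None
    if bmi >= 30.0:
        return POOR
    return INTERMEDIATE if bmi >= 25.0 else IDEAL


def categorize_bp(
    age: float,
    sbp: float | None,
    dbp: float | None,
    bp_pct: float | None = None,
    bp_med: bool = False,
) -> int | None:
    """Blood-pressure category.

    Adults (>=18 y): poor if SBP >= 140 or DBP >= 90; ideal only below 120/80
    and unmedicated (treated-to-ideal counts as intermediate).  Children
    (<18 y): poor above the 95th percentile; ideal below the 90th percentile
    provided SBP < 120 and DBP < 80 and unmedicated; intermediate otherwise
    (the absolute clause demotes a sub-90th-percentile reading).
    """
    if age < BP_PEDIATRIC_AGE:
        if _missing(bp_pct) or _missing(sbp) or _missing(dbp):
            return None
        if bp_pct > 95.0:
            return POOR
        if bp_pct < 90.0 and sbp < 120.0 and dbp < 80.0 and not bp_med:
            return IDEAL
        return INTERMEDIATE
    if _missing(sbp) or _missing(dbp):
        return None
    if sbp >= 140.0 or dbp >= 90.0:
        return POOR
    if sbp < 120.0 and dbp < 80.0 and not bp_med:
        return IDEAL
    return INTERMEDIATE


def categorize_cholesterol(total_chol: float | None, lipid_med: bool = False) -> int | None:
    """Total cholesterol: poor >= 220 mg/dL; ideal < 185 unmedicated;
    intermediate 185-219 or treated to < 185."""
    if _missing(total_chol):
        return None
    if total_chol >= 220.0:
        return POOR
    if total_chol < 185.0 and not lipid_med:
        return IDEAL
    return INTERMEDIATE


def categorize_glucose(glucose: float | None, glucose_med: bool = False) -> int | None:
    """Fasting glucose: poor >= 126 mg/dL; ideal < 100 unmedicated;
    intermediate 100-125 or treated to < 100."""
    if _missing(glucose):
        return None
    if glucose >= 126.0:
        return POOR
    if glucose < 100.0 and not glucose_med:
        return IDEAL
    return INTERMEDIATE


def clinical_cvh_score(record: ExamRecord) -> ScoredExam:
    """Categorize all four factors of one exam and sum the points."""
    return ScoredExam(
        {
            "bmi": categorize_bmi(record.age, record.bmi, record.bmi_pct),
            "bp": categorize_bp(
                record.age, record.sbp, record.dbp, record.bp_pct, record.bp_med
            ),
            "total_chol": categorize_cholesterol(record.total_chol, record.lipid_med),
            "glucose": categorize_glucose(record.glucose, record.glucose_med),
        }
    )


# ---------------------------------------------------------------------------
# dataset-level scoring and the completeness filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InclusionReport:
    """Counts surviving the completeness filter."""

    n_records_in: int
    n_records_complete: int
    n_subjects_in: int
    n_subjects_retained: int


def _record_from_row(row: pd.Series) -> ExamRecord:
    def get(name, default=None):
        v = row.get(name, default)
        return default if v is None or (isinstance(v, float) and np.isnan(v)) else v

    return ExamRecord(
        subject_id=str(row["subject_id"]),
        age=float(row["age"]),
        cohort=str(get("cohort", "")),
        sex=str(get("sex", "")),
        race=str(get("race", "")),
        bmi=get("bmi"),
        bmi_pct=get("bmi_pct"),
        sbp=get("sbp"),
        dbp=get("dbp"),
        bp_pct=get("bp_pct"),
        total_chol=get("total_chol"),
        glucose=get("glucose"),
        # missing medication flags are treated as unmedicated
        bp_med=bool(get("bp_med", False)),
        lipid_med=bool(get("lipid_med", False)),
        glucose_med=bool(get("glucose_med", False)),
    )


def score_dataset(
    records: pd.DataFrame | list[ExamRecord],
    drop_incomplete: bool = True,
) -> tuple[pd.DataFrame, InclusionReport]:
    """Score every exam of a long-format dataset and apply the inclusion rule.

    Appends per-factor category columns (``bmi_cat``, ``bp_cat``,
    ``chol_cat``, ``glu_cat``, names as 'poor'/'intermediate'/'ideal') and
    ``cvh_score``.  With ``drop_incomplete`` (the analysis default), exams
    with any uncategorizable factor are dropped and subjects with zero
    complete exams are excluded; the report carries the counts.
    """
    if isinstance(records, list):
        df = pd.DataFrame([vars(r) for r in records])
    else:
        df = records.copy()
    if len(df) == 0:
        empty = df.assign(
            **{c: pd.Series(dtype=object) for c in
               ("bmi_cat", "bp_cat", "chol_cat", "glu_cat")},
            cvh_score=pd.Series(dtype=float),
        )
        return empty, InclusionReport(0, 0, 0, 0)

    recs = [_record_from_row(row) for _, row in df.iterrows()]
    scored = [clinical_cvh_score(r) for r in recs]

    def cat_col(factor: str) -> list[str | None]:
        return [
            _CATEGORY_NAMES.get(s.categories[factor]) for s in scored
        ]

    df = df.copy()
    df["bmi_cat"] = cat_col("bmi")
    df["bp_cat"] = cat_col("bp")
    df["chol_cat"] = cat_col("total_chol")
    df["glu_cat"] = cat_col("glucose")
    df["cvh_score"] = [float(s.score) if s.complete else np.nan for s in scored]

    if not drop_incomplete:
        report = InclusionReport(
            len(df), int(df["cvh_score"].notna().sum()),
            df["subject_id"].nunique(), df["subject_id"].nunique(),
        )
        return df, report
    return apply_completeness_filter(df)


def apply_completeness_filter(df: pd.DataFrame) -> tuple[pd.DataFrame, InclusionReport]:
    """Keep complete exams only; drop subjects with no complete exam.

    Works on any frame with ``subject_id`` and ``cvh_score`` columns (a
    missing score marks an incomplete exam), so it applies equally to scored
    raw-metric data and to directly simulated score data.
    """
    n_in = len(df)
    n_subj_in = df["subject_id"].nunique() if n_in else 0
    kept = df[df["cvh_score"].notna()].reset_index(drop=True)
    report = InclusionReport(n_in, len(kept), n_subj_in, kept["subject_id"].nunique())
    return kept, report


#: pluggable pediatric percentile provider signature; the default is a
#: pass-through that insists percentiles already accompany the record.
PercentileProvider = Callable[[ExamRecord], tuple[float | None, float | None]]


def passthrough_percentiles(record: ExamRecord) -> tuple[float | None, float | None]:
    """Default provider: return the percentiles carried on the record."""
    return record.bmi_pct, record.bp_pct
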