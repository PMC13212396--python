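"""Cohort ingestion: exam/height tables, free-text measurement parsing,
height-to-exam matching, and patient-level exclusions.

The expected inputs mirror a de-identified EHR export:

* exams CSV: ``patient_id,exam_id,exam_date,age_years,sex,liver_length_cm,
  report_text,diagnosis_codes,abnormal_ast_alt`` (``diagnosis_codes``
  semicolon-separated, dates ISO-8601);
* heights CSV: ``patient_id,obs_date,height_cm``;
* exclusion list: plain text, one ICD-10 prefix per line.

Liver lengths are parsed out of free-text report snippets with a regular
expression and standardized to centimeters. Heights are attached to an exam
only when observed within an age-specific window of the exam date, taking
the observation closest in time.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ExamRecord",
    "HeightObservation",
    "MatchedExam",
    "parse_liver_length",
    "match_height",
    "height_window_days",
    "apply_exclusions",
    "read_exams",
    "read_heights",
    "read_exclusion_prefixes",
    "ingest",
]


@dataclass(frozen=True)
class ExamRecord:
    """One abdominal ultrasound exam with its covariates."""

    patient_id: str
    exam_id: str
    exam_date: _dt.date
    age_years: float
    sex: str = "unknown"  # male / female / unknown
    liver_length_cm: Optional[float] = None
    report_text: Optional[str] = None
    diagnosis_codes: tuple[str, ...] = ()
    abnormal_transaminase: Optional[bool] = None


@dataclass(frozen=True)
class HeightObservation:
    patient_id: str
    obs_date: _dt.date
    height_cm: float


@dataclass(frozen=True)
class MatchedExam(ExamRecord):
    """ExamRecord plus the height matched within the age-specific window."""

    height_cm: Optional[float] = None
    height_gap_days: Optional[int] = None


# number with optional decimal part, optionally followed by a unit
_MEASURE_RE = re.compile(
    r"(\d+(?:[.,]\d+)?|[.,]\d+)\s*(cm|centimeters?|mm|millimeters?)?\b",
    re.IGNORECASE,
)

# unitless heuristic: plausible liver lengths in cm vs mm (disjoint ranges,
# consistent with the 3-25 cm hard bounds used downstream)
_CM_RANGE = (3.0, 25.0)
_MM_RANGE = (30.0, 250.0)


def parse_liver_length(report_text: str) -> Optional[float]:
    """Extract the first liver-length mention from free text, in cm.

    Unit handling: explicit ``cm`` taken as is; explicit ``mm`` divided by
    10. A unitless number is interpreted as cm when in [3, 25], as mm when
    in [30, 250], and ignored otherwise. Returns ``None`` when nothing
    parseable is present (absence is a value, not an error).
    """
    if report_text is None:
        return None
    for m in _MEASURE_RE.finditer(report_text):
        num_txt, unit = m.group(1), m.group(2)
        try:
            value = float(num_txt.replace(",", "."))
        except ValueError:  # pragma: no cover - regex admits only numerics
            log.warning("malformed numeric %r in report text", num_txt)
            continue
        if unit:
            unit = unit.lower()
            if unit.startswith("cm") or unit.startswith("centimeter"):
                return value
            return value / 10.0
        if _CM_RANGE[0] <= value <= _CM_RANGE[1]:
            return value
        if _MM_RANGE[0] <= value <= _MM_RANGE[1]:
            return value / 10.0
        # unitless and implausible under either unit: keep scanning
    return None


def height_window_days(age_years: float) -> int:
    """Age-specific window (days) for attaching a height to an exam."""
    if age_years < 2:
        return 90
    if age_years < 9:
        return 180
    if age_years < 14:
        return 90
    return 180


def match_height(exam: ExamRecord, heights: Sequence[HeightObservation]) -> MatchedExam:
    """Attach the in-window height observation closest to the exam date.

    The window is inclusive at its boundary; equidistant observations are
    broken toward the earlier date. Observations for other patients are
    ignored.
    """
    window = height_window_days(exam.age_years)
    best: Optional[HeightObservation] = None
    best_gap: Optional[int] = None
    for obs in heights:
        if obs.patient_id != exam.patient_id:
            continue
        gap = abs((obs.obs_date - exam.exam_date).days)
        if gap > window:
            continue
        if (
            best is None
            or gap < best_gap
            or (gap == best_gap and obs.obs_date < best.obs_date)
        ):
            best, best_gap = obs, gap
    kwargs = dict(exam.__dict__)
    if best is not None:
        kwargs.update(height_cm=best.height_cm, height_gap_days=best_gap)
    return MatchedExam(**kwargs)


def apply_exclusions(
    records: Iterable[MatchedExam], excluded_codes: Sequence[str]
) -> list[MatchedExam]:
    """Drop all exams of patients with an abnormal AST/ALT flag or any
    diagnosis code starting with an excluded ICD-10 prefix.

    Exclusion is patient-level: one disqualifying exam removes every exam of
    that patient. All qualifying exams of a retained patient are kept (no
    one-exam-per-patient collapse).
    """
    records = list(records)
    prefixes = tuple(p.strip() for p in excluded_codes if p.strip())
    bad_patients: set[str] = set()
    for r in records:
        if r.abnormal_transaminase is True:
            bad_patients.add(r.patient_id)
            continue
        if prefixes and any(
            code.startswith(prefixes) for code in r.diagnosis_codes
        ):
            bad_patients.add(r.patient_id)
    kept = [r for r in records if r.patient_id not in bad_patients]
    if bad_patients:
        log.info(
            "excluded %d patients (%d exams) by patient-level criteria",
            len(bad_patients), len(records) - len(kept),
        )
    return kept


# ---------------------------------------------------------------------------
# CSV readers


def _parse_bool(x) -> Optional[bool]:
    if pd.isna(x) or x == "":
        return None
    s = str(x).strip().lower()
    if s in {"1", "true", "t", "yes", "y"}:
        return True
    if s in {"0", "false", "f", "no", "n"}:
        return False
    return None


def read_exams(path) -> list[ExamRecord]:
    """Read the exams CSV into ExamRecord objects (no filtering)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "exam_id": str})
    records = []
    for row in df.itertuples(index=False):
        codes = ()
        raw_codes = getattr(row, "diagnosis_codes", None)
        if isinstance(raw_codes, str) and raw_codes.strip():
            codes = tuple(c.strip() for c in raw_codes.split(";") if c.strip())
        length = getattr(row, "liver_length_cm", None)
        length = None if pd.isna(length) else float(length)
        text = getattr(row, "report_text", None)
        text = None if (not isinstance(text, str) or not text.strip()) else text
        sex = str(getattr(row, "sex", "unknown")).strip().lower()
        if sex not in {"male", "female"}:
            sex = "unknown"
        records.append(
            ExamRecord(
                patient_id=str(row.patient_id),
                exam_id=str(row.exam_id),
                exam_date=_dt.date.fromisoformat(str(row.exam_date)),
                age_years=float(row.age_years),
                sex=sex,
                liver_length_cm=length,
                report_text=text,
                diagnosis_codes=codes,
                abnormal_transaminase=_parse_bool(getattr(row, "abnormal_ast_alt", None)),
            )
        )
    return records


def read_heights(path) -> list[HeightObservation]:
    """Read the heights CSV; rows with height outside (20, 250) cm are
    rejected at read time with a warning."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    out = []
    n_bad = 0
    for row in df.itertuples(index=False):
        h = float(row.height_cm)
        if not (20.0 < h < 250.0):
            n_bad += 1
            continue
        out.append(
            HeightObservation(
                patient_id=str(row.patient_id),
                obs_date=_dt.date.fromisoformat(str(row.obs_date)),
                height_cm=h,
            )
        )
    if n_bad:
        log.warning("rejected %d height rows outside (20, 250) cm", n_bad)
    return out


def read_exclusion_prefixes(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def ingest(
    exams: Iterable[ExamRecord],
    heights: Sequence[HeightObservation] = (),
    excluded_codes: Sequence[str] = (),
) -> list[MatchedExam]:
    """Full ingestion stage: parse lengths, filter to < 18 years, match
    heights, and apply patient-level exclusions.

    Records whose length cannot be parsed (no numeric column and no
    parseable report text) are dropped with a warning, as are exams at or
    beyond 18 years of age.
    """
    by_patient: dict[str, list[HeightObservation]] = {}
    for obs in heights:
        by_patient.setdefault(obs.patient_id, []).append(obs)

    matched: list[MatchedExam] = []
    n_unparsed = n_overage = 0
    for exam in exams:
        if exam.age_years >= 18 or exam.age_years < 0:
            n_overage += 1
            continue
        length = exam.liver_length_cm
        if length is None and exam.report_text is not None:
            length = parse_liver_length(exam.report_text)
        if length is None:
            n_unparsed += 1
            continue
        exam = replace(exam, liver_length_cm=length)
        matched.append(match_height(exam, by_patient.get(exam.patient_id, [])))
    if n_unparsed:
        log.warning("dropped %d exams without a parseable liver length", n_unparsed)
    if n_overage:
        log.info("dropped %d exams outside the modeled 0-18 year range", n_overage)
    return apply_exclusions(matched, excluded_codes)
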