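"""Two-step robust outlier screening of liver-length measurements.

Step 1 removes physically implausible values (outside 3-25 cm). Step 2
applies two distribution-agnostic rules inside age- and height-stratified
bins: robust z-scores from the median and scaled median absolute deviation
(MAD-z), and Tukey's IQR fences. Measurements with one *extreme* flag or
two *moderate* flags (counted over distinct rule x stratification pairs)
are listed for review; they stay in the modeling set by default because
automated screening cannot adjudicate them the way a human reviewer can.

Age bins: four 3-month bins in year 1, two 6-month bins in year 2, annual
bins thereafter. Height bins: 10-cm increments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import MatchedExam

__all__ = [
    "OutlierFlag",
    "ScreenResult",
    "HARD_MIN_CM",
    "HARD_MAX_CM",
    "hard_bounds_filter",
    "assign_screen_bin",
    "mad_z_scores",
    "tukey_flags",
    "screen",
    "review_report_frame",
]

HARD_MIN_CM = 3.0
HARD_MAX_CM = 25.0

#: normal-consistency constant for the MAD
MAD_SCALE = 1.4826

MADZ_MODERATE = 3.0
MADZ_EXTREME = 3.5


@dataclass(frozen=True)
class OutlierFlag:
    exam_id: str
    rule: str  # "mad_z" | "tukey"
    stratification: str  # "age" | "height"
    severity: str  # "moderate" | "extreme"
    score: float  # z_r for mad_z; fence distance in IQR multiples for tukey


@dataclass(frozen=True)
class ScreenResult:
    retained: list
    hard_excluded: list
    review_list: list  # (exam_id, [OutlierFlag, ...])


def hard_bounds_filter(records: Iterable[MatchedExam]):
    """Split records into (kept, excluded_ids) by the 3-25 cm hard bounds
    (inclusive)."""
    kept, excluded = [], []
    for r in records:
        if r.liver_length_cm is None:
            raise ValueError(f"exam {r.exam_id} has no liver length")
        if HARD_MIN_CM <= r.liver_length_cm <= HARD_MAX_CM:
            kept.append(r)
        else:
            excluded.append(r.exam_id)
    return kept, excluded


def assign_screen_bin(covariate: float, stratification: str) -> str:
    """Screening-bin label for one covariate value.

    Age bins are half-open: [0,0.25), [0.25,0.5), [0.5,0.75), [0.75,1),
    [1,1.5), [1.5,2), then annual [k,k+1) up to 18 years. Height bins are
    [10m, 10m+10).
    """
    if not np.isfinite(covariate) or covariate < 0:
        raise ValueError("out of modeled range")
    if stratification == "age":
        if covariate >= 18:
            raise ValueError("out of modeled range")
        edges = [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0] + [float(k) for k in range(3, 19)]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if lo <= covariate < hi:
                return _age_label(lo, hi)
        raise ValueError("out of modeled range")  # pragma: no cover
    if stratification == "height":
        m = int(covariate // 10)
        return f"{10 * m}–{10 * m + 9}"
    raise ValueError(f"unknown stratification {stratification!r}")


def _age_label(lo: float, hi: float) -> str:
    def fmt(v: float) -> str:
        return f"{v:g}"

    return f"{fmt(lo)}–{fmt(hi - 0.01)}"


def mad_z_scores(values: Sequence[float]) -> np.ndarray:
    """Robust z-scores (x - median) / (1.4826 * MAD) within one stratum.

    With MAD = 0 the rule abstains: all scores are returned as 0 so that no
    value can cross a flag threshold.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty stratum")
    if x.size < 2:
        return np.zeros_like(x)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    return (x - med) / (MAD_SCALE * mad)


def tukey_flags(values: Sequence[float]) -> list:
    """Per-value Tukey-fence severities within one stratum.

    Quartiles use linear interpolation of order statistics. Returns one of
    ``None`` / ``"moderate"`` / ``"extreme"`` per value; the rule abstains
    (all ``None``) for strata smaller than 4 or with zero IQR. Values
    exactly on a fence are not flagged (strict inequalities).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        return [None] * x.size
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    if iqr == 0:
        return [None] * x.size
    out = []
    for v in x:
        if v < q1 - 3 * iqr or v > q3 + 3 * iqr:
            out.append("extreme")
        elif v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr:
            out.append("moderate")
        else:
            out.append(None)
    return out


def _tukey_score(v: float, values: np.ndarray) -> float:
    """Distance beyond the nearer quartile in IQR multiples (0 inside)."""
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    if iqr == 0:
        return 0.0
    if v > q3:
        return (v - q3) / iqr
    if v < q1:
        return (q1 - v) / iqr
    return 0.0


def screen(records: Sequence[MatchedExam], drop_review: bool = False) -> ScreenResult:
    """Run both rules under both stratifications and assemble the result.

    Height-stratified rules only see records carrying a matched height.
    A record enters the review list iff it carries at least one extreme
    flag or at least two moderate flags over distinct (rule,
    stratification) pairs. Review records are retained unless
    ``drop_review`` is set.
    """
    records = list(records)
    kept, hard_excluded = hard_bounds_filter(records)

    flags: dict[str, list[OutlierFlag]] = {r.exam_id: [] for r in kept}

    for strat, cov in (("age", lambda r: r.age_years), ("height", lambda r: r.height_cm)):
        strata: dict[str, list[MatchedExam]] = {}
        for r in kept:
            c = cov(r)
            if c is None:
                continue
            strata.setdefault(assign_screen_bin(c, strat), []).append(r)
        for members in strata.values():
            vals = np.array([m.liver_length_cm for m in members])
            if vals.size >= 2:
                z = mad_z_scores(vals)
                for m, zi in zip(members, z):
                    if abs(zi) >= MADZ_EXTREME:
                        sev = "extreme"
                    elif abs(zi) >= MADZ_MODERATE:
                        sev = "moderate"
                    else:
                        continue
                    flags[m.exam_id].append(
                        OutlierFlag(m.exam_id, "mad_z", strat, sev, float(zi))
                    )
            for m, sev in zip(members, tukey_flags(vals)):
                if sev is None:
                    continue
                flags[m.exam_id].append(
                    OutlierFlag(m.exam_id, "tukey", strat, sev, _tukey_score(m.liver_length_cm, vals))
                )

    review = []
    review_ids = set()
    for r in kept:
        fl = flags[r.exam_id]
        n_extreme = sum(f.severity == "extreme" for f in fl)
        moderate_pairs = {(f.rule, f.stratification) for f in fl if f.severity == "moderate"}
        if n_extreme >= 1 or len(moderate_pairs) >= 2:
            review.append((r.exam_id, fl))
            review_ids.add(r.exam_id)

    retained = kept if not drop_review else [r for r in kept if r.exam_id not in review_ids]
    return ScreenResult(retained=retained, hard_excluded=hard_excluded, review_list=review)


def review_report_frame(result: ScreenResult, records: Sequence[MatchedExam]) -> pd.DataFrame:
    """Flat review report (one row per flag) for export to CSV."""
    by_id = {r.exam_id: r for r in records}
    rows = []
    for exam_id, fl in result.review_list:
        r = by_id[exam_id]
        for f in fl:
            rows.append(
                dict(
                    exam_id=exam_id,
                    liver_length_cm=r.liver_length_cm,
                    age_years=r.age_years,
                    height_cm=r.height_cm,
                    rule=f.rule,
                    stratification=f.stratification,
                    severity=f.severity,
                    score=f.score,
                )
            )
    cols = [
        "exam_id", "liver_length_cm", "age_years", "height_cm",
        "rule", "stratification", "severity", "score",
    ]
    return pd.DataFrame(rows, columns=cols)
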