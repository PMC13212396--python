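"""Percentile reference tables and band classification.

Tables evaluate the fitted centiles (P5/P15/P50/P85/P95) at the midpoint of
each half-open covariate bin, report only bins meeting a minimum count
(100 overall, 50 for sex-stratified tables by default), and round to 0.1 cm
for display. Individual measurements are classified into five bands:
below P5 and above P95 are abnormal; P5-P15 and P85-P95 form low- and
high-normal gray zones around the P15-P85 normal core.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CENTILES

log = logging.getLogger(__name__)

__all__ = [
    "Bin",
    "CentileTable",
    "Band",
    "BANDS",
    "default_bins",
    "age_bins",
    "height_bins",
    "make_table",
    "classify",
    "choose_reference",
]

BANDS = ("abnormal_low", "low_normal", "normal", "high_normal", "abnormal_high")

MIN_N_OVERALL = 100
MIN_N_SEX = 50


@dataclass(frozen=True)
class Bin:
    lo: float
    hi: float  # exclusive

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def label(self, covariate: str) -> str:
        if covariate.startswith("age"):
            return f"{self.lo:g}–{self.hi - 0.01:g}"
        return f"{self.lo:g}–{self.hi - 1:g}"

    def contains(self, x: float) -> bool:
        return self.lo <= x < self.hi


def age_bins() -> list[Bin]:
    """The standard age bins: quarterly in year 1, half-yearly in year 2,
    annual thereafter."""
    edges = [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0] + [float(k) for k in range(3, 19)]
    return [Bin(a, b) for a, b in zip(edges[:-1], edges[1:])]


def height_bins(lo: float = 50.0, hi: float = 180.0) -> list[Bin]:
    """10-cm height bins covering [lo, hi)."""
    edges = np.arange(lo, hi + 10.0, 10.0)
    return [Bin(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def default_bins(covariate: str, covariate_range=None) -> list[Bin]:
    bins = age_bins() if covariate.startswith("age") else height_bins()
    if covariate_range is not None:
        lo, hi = covariate_range
        bins = [b for b in bins if lo <= b.midpoint <= hi]
    return bins


@dataclass
class CentileTable:
    covariate: str
    sex_stratum: str  # all / male / female
    rows: pd.DataFrame  # bin, midpoint, n, P5..P95 (rounded) + unrounded copies
    min_n_applied: int

    def row_for(self, x: float):
        """The (unrounded) centile row covering covariate value x, or None."""
        for _, row in self.rows.iterrows():
            if row["bin_lo"] <= x < row["bin_hi"]:
                return row
        return None

    def to_csv(self, path) -> None:
        cols = ["bin", "midpoint", "n", "P5", "P15", "P50", "P85", "P95"]
        self.rows[cols].to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "covariate": self.covariate,
            "sex_stratum": self.sex_stratum,
            "min_n": self.min_n_applied,
            "rows": self.rows.to_dict(orient="records"),
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def make_table(results, bins, counts=None, min_n: int = MIN_N_OVERALL,
               sex_stratum: str = "all") -> CentileTable:
    """Evaluate fitted centiles at bin midpoints, applying the reporting
    count rule.

    ``counts`` maps bins to case counts; when omitted they are taken from
    the model's training covariate values. Bins whose midpoint falls
    outside the fitted covariate range, or with n < min_n, are omitted
    with a logged notice. Classification downstream uses the unrounded
    centiles; the P* columns are rounded to 0.1 cm for display.
    """
    if not results.converged:
        log.warning("building a table from a non-converged fit")
    if counts is None:
        x = np.asarray(results.model.x, dtype=float)
        counts = {b: int(np.sum((x >= b.lo) & (x < b.hi))) for b in bins}
    lo, hi = results.covariate_range
    rows = []
    for b in bins:
        n = int(counts.get(b, 0))
        if not (lo <= b.midpoint <= hi):
            log.info("bin %s outside fitted range: omitted", b.label(results.covariate))
            continue
        if n < min_n:
            log.info("bin %s has n=%d < %d: omitted", b.label(results.covariate), n, min_n)
            continue
        cents = [results.predict_centile(b.midpoint, p) for p in CENTILES]
        if not all(a < bb for a, bb in zip(cents[:-1], cents[1:])):
            raise ValueError(f"non-monotone centiles in bin {b.label(results.covariate)}")
        rows.append({
            "bin": b.label(results.covariate),
            "bin_lo": b.lo, "bin_hi": b.hi,
            "midpoint": b.midpoint, "n": n,
            "P5": round(cents[0], 1), "P15": round(cents[1], 1),
            "P50": round(cents[2], 1), "P85": round(cents[3], 1),
            "P95": round(cents[4], 1),
            "P5_raw": cents[0], "P15_raw": cents[1], "P50_raw": cents[2],
            "P85_raw": cents[3], "P95_raw": cents[4],
        })
    if not rows:
        raise ValueError("no reportable bins (all below min_n or out of range)")
    return CentileTable(
        covariate=results.covariate,
        sex_stratum=sex_stratum,
        rows=pd.DataFrame(rows),
        min_n_applied=min_n,
    )


def classify(y: float, row) -> str:
    """Band of a measurement against one centile row.

    Uses unrounded centiles when present. Boundary conventions:
    y < P5 abnormal_low; P5 <= y < P15 low_normal; P15 <= y <= P85 normal;
    P85 < y <= P95 high_normal; y > P95 abnormal_high.
    """
    keys = (
        ["P5_raw", "P15_raw", "P85_raw", "P95_raw"]
        if "P5_raw" in row else ["P5", "P15", "P85", "P95"]
    )
    p5, p15, p85, p95 = (float(row[k]) for k in keys)
    if not (p5 < p15 < p85 < p95):
        raise ValueError("non-monotone centile row")
    if y < p5:
        return "abnormal_low"
    if y < p15:
        return "low_normal"
    if y <= p85:
        return "normal"
    if y <= p95:
        return "high_normal"
    return "abnormal_high"


def choose_reference(age_years, height_cm, tables: dict):
    """Pick the applicable reference row, preferring height over age.

    ``tables`` maps covariate name ("age_years" / "height_cm") to a
    CentileTable. Returns (row, provenance) where provenance records which
    covariate was used. Height correlates more strongly with liver length,
    so a covered height bin wins whenever available; otherwise the age row
    is used (with a warning when height was available but uncovered).
    """
    if height_cm is not None and "height_cm" in tables:
        row = tables["height_cm"].row_for(height_cm)
        if row is not None:
            return row, "height_cm"
        log.warning("height %.1f cm outside reported bins; falling back to age", height_cm)
    if age_years is not None and "age_years" in tables:
        row = tables["age_years"].row_for(age_years)
        if row is not None:
            return row, "age_years"
    raise ValueError("no applicable reference for the given covariates")
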