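"""Outlier screening: hard bounds, stratified MAD-z and Tukey rules,
review triggering, and brute-force oracle equivalence."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, strategies as st

from liversize.ingest import ExamRecord, match_height
from liversize.screen import (
    MAD_SCALE,
    assign_screen_bin,
    hard_bounds_filter,
    mad_z_scores,
    review_report_frame,
    screen,
    tukey_flags,
)


def rec(eid, length, age=5.0, height=None, pid=None):
    base = ExamRecord(patient_id=pid or f"p_{eid}", exam_id=eid,
                      exam_date=dt.date(2020, 1, 1), age_years=age,
                      liver_length_cm=length)
    m = match_height(base, [])
    if height is not None:
        m = type(m)(**{**m.__dict__, "height_cm": height, "height_gap_days": 0})
    return m


# ---------------------------------------------------------------------------
# brute-force oracles, straight from the definitions

def oracle_madz(values):
    med = sorted(values)[len(values) // 2] if len(values) % 2 else (
        sorted(values)[len(values) // 2 - 1] + sorted(values)[len(values) // 2]) / 2
    devs = sorted(abs(v - med) for v in values)
    mad = devs[len(devs) // 2] if len(devs) % 2 else (
        devs[len(devs) // 2 - 1] + devs[len(devs) // 2]) / 2
    if mad == 0:
        return [0.0] * len(values)
    return [(v - med) / (MAD_SCALE * mad) for v in values]


def oracle_quartile(values, q):
    """Linear interpolation of order statistics (the numpy 'linear' rule)."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def oracle_tukey(values):
    if len(values) < 4:
        return [None] * len(values)
    q1 = oracle_quartile(values, 0.25)
    q3 = oracle_quartile(values, 0.75)
    iqr = q3 - q1
    if iqr == 0:
        return [None] * len(values)
    out = []
    for v in values:
        if v < q1 - 3 * iqr or v > q3 + 3 * iqr:
            out.append("extreme")
        elif v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr:
            out.append("moderate")
        else:
            out.append(None)
    return out


class TestHardBounds:
    def test_boundaries(self):
        records = [rec("a", 2.9), rec("b", 25.1), rec("c", 10.0),
                   rec("d", 3.0), rec("e", 25.0)]
        kept, excluded = hard_bounds_filter(records)
        assert {r.exam_id for r in kept} == {"c", "d", "e"}
        assert set(excluded) == {"a", "b"}


class TestScreenBins:
    @pytest.mark.parametrize("age,label", [
        (0.3, "0.25–0.49"), (0.0, "0–0.24"), (0.6, "0.5–0.74"),
        (0.8, "0.75–0.99"), (1.2, "1–1.49"), (1.6, "1.5–1.99"),
        (2.5, "2–2.99"), (17.9, "17–17.99"),
    ])
    def test_age_bins(self, age, label):
        assert assign_screen_bin(age, "age") == label

    @pytest.mark.parametrize("h,label", [(95, "90–99"), (50, "50–59"), (179.9, "170–179")])
    def test_height_bins(self, h, label):
        assert assign_screen_bin(h, "height") == label

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="out of modeled range"):
            assign_screen_bin(18.0, "age")
        with pytest.raises(ValueError, match="out of modeled range"):
            assign_screen_bin(float("nan"), "age")


class TestMadZ:
    def test_hand_value(self):
        # {1..7} with 10 appended: median 4.5, MAD 2.0
        z = mad_z_scores([1, 2, 3, 4, 5, 6, 7, 10])
        expected = (10 - 4.5) / (MAD_SCALE * 2.0)
        assert z[-1] == pytest.approx(expected, abs=1e-6)
        assert abs(z[-1]) < 3  # no flag
        assert z == pytest.approx(oracle_madz([1, 2, 3, 4, 5, 6, 7, 10]), abs=1e-12)

    def test_mad_zero_abstains(self):
        assert np.all(mad_z_scores([5.0] * 6) == 0)

    def test_median_element_centered(self):
        z = mad_z_scores([1, 2, 3, 4, 5])
        assert z[2] == 0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mad_z_scores([])

    @given(st.lists(st.floats(3.0, 25.0), min_size=2, max_size=50))
    def test_matches_oracle(self, values):
        np.testing.assert_allclose(
            mad_z_scores(values), oracle_madz(values), atol=1e-9)

    def test_monotone_above_median(self):
        base = [4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        z1 = mad_z_scores(base + [11.0])[-1]
        z2 = mad_z_scores(base + [13.0])[-1]
        assert z2 >= z1


class TestTukey:
    def test_gross_value_extreme(self):
        values = list(range(1, 101)) + [300]
        flags = tukey_flags(values)
        assert flags[-1] == "extreme"
        assert flags == oracle_tukey(values)

    def test_exact_fence_not_flagged(self):
        # for {1,2,3,4,7}: Q1=2, Q3=4, IQR=2, so the moderate fence is
        # exactly 7 -- a value sitting on the fence is not flagged
        assert tukey_flags([1.0, 2.0, 3.0, 4.0, 7.0])[-1] is None
        assert tukey_flags([1.0, 2.0, 3.0, 4.0, 7.01])[-1] == "moderate"

    def test_zero_iqr_abstains(self):
        assert tukey_flags([5, 5, 5, 5, 5, 30]) == [None] * 6

    def test_small_stratum_abstains(self):
        assert tukey_flags([1, 2, 100]) == [None, None, None]

    @given(st.lists(st.floats(3.0, 25.0), min_size=4, max_size=50))
    def test_matches_oracle(self, values):
        assert tukey_flags(values) == oracle_tukey(values)


def _stratum_with_outlier(age, outlier, n=40, pid_prefix="q", spread=0.3):
    """A tight stratum plus one outlying value in the same age bin."""
    rng = np.random.default_rng(abs(hash(pid_prefix)) % 2**31)
    vals = 10.0 + spread * rng.standard_normal(n)
    records = [rec(f"{pid_prefix}{i}", float(np.clip(v, 3, 25)), age=age)
               for i, v in enumerate(vals)]
    records.append(rec(f"{pid_prefix}_out", outlier, age=age))
    return records


class TestScreenAssembly:
    def test_extreme_triggers_review(self):
        records = _stratum_with_outlier(5.5, 20.0)
        result = screen(records)
        ids = {eid for eid, _ in result.review_list}
        assert f"q_out" in ids
        assert len(result.retained) == len(records)  # review kept by default

    def test_drop_review_removes(self):
        records = _stratum_with_outlier(5.5, 20.0)
        result = screen(records, drop_review=True)
        assert all(r.exam_id != "q_out" for r in result.retained)

    def test_two_moderate_flags_trigger(self):
        """A value moderate under both rules (same stratification) counts
        as two distinct (rule, stratification) pairs and triggers review."""
        # evenly spread stratum 9.0..11.0; 12.6 scores MAD-z ~3.13
        # (moderate) and sits between the 1.5x and 3x IQR fences
        base = [round(10 + 0.1 * k, 1) for k in range(-10, 11)]
        assert 3 <= abs(mad_z_scores(base + [12.6])[-1]) < 3.5
        assert tukey_flags(base + [12.6])[-1] == "moderate"
        records = [rec(f"m{i}", v, age=5.5) for i, v in enumerate(base)]
        records.append(rec("m_out", 12.6, age=5.5))
        result = screen(records)
        flags = dict(result.review_list)["m_out"]
        assert {f.severity for f in flags} == {"moderate"}
        assert {(f.rule, f.stratification) for f in flags} == {
            ("mad_z", "age"), ("tukey", "age")}

    def test_single_moderate_not_reviewed(self):
        # uniform-ish stratum: MAD and IQR wide, a mild outlier gets at
        # most one moderate flag
        records = [rec(f"u{i}", 8.0 + 0.1 * i, age=7.5) for i in range(30)]
        records.append(rec("u_mild", 12.3, age=7.5))
        result = screen(records)
        for eid, flags in result.review_list:
            assert not (len(flags) == 1 and flags[0].severity == "moderate")

    def test_height_stratification_used(self):
        records = _stratum_with_outlier(5.5, 10.0)  # nothing odd by age
        # same records, but give the outlier record an extreme value only
        # within a height stratum of its own peers
        tall = [rec(f"h{i}", 12.0 + 0.1 * (i % 5), age=float(2 + i % 10),
                    height=140.0 + (i % 7)) for i in range(30)]
        tall.append(rec("h_out", 22.0, age=9.5, height=143.0))
        result = screen(records + tall)
        flagged = dict(result.review_list)
        assert "h_out" in flagged
        assert any(f.stratification == "height" for f in flagged["h_out"])

    def test_review_report_columns(self):
        records = _stratum_with_outlier(5.5, 20.0)
        result = screen(records)
        frame = review_report_frame(result, records)
        assert list(frame.columns) == [
            "exam_id", "liver_length_cm", "age_years", "height_cm",
            "rule", "stratification", "severity", "score",
        ]
        assert len(frame) >= 1


def test_oracle_equivalence_random_strata():
    """Flags from both rules match exhaustive brute-force evaluation on
    random strata."""
    rng = np.random.default_rng(1234)
    for _ in range(200):
        n = int(rng.integers(2, 51))
        values = np.round(rng.uniform(3, 25, size=n), 2).tolist()
        np.testing.assert_allclose(mad_z_scores(values), oracle_madz(values),
                                   atol=1e-9)
        assert tukey_flags(values) == oracle_tukey(values)


def test_madz_false_positive_rate_normal():
    """|z_r| >= 3.5 occurs in well under 0.1% of standard-normal draws."""
    rng = np.random.default_rng(99)
    z = mad_z_scores(rng.standard_normal(10_000))
    assert np.mean(np.abs(z) >= 3.5) < 0.001
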