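"""Synthetic-cohort generator: quantile inversion, anchored truth,
cohort structure, determinism."""

import numpy as np
import pytest

from liversize.bcpe import bcpe_quantile
from liversize.ingest import ingest, read_exams, read_heights
from liversize.screen import hard_bounds_filter, screen
from liversize.simulate import (
    ANCHOR_TABLES,
    MALE_SHARE,
    build_truth,
    generate,
    load_anchor_table,
    solve_params_from_quantiles,
)


class TestSolveParams:
    def test_symmetric_quantiles_give_normal_case(self):
        p = solve_params_from_quantiles(8.0, 10.0, 12.0, tau=2.0)
        assert p.mu == 10.0
        assert p.nu == pytest.approx(1.0, abs=1e-6)
        assert p.sigma == pytest.approx(0.2 / 1.6449, abs=1e-4)

    def test_published_row_roundtrips(self):
        # a mid-childhood row: P5=8.7, P50=10.2, P95=11.8
        p = solve_params_from_quantiles(8.7, 10.2, 11.8, tau=2.0)
        assert bcpe_quantile(0.05, p) == pytest.approx(8.7, abs=1e-6)
        assert bcpe_quantile(0.5, p) == pytest.approx(10.2, abs=1e-12)
        assert bcpe_quantile(0.95, p) == pytest.approx(11.8, abs=1e-6)

    def test_median_exact_for_any_solution(self):
        p = solve_params_from_quantiles(5.3, 6.6, 7.9, tau=1.7)
        assert bcpe_quantile(0.5, p) == pytest.approx(6.6, rel=1e-12)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            solve_params_from_quantiles(10.0, 9.0, 12.0)

    @pytest.mark.parametrize("name", ["age_all", "height_all"])
    def test_every_anchor_row_roundtrips(self, name):
        """Solved parameters reproduce the printed P5/P50/P95 to 1e-6 in
        every bin of the main tables."""
        table = load_anchor_table(name)
        for row in table.itertuples(index=False):
            p = solve_params_from_quantiles(row.p5, row.p50, row.p95, tau=2.0)
            for q, target in ((0.05, row.p5), (0.5, row.p50), (0.95, row.p95)):
                assert float(bcpe_quantile(q, p)) == pytest.approx(
                    target, abs=1e-6), (name, row.bin_lo, q)


class TestBuildTruth:
    def test_age_truth_upper_p95(self):
        truth = build_truth("age_all", tau=2.0)
        assert float(truth.quantile(17.5, 0.95)) == pytest.approx(17.2, abs=1e-6)

    def test_height_truth_lower_p5(self):
        truth = build_truth("height_all", tau=2.0)
        assert float(truth.quantile(55.0, 0.05)) == pytest.approx(5.3, abs=1e-6)

    def test_anchor_midpoints_reproduce_p50(self):
        truth = build_truth("age_all", tau=2.0)
        table = load_anchor_table("age_all")
        mids = 0.5 * (table["bin_lo"] + table["bin_hi"])
        np.testing.assert_allclose(
            np.asarray(truth.quantile(mids.to_numpy(), 0.5)),
            table["p50"].to_numpy(), atol=1e-9)

    def test_constant_extension_beyond_anchors(self):
        truth = build_truth("age_all", tau=2.0)
        inner = float(truth.quantile(0.125, 0.5))
        assert float(truth.quantile(0.01, 0.5)) == pytest.approx(inner, rel=1e-12)

    def test_implied_inner_centiles_close(self):
        """The tau=2 anchored truth implies P15/P85 within 0.3 cm of the
        printed values for at least 80% of rows."""
        hits = total = 0
        for name in ("age_all", "height_all"):
            truth = build_truth(name, tau=2.0)
            table = load_anchor_table(name)
            for row in table.itertuples(index=False):
                mid = 0.5 * (row.bin_lo + row.bin_hi)
                for q, target in ((0.15, row.p15), (0.85, row.p85)):
                    total += 1
                    if abs(float(truth.quantile(mid, q)) - target) <= 0.3:
                        hits += 1
        assert hits / total >= 0.8

    def test_all_packaged_tables_load(self):
        for name in ANCHOR_TABLES:
            t = load_anchor_table(name)
            assert {"bin_lo", "bin_hi", "p5", "p15", "p50", "p85", "p95"} <= set(t.columns)
            assert (t[["p5", "p15", "p50", "p85", "p95"]].diff(axis=1)
                    .iloc[:, 1:] > 0).all().all()


class TestGenerate:
    def test_deterministic_output(self, tmp_path):
        truth = build_truth("age_all", tau=2.0)
        files = []
        for tag in ("a", "b"):
            cohort = generate(truth, 500, seed=77)
            p = tmp_path / f"exams_{tag}.csv"
            cohort.write(p, tmp_path / f"h_{tag}.csv")
            files.append(p.read_bytes())
        assert files[0] == files[1]

    def test_no_outliers_when_rate_zero(self):
        truth = build_truth("age_all", tau=2.0)
        cohort = generate(truth, 2000, seed=3, outlier_rate=0.0,
                          exclusion_rate=0.0, report_fraction=0.0)
        records = [r for r in _ingest_cohort(cohort)]
        kept, excluded = hard_bounds_filter(records)
        assert excluded == []
        assert cohort.injected_outlier_ids == []

    def test_injected_outliers_all_removed(self):
        truth = build_truth("age_all", tau=2.0)
        cohort = generate(truth, 4000, seed=4, outlier_rate=0.05,
                          exclusion_rate=0.0)
        records = _ingest_cohort(cohort)
        kept, excluded = hard_bounds_filter(records)
        assert set(cohort.injected_outlier_ids) <= set(excluded)

    def test_tail_calibration_across_ages(self):
        """In every age decile the fraction below the truth's P5 is
        0.05 +- 0.01 (n chosen so the bound sits at ~3.6 binomial sigma:
        a sound calibration check rather than a coin flip)."""
        truth = build_truth("age_all", tau=2.0)
        cohort = generate(truth, 60_000, seed=5, outlier_rate=0.0,
                          exclusion_rate=0.0, report_fraction=0.0)
        df = cohort.exams
        ages = df["age_years"].astype(float).to_numpy()
        y = df["liver_length_cm"].astype(float).to_numpy()
        p5 = np.asarray(truth.quantile(ages, 0.05))
        for lo in np.arange(0, 18, 1.8):
            m = (ages >= lo) & (ages < lo + 1.8)
            assert np.mean(y[m] < p5[m]) == pytest.approx(0.05, abs=0.01)

    def test_sex_frequencies_match_cohort(self):
        truth = build_truth("age_all", tau=2.0)
        cohort = generate(truth, 20_000, seed=6)
        share = (cohort.exams["sex"] == "male").mean()
        assert share == pytest.approx(MALE_SHARE, abs=0.01)

    def test_cohort_like_age_law(self):
        truth = build_truth("age_all", tau=2.0)
        cohort = generate(truth, 20_000, seed=7, covariate_sampling="cohort_like")
        ages = cohort.exams["age_years"].astype(float)
        assert ages.median() == pytest.approx(5.91, abs=1.0)
        q1, q3 = ages.quantile([0.25, 0.75])
        assert q1 == pytest.approx(1.88, abs=1.0)
        assert q3 == pytest.approx(12.47, abs=1.5)

    def test_roundtrips_through_ingest(self, tmp_path):
        truth = build_truth("age_all", tau=2.0)
        cohort = generate(truth, 2000, seed=8, outlier_rate=0.0,
                          exclusion_rate=0.0)
        cohort.write(tmp_path / "e.csv", tmp_path / "h.csv", tmp_path / "t.json")
        records = ingest(read_exams(tmp_path / "e.csv"),
                         read_heights(tmp_path / "h.csv"))
        # free-text rendering quantizes to 0.1 cm but loses no record
        assert len(records) == 2000
        with_height = [r for r in records if r.height_cm is not None]
        assert 0.55 < len(with_height) / 2000 < 0.85

    def test_excluded_patients_dropped_at_ingest(self, tmp_path):
        truth = build_truth("age_all", tau=2.0)
        cohort = generate(truth, 3000, seed=9, outlier_rate=0.0,
                          exclusion_rate=0.1)
        cohort.write(tmp_path / "e.csv", tmp_path / "h.csv")
        records = ingest(read_exams(tmp_path / "e.csv"),
                         read_heights(tmp_path / "h.csv"), ["K76"])
        kept_pids = {r.patient_id for r in records}
        assert not (kept_pids & set(cohort.excluded_patient_ids))


def _ingest_cohort(cohort):
    """In-memory ingest of a cohort's exam frame (no exclusion list)."""
    import tempfile, os

    d = tempfile.mkdtemp()
    e, h = os.path.join(d, "e.csv"), os.path.join(d, "h.csv")
    cohort.write(e, h)
    return ingest(read_exams(e), read_heights(h))
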