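"""Within-subject SD, CV, repeatability coefficient, paired tests, report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from octavd import (MACULA_SEGMENTS, REPEATABILITY_FACTOR, PairedScanConfig,
                    coefficient_of_variation, generate_paired_scans,
                    mean_difference_test, repeatability_coefficient,
                    repeatability_report, sw_confidence_interval,
                    within_subject_sd)
from octavd.density import REGION_ORDER


class TestWithinSubjectSd:
    def test_identical_pairs_give_zero(self):
        assert within_subject_sd([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 0.0

    def test_worked_pair_set(self):
        # sqrt((0.1-0.2)^2 + 0) / (2*2)) = sqrt(0.01/4) = 0.05
        assert within_subject_sd([0.1, 0.3], [0.2, 0.3]) == pytest.approx(0.05)

    def test_matches_anova_within_mean_square(self):
        # independent route: one-way ANOVA within-group mean square with
        # subject as the factor, computed from the raw sums of squares
        rng = np.random.default_rng(6)
        v1 = rng.uniform(0.1, 0.4, size=12)
        v2 = v1 + rng.normal(0, 0.02, size=12)
        values = np.stack([v1, v2], axis=1)
        ss_within = float(np.sum((values - values.mean(axis=1, keepdims=True)) ** 2))
        ms_within = ss_within / (12 * (2 - 1))
        assert within_subject_sd(v1, v2) == pytest.approx(np.sqrt(ms_within))

    def test_shift_invariance(self):
        v1, v2 = np.array([0.1, 0.25, 0.3]), np.array([0.12, 0.2, 0.33])
        assert within_subject_sd(v1 + 0.2, v2 + 0.2) == pytest.approx(
            within_subject_sd(v1, v2))

    def test_incomplete_pairs_excluded(self):
        sw = within_subject_sd([0.1, 0.3, np.nan], [0.2, 0.3, 0.4])
        assert sw == pytest.approx(0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            within_subject_sd([0.1], [0.2])


class TestRepeatabilityCoefficient:
    @pytest.mark.parametrize("sw, expected", [
        (0.008, 0.022), (0.076, 0.211), (0.0, 0.0)])
    def test_known_values(self, sw, expected):
        assert round(repeatability_coefficient(sw), 3) == expected

    def test_negative_sw_rejected(self):
        with pytest.raises(ValueError):
            repeatability_coefficient(-0.01)


class TestCoefficientOfVariation:
    def test_values(self):
        assert coefficient_of_variation(0.0, 0.2) == 0.0
        assert coefficient_of_variation(0.05, 0.25) == pytest.approx(0.20)

    def test_scale_invariance(self):
        v1 = np.array([0.1, 0.2, 0.35])
        v2 = np.array([0.12, 0.19, 0.3])
        for a in (1.0, 2.5):
            sw = within_subject_sd(a * v1, a * v2)
            mean = np.mean(np.concatenate([a * v1, a * v2]))
            assert coefficient_of_variation(sw, mean) == pytest.approx(
                coefficient_of_variation(within_subject_sd(v1, v2),
                                         np.mean(np.concatenate([v1, v2]))))

    def test_cv_decreases_with_mean(self):
        v1 = np.array([0.1, 0.2, 0.35])
        v2 = np.array([0.12, 0.19, 0.3])
        sw = within_subject_sd(v1, v2)
        cvs = [coefficient_of_variation(
            sw, np.mean(np.concatenate([v1 + c, v2 + c]))) for c in (0, 0.1, 0.2)]
        assert cvs[0] > cvs[1] > cvs[2]

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(0.05, 0.0)


class TestSwConfidenceInterval:
    def test_zero_sw_zero_interval(self):
        assert sw_confidence_interval(0.0, 10) == (0.0, 0.0)

    def test_worked_example_n50(self):
        lo, hi = sw_confidence_interval(0.05, 50)
        assert lo == pytest.approx(0.0402, abs=1e-4)
        assert hi == pytest.approx(0.0598, abs=1e-4)

    def test_width_vanishes_at_large_n(self):
        lo, hi = sw_confidence_interval(0.05, 10**6)
        assert (hi - lo) < 0.003 * 0.05

    def test_chi2_interval_contains_estimate(self):
        lo, hi = sw_confidence_interval(0.05, 30, method="chi2")
        assert lo < 0.05 < hi

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            sw_confidence_interval(0.05, 1)


class TestMeanDifferenceTest:
    def test_identical_pairs_degenerate(self):
        res = mean_difference_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.mean_difference == 0.0
        assert res.ci == (0.0, 0.0)
        assert res.p_value == 1.0
        assert res.degenerate

    def test_textbook_paired_t(self):
        # oracle: scipy's paired t-test on d = {0.01, 0.02, 0.03, 0.04}
        v1 = np.array([0.21, 0.32, 0.23, 0.34])
        v2 = v1 - np.array([0.01, 0.02, 0.03, 0.04])
        res = mean_difference_test(v1, v2)
        t_ref, p_ref = stats.ttest_rel(v1, v2)
        assert res.p_value == pytest.approx(p_ref)
        assert res.mean_difference == pytest.approx(0.025)
        se = np.std(v1 - v2, ddof=1) / 2.0
        assert res.ci[1] - res.ci[0] == pytest.approx(
            2 * stats.t.ppf(0.975, 3) * se)

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(9)
        v1 = rng.uniform(0.1, 0.3, 8)
        v2 = v1 + rng.normal(0, 0.02, 8)
        assert mean_difference_test(v1, v2).p_value == pytest.approx(
            mean_difference_test(v2, v1).p_value)


def _complete_pairs(n=20, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for eye in ("OD", "OS"):
        for seg in MACULA_SEGMENTS:
            for region in REGION_ORDER:
                truth = rng.uniform(0.1, 0.3, size=n)
                rows.append(pd.DataFrame({
                    "subject_id": [f"S{i}" for i in range(n)],
                    "eye": eye, "scan_type": "macula", "segment_label": seg,
                    "region": region,
                    "value_1": truth + rng.normal(0, 0.02, n),
                    "value_2": truth + rng.normal(0, 0.02, n)}))
    return pd.concat(rows, ignore_index=True)


class TestRepeatabilityReport:
    def test_complete_macular_dataset_gives_40_rows(self):
        report = repeatability_report(_complete_pairs())
        assert len(report) == 40
        assert report["available"].all()
        # deterministic ordering: OD first, segments in device order
        assert report["eye"].iloc[0] == "OD"
        assert list(report["segment_label"].iloc[:5]) == ["superficial_retina"] * 5

    def test_repeatability_is_exact_multiple_of_sw(self):
        report = repeatability_report(_complete_pairs())
        np.testing.assert_array_equal(report["repeatability"],
                                      REPEATABILITY_FACTOR * report["sw"])

    def test_cis_contain_point_estimates(self):
        report = repeatability_report(_complete_pairs())
        assert (report["sw_ci_lo"] <= report["sw"]).all()
        assert (report["sw"] <= report["sw_ci_hi"]).all()
        assert (report["md_ci_lo"] <= report["mean_difference"]).all()
        assert (report["mean_difference"] <= report["md_ci_hi"]).all()

    def test_sw_recovered_within_sampling_interval(self):
        # oracle: sw/sigma_w ~ sqrt(chi2(n)/n) for n subjects, 2 replicates
        df = generate_paired_scans(PairedScanConfig(
            n_subjects=500, within_subject_sd=0.02, seed=21))
        sw = within_subject_sd(df["value_1"], df["value_2"])
        lo, hi = 0.02 * np.sqrt(stats.chi2.ppf([0.025, 0.975], 500) / 500)
        assert lo <= sw <= hi

    def test_underfilled_region_marked_unavailable(self):
        pairs = _complete_pairs(n=20)
        single = pairs.iloc[:1].copy()
        single["region"] = "segment"
        single["segment_label"] = "outer_retina"
        single["eye"] = "OS"
        pairs = pairs[~((pairs["eye"] == "OS")
                        & (pairs["segment_label"] == "outer_retina")
                        & (pairs["region"] == "segment"))]
        report = repeatability_report(pd.concat([pairs, single],
                                                ignore_index=True))
        row = report[(report["eye"] == "OS")
                     & (report["segment_label"] == "outer_retina")
                     & (report["region"] == "segment")]
        assert len(row) == 1
        assert not row["available"].item()
        assert np.isnan(row["sw"].item())

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            repeatability_report(pd.DataFrame({"value_1": [1.0]}))

    def test_ci_coverage_at_study_scale(self):
        # 200 simulated studies at n=47, sigma_w=0.02: the normal-theory 95%
        # CI for Sw should cover the truth between 90% and 98% of the time
        covered = 0
        for seed in range(200):
            df = generate_paired_scans(PairedScanConfig(
                n_subjects=47, within_subject_sd=0.02, seed=seed))
            sw = within_subject_sd(df["value_1"], df["value_2"])
            lo, hi = sw_confidence_interval(sw, 47)
            covered += lo <= 0.02 <= hi
        assert 0.90 * 200 <= covered <= 0.98 * 200
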