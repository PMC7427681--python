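"""Method-comparison statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from sirtdose.comparison import (NTV_THRESHOLDS, TUMOR_THRESHOLDS,
                                 PairedSeries, agreement_report, bland_altman,
                                 classify_criteria, correlate,
                                 paired_wilcoxon, passing_bablok,
                                 planned_vs_calculated, ratio_summary)


def series(x, y, **kw):
    return PairedSeries(np.asarray(x, float), np.asarray(y, float), **kw)


def pb_oracle(x, y):
    """Independent Passing–Bablok estimate by explicit enumeration."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] != x[i]:
                s = (y[j] - y[i]) / (x[j] - x[i])
                if s != -1.0:
                    slopes.append(s)
    slopes.sort()
    nn = len(slopes)
    k = sum(1 for s in slopes if s < -1.0)
    if nn % 2:
        b = slopes[(nn + 1) // 2 + k - 1]
    else:
        b = 0.5 * (slopes[nn // 2 + k - 1] + slopes[nn // 2 + k])
    a = float(np.median([yi - b * xi for xi, yi in zip(x, y)]))
    return b, a


class TestPassingBablok:
    def test_identity_line(self):
        x = np.arange(1.0, 9.0)
        out = passing_bablok(series(x, x))
        assert out["slope"] == 1.0 and out["intercept"] == 0.0

    def test_exact_linear_data(self):
        x = np.arange(1.0, 11.0)
        out = passing_bablok(series(x, 2 * x + 1))
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(8) * 50
        y = 1.4 * x + rng.normal(0, 5, 8)
        out = passing_bablok(series(x, y))
        b, a = pb_oracle(list(x), list(y))
        assert out["slope"] == pytest.approx(b, rel=1e-12)
        assert out["intercept"] == pytest.approx(a, rel=1e-12)

    def test_axis_swap_inverts_slope(self, rng):
        x = rng.random(15) * 100
        y = 2.0 * x * (1 + rng.normal(0, 0.02, 15))
        fwd = passing_bablok(series(x, y))["slope"]
        rev = passing_bablok(series(y, x))["slope"]
        assert rev == pytest.approx(1.0 / fwd, rel=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            passing_bablok(series([1, 2], [1, 2]))
        with pytest.raises(ValueError, match="identical"):
            passing_bablok(series([3, 3, 3, 3], [1, 2, 3, 4]))

    def test_ci_brackets_the_estimate(self, rng):
        x = rng.random(20) * 80
        y = 0.9 * x + rng.normal(0, 4, 20)
        out = passing_bablok(series(x, y))
        lo, hi = out["slope_ci"]
        assert lo <= out["slope"] <= hi


class TestBlandAltman:
    def test_identical_series(self):
        x = np.arange(5.0)
        out = bland_altman(series(x, x))
        assert out["mean_diff"] == 0.0
        assert out["loa_low"] == 0.0 and out["loa_high"] == 0.0

    def test_two_point_hand_example(self):
        out = bland_altman(series([0.0, 0.0], [-1.0, 1.0]))
        assert out["mean_diff"] == 0.0
        assert out["sd_diff"] == pytest.approx(np.sqrt(2), rel=1e-12)
        assert out["loa_high"] == pytest.approx(2.7719, abs=1e-3)
        assert out["loa_low"] == pytest.approx(-2.7719, abs=1e-3)

    def test_limits_width_definitional(self, rng):
        x = rng.random(30) * 10
        y = x + rng.normal(0, 2, 30)
        out = bland_altman(series(x, y))
        assert out["loa_high"] - out["loa_low"] == pytest.approx(
            2 * 1.96 * out["sd_diff"], rel=1e-12)
        assert out["loa_low"] <= out["mean_diff"] <= out["loa_high"]


class TestCorrelation:
    def test_perfect_line_is_strong(self):
        x = np.arange(10.0)
        out = correlate(series(x, 3 * x + 2))
        assert out["r"] == pytest.approx(1.0)
        assert out["grade"] == "strong"

    @pytest.mark.parametrize("target_r, grade", [
        (0.94, "strong"), (0.62, "moderate"), (0.4, "weak"), (0.1, "negligible"),
    ])
    def test_grading_thresholds(self, target_r, grade):
        # construct a pair with the requested correlation via a rotation trick
        rng = np.random.default_rng(7)
        n = 4000
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        y = target_r * a + np.sqrt(1 - target_r**2) * b
        out = correlate(series(a, y))
        assert out["r"] == pytest.approx(target_r, abs=0.04)
        assert out["grade"] == grade

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate(series([1, 1, 1], [1, 2, 3]))


def wilcoxon_oracle_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # handle ties by average ranks
    absd = np.abs(d)
    for v in np.unique(absd):
        sel = absd == v
        ranks[sel] = ranks[sel].mean()
    w_obs = ranks[d > 0].sum()
    n = d.size
    total = ranks.sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        stats.append(w)
    stats = np.asarray(stats)
    mean = total / 2.0
    p = np.mean(np.abs(stats - mean) >= abs(w_obs - mean) - 1e-12)
    return float(p)


class TestWilcoxon:
    def test_antisymmetric_differences_give_p_one(self):
        x = np.zeros(6)
        y = np.array([-3.0, -1.0, 1.0, 3.0, -2.0, 2.0])
        out = paired_wilcoxon(series(x, y))
        assert out["p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(1.0, 2.0, 6), 2)
        d[d == 0] = 0.5
        out = paired_wilcoxon(series(np.zeros(6), d))
        assert out["p"] == pytest.approx(wilcoxon_oracle_p(d), rel=1e-9)

    def test_constant_shift_is_significant(self):
        x = np.arange(10.0)
        out = paired_wilcoxon(series(x, x + 5))
        assert out["p"] == pytest.approx(2 / 1024)
        assert out["p"] < 0.05

    def test_all_zero_differences_degenerate(self):
        x = np.arange(6.0)
        out = paired_wilcoxon(series(x, x))
        assert out["degenerate"]


class TestRatioSummary:
    def test_identity(self):
        x = np.arange(1.0, 6.0)
        out = ratio_summary(series(x, x))
        assert (out["q1"], out["median"], out["q3"]) == (1.0, 1.0, 1.0)

    def test_simple_median(self):
        out = ratio_summary(series([1, 1, 1], [0.5, 1.0, 2.0]))
        assert out["median"] == 1.0

    def test_lognormal_cohort_recovers_generating_median(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(20, 120, 100)
        ratio = np.exp(rng.normal(0.0, 0.4, 100))  # generating median 1.0
        out = ratio_summary(series(x, x * ratio))
        assert out["median"] == pytest.approx(1.0, abs=0.05)
        assert out["q1"] < out["median"] < out["q3"]

    def test_nonpositive_predictions_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            out = ratio_summary(series([0.0, 2.0, 2.0, 2.0], [1, 2, 2, 2]))
        assert out["n"] == 3


class TestClassification:
    @pytest.mark.parametrize("pred, meas, category", [
        (84.0, 95.0, "concordant_above"),       # agreement above 70 Gy
        (165.0, 4.0, "predicted_only_above"),   # falsely predicted coverage
        (33.0, 130.0, "measured_only_above"),   # better than suggested
        (50.0, 60.0, "concordant_below"),
    ])
    def test_tumor_fourway_regions(self, pred, meas, category):
        cls = classify_criteria(series([pred], [meas]), "tumor")
        assert cls.categories == [category]

    def test_ntv_boundary_and_joint_histogram_cell(self):
        cls = classify_criteria(series([45.0], [45.0]), "ntv")
        assert cls.categories == ["concordant_below"]
        assert cls.joint_histogram[1, 1] == 1

    def test_boundary_value_goes_to_upper_bin(self):
        cls = classify_criteria(series([70.0], [100.0]), "tumor")
        assert cls.categories == ["concordant_above"]
        assert cls.joint_histogram[1, 2] == 1

    def test_histogram_collapse_recovers_region_counts(self, rng):
        x = rng.uniform(0, 200, 50)
        y = rng.uniform(0, 200, 50)
        for compartment in ("tumor", "ntv"):
            cls = classify_criteria(series(x, y), compartment)
            assert cls.collapse_to_regions() == cls.region_counts
            assert cls.joint_histogram.sum() == 50
            assert sum(cls.region_counts.values()) == 50

    def test_thresholds_match_clinical_convention(self):
        assert TUMOR_THRESHOLDS == (70.0, 100.0)
        assert NTV_THRESHOLDS == (50.0, 40.0)


class TestPlannedVsCalculated:
    def test_ntv_below_plan_is_negative(self):
        assert planned_vs_calculated(25.0, 20.0, "ntv") == pytest.approx(-20.0)

    def test_tumor_above_plan_is_negative(self):
        assert planned_vs_calculated(120.0, 150.0, "tumor") == pytest.approx(-25.0)

    def test_exact_plan_is_zero(self):
        assert planned_vs_calculated(40.0, 40.0, "ntv") == 0.0
        assert planned_vs_calculated(40.0, 40.0, "tumor") == 0.0

    def test_nonpositive_plan_rejected(self):
        with pytest.raises(ValueError):
            planned_vs_calculated(0.0, 10.0, "ntv")


class TestAgreementReport:
    def test_bundle_contains_all_layers(self, rng):
        x = rng.uniform(10, 120, 20)
        y = x * np.exp(rng.normal(0, 0.2, 20))
        report = agreement_report(series(x, y, parameter="mean dose"))
        assert set(report) >= {"pb", "ba", "pearson", "wilcoxon", "ratio"}
        assert report["pearson"]["grade"] in {"strong", "moderate", "weak", "negligible"}
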