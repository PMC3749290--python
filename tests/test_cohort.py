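import numpy as np
import pandas as pd
import pytest

from lungdens import (
    CohortSpec,
    bonferroni_threshold,
    ci_band_intersection,
    compare_groups,
    compare_slopes,
    correlation_matrix,
    fit_age_regression,
    generate_cohort,
    validate_cohort,
    validate_lv_tlc,
    variance_explained,
)
from lungdens.cohort import RegressionBand, choose_correlation_method, correlate
from lungdens.errors import DataError, DegenerateInputError


def _two_group_frame(x_cf, x_ctrl, metric="EI"):
    return pd.DataFrame(
        {
            "group": ["CF"] * len(x_cf) + ["control"] * len(x_ctrl),
            metric: list(x_cf) + list(x_ctrl),
        }
    )


class TestCompareGroups:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 1, 15)
        df = _two_group_frame(vals, vals)
        for test in ("t", "wilcoxon"):
            res = compare_groups(df, "EI", test=test)
            assert res.p_value > 0.9
        res = compare_groups(df, "EI", test="t")
        diff = res.summaries["CF"].mean - res.summaries["control"].mean
        assert diff == pytest.approx(0.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        cf = rng.normal(10, 1, 20)
        ctrl = rng.normal(4, 1, 20)  # > 3 pooled SDs apart
        res = compare_groups(_two_group_frame(cf, ctrl), "EI")
        assert res.p_value < 1e-3

    def test_ranksum_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        cf = rng.normal(2, 1, 12)
        ctrl = rng.normal(1, 1, 10)
        a = compare_groups(_two_group_frame(cf, ctrl), "EI", test="wilcoxon")
        b = compare_groups(
            _two_group_frame(np.exp(cf), np.exp(ctrl)), "EI", test="wilcoxon"
        )
        assert a.statistic == b.statistic
        assert a.p_value == pytest.approx(b.p_value)

    def test_missing_group_data(self):
        df = _two_group_frame([1.0, 2.0], [np.nan, np.nan])
        with pytest.raises(DataError):
            compare_groups(df, "EI")


class TestCorrelations:
    def test_perfect_anticorrelation_both_methods(self):
        x = np.linspace(0, 1, 20)
        for method in ("pearson", "spearman"):
            r, p = correlate(x, -x, method)
            assert r == pytest.approx(-1.0)
            assert p < 1e-6

    def test_method_assignment_rule(self):
        assert choose_correlation_method("EI", "FEV1") == "spearman"
        assert choose_correlation_method("LV", "FEV1pct") == "spearman"
        assert choose_correlation_method("LV", "RV_TLC") == "spearman"
        assert choose_correlation_method("LV", "FEV1") == "pearson"
        assert choose_correlation_method("MLD", "TLC") == "pearson"

    def test_bonferroni_threshold_seven_tests(self):
        thr = bonferroni_threshold(0.05, 7)
        assert thr == pytest.approx(0.05 / 7)
        assert round(thr, 3) == 0.007

    def test_bonferroni_flag_reproducible(self):
        df, _ = generate_cohort(CohortSpec(seed=3))
        for res in correlation_matrix(df, group="CF"):
            if res.defined:
                assert res.significant_bonferroni == (
                    res.p_value < res.alpha / res.m_tests
                )

    def test_constant_column_reported_not_raised(self):
        df = pd.DataFrame(
            {"EI": [0.1] * 6, "FEV1": [1.0, 2, 3, 4, 5, 6], "group": ["CF"] * 6}
        )
        res = correlation_matrix(df, ["EI"], ["FEV1"])[0]
        assert not res.defined
        assert not res.significant_bonferroni
        assert "constant" in res.note

    def test_exact_permutation_small_n(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        r, p = correlate(x, x**3, "spearman")  # monotone, rho = 1
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(2 / 720, rel=0.01)  # 2 of 6! pairings


class TestVarianceExplained:
    @pytest.mark.parametrize("r,expected", [(-0.66, 43), (0.0, 0), (1.0, 100), (0.33, 10)])
    def test_truncated_percent(self, r, expected):
        assert variance_explained(r) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            variance_explained(1.5)


class TestAgeRegression:
    def test_noiseless_slope_recovered_exactly(self):
        ages = np.linspace(10, 60, 25)
        df = pd.DataFrame({"age": ages, "EI_pct": 0.35 * ages + 1.0})
        band = fit_age_regression(df, "EI_pct")
        assert band.slope == pytest.approx(0.35)
        assert band.intercept == pytest.approx(1.0)
        assert band.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_band_width_at_mean_age_closed_form(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(5, 65, 40)
        df = pd.DataFrame({"age": ages, "EI_pct": 0.3 * ages + rng.normal(0, 2, 40)})
        band = fit_age_regression(df, "EI_pct")
        lo, hi = band.band(band.age_mean)
        expected = 2 * band.t_crit * band.residual_sd / np.sqrt(band.n)
        assert hi - lo == pytest.approx(expected)

    def test_band_brackets_fit_and_is_narrowest_at_mean(self):
        df, _ = generate_cohort(CohortSpec(seed=7))
        dfp = df.assign(EI_pct=100 * df["EI"])
        band = fit_age_regression(dfp[dfp.group == "CF"], "EI_pct")
        ages = np.linspace(5, 65, 50)
        lo, hi = band.band(ages)
        fit = band.predict(ages)
        assert np.all(lo <= fit) and np.all(fit <= hi)
        widths = hi - lo
        assert widths.min() == pytest.approx((hi - lo)[np.argmin(np.abs(ages - band.age_mean))])

    def test_band_recomputable_from_stored_parameters(self):
        df, _ = generate_cohort(CohortSpec(seed=8))
        dfp = df.assign(EI_pct=100 * df["EI"])
        band = fit_age_regression(dfp[dfp.group == "CF"], "EI_pct")
        clone = RegressionBand(
            band.slope, band.intercept, band.residual_sd, band.n,
            band.age_mean, band.age_ssx, band.ci_level,
        )
        ages = np.linspace(5, 65, 13)
        np.testing.assert_allclose(clone.band(ages), band.band(ages))

    def test_degenerate_design(self):
        df = pd.DataFrame({"age": [20.0, 20.0, 20.0], "EI_pct": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateInputError):
            fit_age_regression(df, "EI_pct")


class TestBandIntersection:
    def test_identical_cohorts_never_separate(self):
        df, _ = generate_cohort(CohortSpec(seed=9))
        dfp = df.assign(EI_pct=100 * df["EI"])
        band = fit_age_regression(dfp[dfp.group == "CF"], "EI_pct")
        onset = ci_band_intersection(band, band, (5.0, 65.0))
        assert onset.age is None

    def test_designed_crossing_recovered(self):
        df, truth = generate_cohort(CohortSpec(seed=10))
        dfp = df.assign(EI_pct=100 * df["EI"])
        bcf = fit_age_regression(dfp[dfp.group == "CF"], "EI_pct")
        bct = fit_age_regression(dfp[dfp.group == "control"], "EI_pct")
        onset = ci_band_intersection(bcf, bct, (4.0, 68.0))
        assert onset.age is not None

    def test_fully_separated_range_flagged(self):
        cf = RegressionBand(0.3, 50.0, 0.5, 30, 35.0, 4000.0)
        ctrl = RegressionBand(0.01, 0.0, 0.5, 30, 35.0, 4000.0)
        onset = ci_band_intersection(cf, ctrl, (5.0, 65.0))
        assert onset.age == 5.0
        assert onset.separated_at_range_start


class TestSlopeComparison:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(11)
        ages = rng.uniform(5, 65, 30)
        y = 0.2 * ages + rng.normal(0, 1, 30)
        df = pd.DataFrame(
            {
                "age": np.concatenate([ages, ages]),
                "EI_pct": np.concatenate([y, y]),
                "group": ["CF"] * 30 + ["control"] * 30,
            }
        )
        res = compare_slopes(df, "EI_pct")
        assert res.slope_difference == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.99

    def test_label_swap_leaves_p_unchanged(self):
        df, _ = generate_cohort(CohortSpec(seed=12))
        dfp = df.assign(EI_pct=100 * df["EI"])
        p1 = compare_slopes(dfp, "EI_pct").p_value
        swapped = dfp.assign(
            group=dfp["group"].map({"CF": "control", "control": "CF"})
        )
        p2 = compare_slopes(swapped, "EI_pct").p_value
        assert p1 == pytest.approx(p2)


class TestLvTlc:
    def test_perfect_agreement(self):
        tlc = np.linspace(3, 7, 10)
        df = pd.DataFrame({"LV": tlc * 1000.0, "TLC": tlc})
        assert validate_lv_tlc(df).coefficient == pytest.approx(1.0)

    def test_unit_invariance(self):
        df, _ = generate_cohort(CohortSpec(seed=13))
        r_ml = validate_lv_tlc(df).coefficient
        df2 = df.assign(LV=df["LV"] * 1000.0)  # absurd units, same correlation
        assert validate_lv_tlc(df2).coefficient == pytest.approx(r_ml)

    def test_generator_construction_gives_high_r(self):
        df, _ = generate_cohort(CohortSpec(seed=14))
        assert validate_lv_tlc(df).coefficient > 0.9


def test_validate_cohort_rejects_bad_ei():
    df = pd.DataFrame({"group": ["CF"], "age": [20.0], "EI": [1.5]})
    with pytest.raises(DataError):
        validate_cohort(df)
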