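"""Cohort statistics relating densitometry to lung function and age.

The cohort lives in a pandas ``DataFrame`` with one row per subject and
columns named after :class:`SubjectRecord` fields.  The analysis mirrors the
standard design for this kind of study:

* group comparisons by Student's t-test (when both groups look normal under
  Shapiro-Wilk) or the Wilcoxon rank-sum test,
* a densitometry x pulmonary-function correlation matrix, Pearson for
  absolute-valued variables and Spearman for the emphysema index and
  percent-predicted / ratio variables, with Bonferroni correction at
  alpha/m (m = number of PFT variables tested per densitometry metric,
  7 in the default design, i.e. a per-test threshold of 0.05/7 ~ 0.007),
* ordinary least-squares regression of a metric on age with the t-based 95%
  confidence band for the mean response, the age at which the CF band
  separates from the control band (an operationalization of "the CI limits
  intersect"), and an ANCOVA interaction test for equality of slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateInputError

#: Column order of a cohort CSV (one row per subject; empty cells = missing).
SUBJECT_FIELDS = [
    "id",
    "group",
    "age",
    "sex",
    "FEV1",
    "FEV1pct",
    "VC",
    "VCpct",
    "FEV1_VC",
    "RV",
    "RVpct",
    "TLC",
    "TLCpct",
    "RV_TLC",
    "LV",
    "EV",
    "EI",
    "MLD",
    "LW",
    "perc15",
    "pft_mdct_gap_days",
]

#: PFT variables of the default correlation design (7 tests per metric).
DEFAULT_PFT_METRICS = ["FEV1", "FEV1pct", "VC", "FEV1_VC", "RV", "TLC", "RV_TLC"]
DEFAULT_MDCT_METRICS = ["LV", "LW", "EV", "EI", "MLD", "perc15"]

#: Variables analysed with Spearman rank correlation: the emphysema index and
#: dimensionless percent-predicted / ratio variables.  Absolute-valued
#: variables use Pearson.
SPEARMAN_VARIABLES = {
    "EI",
    "FEV1pct",
    "VCpct",
    "RVpct",
    "TLCpct",
    "RV_TLC",
    "FEV1_VC",
}

DEFAULT_ALPHA = 0.05


@dataclass
class SubjectRecord:
    """One subject: demographics, pulmonary function, densitometry metrics.

    Pulmonary function values (plethysmography/spirometry) are inputs, never
    computed here.  EI is stored as a fraction of 1.
    """

    id: str
    group: Literal["CF", "control"]
    age: float
    sex: str = ""
    FEV1: Optional[float] = None
    FEV1pct: Optional[float] = None
    VC: Optional[float] = None
    VCpct: Optional[float] = None
    FEV1_VC: Optional[float] = None
    RV: Optional[float] = None
    RVpct: Optional[float] = None
    TLC: Optional[float] = None
    TLCpct: Optional[float] = None
    RV_TLC: Optional[float] = None
    LV: Optional[float] = None
    EV: Optional[float] = None
    EI: Optional[float] = None
    MLD: Optional[float] = None
    LW: Optional[float] = None
    perc15: Optional[float] = None
    pft_mdct_gap_days: Optional[float] = None


def cohort_from_records(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=SUBJECT_FIELDS)


def validate_cohort(df: pd.DataFrame) -> None:
    """Check SubjectRecord invariants; raises :class:`DataError` on violation."""
    if "group" not in df or "age" not in df:
        raise DataError("cohort table needs 'group' and 'age' columns")
    if not set(df["group"].dropna()).issubset({"CF", "control"}):
        raise DataError("group must be 'CF' or 'control'")
    if (df["age"].dropna() <= 0).any():
        raise DataError("age must be positive")
    if "EI" in df:
        ei = df["EI"].dropna()
        if ((ei < 0) | (ei > 1)).any():
            raise DataError("EI must be a fraction in [0, 1]")
    if {"RV", "TLC", "RV_TLC"}.issubset(df.columns):
        sub = df[["RV", "TLC", "RV_TLC"]].dropna()
        if len(sub) and not np.allclose(
            sub["RV_TLC"], sub["RV"] / sub["TLC"], atol=0.01
        ):
            raise DataError("RV_TLC inconsistent with RV/TLC")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_cohort(df)
    return df


# ---------------------------------------------------------------------------
# Group comparison


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float

    def formatted(self, style: str) -> str:
        if style == "mean_sd":
            return f"{self.mean:.2f} ± {self.sd:.2f}"
        return f"{self.median:.2f} ({self.minimum:.2f}-{self.maximum:.2f})"


@dataclass
class GroupComparison:
    metric: str
    test_used: Literal["t", "wilcoxon"]
    statistic: float
    p_value: float
    summaries: dict[str, GroupSummary]
    summary_style: str  # "mean_sd" for t, "median_range" for wilcoxon


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def compare_groups(
    cohort: pd.DataFrame,
    metric: str,
    test: Literal["auto", "t", "wilcoxon"] = "auto",
) -> GroupComparison:
    """Compare CF vs control for one metric.

    ``auto`` uses Student's t-test when both groups pass Shapiro-Wilk at 0.05
    and the Wilcoxon rank-sum (Mann-Whitney U) test otherwise; summaries are
    mean +/- SD for t and median (range) for the rank test.
    """
    groups = {}
    for g in ("CF", "control"):
        vals = cohort.loc[cohort["group"] == g, metric].dropna().to_numpy(float)
        if vals.size == 0:
            raise DataError(f"metric {metric!r} absent for all of group {g!r}")
        groups[g] = vals
    x, y = groups["CF"], groups["control"]
    if test == "auto":
        test = "t" if (_is_normal(x) and _is_normal(y)) else "wilcoxon"
    if test == "t":
        res = stats.ttest_ind(x, y, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        style = "mean_sd"
    else:
        try:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        except ValueError:  # zero variance everywhere
            stat, p = float(len(x) * len(y) / 2), 1.0
        if math.isnan(p):
            p = 1.0
        style = "median_range"
    summaries = {
        g: GroupSummary(
            n=len(v),
            mean=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            median=float(np.median(v)),
            minimum=float(np.min(v)),
            maximum=float(np.max(v)),
        )
        for g, v in groups.items()
    }
    if math.isnan(stat):
        stat, p = 0.0, 1.0
    return GroupComparison(metric, test, stat, p, summaries, style)


# ---------------------------------------------------------------------------
# Correlation matrix


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    method: Literal["pearson", "spearman"]
    coefficient: float
    p_value: float
    n: int
    m_tests: int = 1
    alpha: float = DEFAULT_ALPHA
    note: str = ""

    @property
    def defined(self) -> bool:
        return math.isfinite(self.coefficient)

    @property
    def significant_bonferroni(self) -> bool:
        return self.defined and self.p_value < self.alpha / self.m_tests


def choose_correlation_method(x_name: str, y_name: str) -> str:
    """Spearman when either variable is EI or a percent/ratio; else Pearson."""
    if x_name in SPEARMAN_VARIABLES or y_name in SPEARMAN_VARIABLES:
        return "spearman"
    return "pearson"


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with average ranks; exact permutation p below n=10,
    t-approximation otherwise."""
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    if not math.isfinite(rho):
        return rho, float("nan")
    if n < 10:
        def statistic(perm_y):
            return stats.spearmanr(x, perm_y).statistic

        res = stats.permutation_test(
            (y,),
            statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=math.factorial(n),
            rng=0,
        )
        return rho, float(res.pvalue)
    return rho, float(stats.spearmanr(x, y).pvalue)


def correlate(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    return _spearman(x, y)


def correlation_matrix(
    cohort: pd.DataFrame,
    mdct_metrics: Sequence[str] = DEFAULT_MDCT_METRICS,
    pft_metrics: Sequence[str] = DEFAULT_PFT_METRICS,
    alpha: float = DEFAULT_ALPHA,
    group: str | None = None,
) -> list[CorrelationResult]:
    """All (densitometry, PFT) pairwise correlations with Bonferroni flags.

    ``m`` is the number of PFT variables tested per densitometry metric
    (recomputed from the actual list).  Undefined correlations (constant
    columns) are reported with NaN coefficients, never raised.
    """
    df = cohort if group is None else cohort[cohort["group"] == group]
    m = len(pft_metrics)
    results: list[CorrelationResult] = []
    for xm in mdct_metrics:
        for ym in pft_metrics:
            sub = df[[xm, ym]].dropna()
            n = len(sub)
            method = choose_correlation_method(xm, ym)
            if n < 4:
                results.append(
                    CorrelationResult(xm, ym, method, float("nan"), float("nan"), n, m, alpha, "fewer than 4 paired observations")
                )
                continue
            r, p = correlate(sub[xm].to_numpy(), sub[ym].to_numpy(), method)
            note = "" if math.isfinite(r) else "undefined (constant column)"
            results.append(CorrelationResult(xm, ym, method, r, p, n, m, alpha, note))
    return results


def correlation_matrix_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mdct_metric": r.x_name,
                "pft_metric": r.y_name,
                "method": r.method,
                "coefficient": r.coefficient,
                "p_value": r.p_value,
                "n": r.n,
                "m_tests": r.m_tests,
                "significant_bonferroni": r.significant_bonferroni,
                "note": r.note,
            }
            for r in results
        ]
    )


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA, m: int = 7) -> float:
    """Per-test significance threshold alpha/m (0.05/7 ~ 0.00714...)."""
    return alpha / m


def variance_explained(r: float) -> int:
    """Percent of variance explained, 100*r^2 truncated to an integer.

    Truncation (not rounding) matches the conventional display of r_s^2:
    r = -0.66 gives 43.56 -> 43%.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation coefficient must be in [-1, 1]")
    return int(100.0 * r * r)


# ---------------------------------------------------------------------------
# Age regression and confidence bands


@dataclass
class RegressionBand:
    """OLS fit of a metric on age with the t-based mean-response CI band."""

    slope: float
    intercept: float
    residual_sd: float
    n: int
    age_mean: float
    age_ssx: float  # sum of squared age deviations
    ci_level: float = 0.95

    @property
    def t_crit(self) -> float:
        return float(stats.t.ppf(0.5 + self.ci_level / 2.0, self.n - 2))

    def predict(self, age):
        age = np.asarray(age, float)
        return self.intercept + self.slope * age

    def se_mean(self, age):
        age = np.asarray(age, float)
        return self.residual_sd * np.sqrt(
            1.0 / self.n + (age - self.age_mean) ** 2 / self.age_ssx
        )

    def band(self, age):
        """Lower/upper limits of the mean-response confidence band."""
        fit = self.predict(age)
        hw = self.t_crit * self.se_mean(age)
        return fit - hw, fit + hw

    def slope_ci(self) -> tuple[float, float]:
        se = self.residual_sd / math.sqrt(self.age_ssx)
        return (self.slope - self.t_crit * se, self.slope + self.t_crit * se)


def fit_age_regression(
    cohort: pd.DataFrame,
    y: str,
    age_col: str = "age",
    ci_level: float = 0.95,
) -> RegressionBand:
    """Ordinary least squares of a metric on age with a 95% CI band."""
    sub = cohort[[age_col, y]].dropna()
    ages = sub[age_col].to_numpy(float)
    ys = sub[y].to_numpy(float)
    if len(np.unique(ages)) < 3:
        raise DegenerateInputError("need at least 3 distinct ages")
    res = stats.linregress(ages, ys)
    n = len(ages)
    resid = ys - (res.intercept + res.slope * ages)
    s = math.sqrt(float(resid @ resid) / (n - 2))
    ssx = float(((ages - ages.mean()) ** 2).sum())
    return RegressionBand(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=s,
        n=n,
        age_mean=float(ages.mean()),
        age_ssx=ssx,
        ci_level=ci_level,
    )


@dataclass
class OnsetEstimate:
    """First age at which the CF lower CI limit exceeds the control upper limit."""

    age: Optional[float]
    separated_at_range_start: bool = False


def ci_band_intersection(
    band_cf: RegressionBand,
    band_ctrl: RegressionBand,
    age_range: tuple[float, float],
    precision: float = 0.1,
) -> OnsetEstimate:
    """Smallest age where the two 95% bands separate, to 0.1-year precision.

    Separation means the CF band's lower limit is at or above the control
    band's upper limit.  Returns ``age=None`` if the bands never separate in
    range; if they are separated over the entire range, the range minimum is
    returned with ``separated_at_range_start=True``.
    """
    lo, hi = age_range
    ages = np.arange(lo, hi + precision * 0.5, precision)
    diff = band_cf.band(ages)[0] - band_ctrl.band(ages)[1]
    sep = diff >= 0
    if not sep.any():
        return OnsetEstimate(None)
    first = int(np.argmax(sep))
    if first == 0:
        return OnsetEstimate(float(ages[0]), separated_at_range_start=True)
    # bisect the continuous difference inside the bracketing interval
    a, b = float(ages[first - 1]), float(ages[first])
    f = lambda t: float(band_cf.band(t)[0] - band_ctrl.band(t)[1])
    for _ in range(30):
        mid = 0.5 * (a + b)
        if f(mid) >= 0:
            b = mid
        else:
            a = mid
        if b - a < precision / 10:
            break
    return OnsetEstimate(round(b, 2))


@dataclass
class SlopeComparison:
    slope_cf: float
    slope_ctrl: float
    slope_difference: float
    t_statistic: float
    p_value: float
    df: int


def compare_slopes(
    cohort: pd.DataFrame,
    y: str,
    group_col: str = "group",
    age_col: str = "age",
) -> SlopeComparison:
    """Test slope equality via the group x age interaction in a pooled OLS
    model (ANCOVA with pooled residual variance); two-sided p-value."""
    import statsmodels.api as sm

    sub = cohort[[age_col, y, group_col]].dropna()
    ages = sub[age_col].to_numpy(float)
    ys = sub[y].to_numpy(float)
    g = (sub[group_col] == "CF").to_numpy(float)
    if len(np.unique(ages[g == 1])) < 3 or len(np.unique(ages[g == 0])) < 3:
        raise DegenerateInputError("need >= 3 distinct ages per group")
    X = sm.add_constant(np.column_stack([ages, g, ages * g]))
    fit = sm.OLS(ys, X).fit()
    b_age, b_int = float(fit.params[1]), float(fit.params[3])
    return SlopeComparison(
        slope_cf=b_age + b_int,
        slope_ctrl=b_age,
        slope_difference=b_int,
        t_statistic=float(fit.tvalues[3]),
        p_value=float(fit.pvalues[3]),
        df=int(fit.df_resid),
    )


def validate_lv_tlc(cohort: pd.DataFrame) -> CorrelationResult:
    """Pooled Pearson correlation of CT lung volume (converted to litres)
    against plethysmographic TLC — the segmentation sanity check."""
    sub = cohort[["LV", "TLC"]].dropna()
    if len(sub) < 4:
        raise DataError("need at least 4 subjects with both LV and TLC")
    lv_l = sub["LV"].to_numpy(float) / 1000.0
    tlc = sub["TLC"].to_numpy(float)
    r, p = correlate(lv_l, tlc, "pearson")
    note = "" if math.isfinite(r) else "undefined (constant column)"
    return CorrelationResult("LV", "TLC", "pearson", r, p, len(sub), 1, DEFAULT_ALPHA, note)
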