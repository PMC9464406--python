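"""Statistical analysis layer: reliability, correlation, regression, prediction.

Implements the study-style analysis of a cohort of hip records: ICC
reliability of repeated measurements, Pearson correlations between angles,
chi-square comparison of categorical data, a Shapiro-Wilk normality gate,
Welch/Student group comparisons formatted "mean +/- sd (range)", a
forced-entry (all predictors entered simultaneously) multiple linear
regression of the femoral anteversion angle on the AW angle and sex with
standard diagnostics (standardized betas, 95% CIs, F, adjusted R^2,
Durbin-Watson, +/-3 SD outlier screen), and the sex-specific rounded
approximation equations derived from the fit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.stattools import durbin_watson as _dw

__all__ = [
    "ICCResult",
    "RegressionFit",
    "PredictionModel",
    "StatsError",
    "pearson_r",
    "icc",
    "chi_square_counts",
    "normality_gate",
    "group_compare",
    "ols_forced",
    "make_prediction_model",
    "predict_fa",
    "error_gt10_fraction",
    "pooled_mean",
    "round_half_up",
    "format_mean_sd_range",
    "format_p",
    "analyze_cohort",
]

MALE_CODE = 1  # sex coding: 0 = female, 1 = male
FEMALE_CODE = 0


class StatsError(ValueError):
    """Invalid input to a statistical routine (degenerate variance etc.)."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (away from zero on ties), e.g. -0.668 -> -0.7."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def format_mean_sd_range(values) -> str:
    """Summary string in the tables' "mean +/- sd (range)" style."""
    v = np.asarray(values, dtype=float)
    return (f"{v.mean():.1f} ± {v.std(ddof=1):.1f} "
            f"({v.min():.1f}–{v.max():.1f})")


# ---------------------------------------------------------------------------
# elementary tests


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need matched samples of n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatsError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def chi_square_counts(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a contingency table of counts.

    Continuity correction is off by default (SPSS-style Pearson chi-square);
    enable it via ``correction=True``.
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise StatsError("table must hold non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("zero marginal in the contingency table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def normality_gate(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk test; returns (W, p, passed) with passed = (p >= alpha)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= len(v) <= 5000:
        raise StatsError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise StatsError("constant input")
    w, p = sps.shapiro(v)
    return float(w), float(p), bool(p >= alpha)


def group_compare(values_a, values_b, welch: bool = True) -> dict:
    """Two-sided two-sample t-test with table-style group summaries.

    Welch's unequal-variance test by default; ``welch=False`` gives the
    pooled-variance Student test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return {
        "summary_a": format_mean_sd_range(a),
        "summary_b": format_mean_sd_range(b),
        "t": float(t),
        "p": float(p),
        "p_display": format_p(float(p)),
    }


def pooled_mean(group_means, group_counts) -> float:
    """Count-weighted mean of subgroup means, reported at one decimal."""
    m = np.asarray(group_means, dtype=float)
    c = np.asarray(group_counts, dtype=float)
    if m.shape != c.shape:
        raise StatsError("group_means and group_counts must have equal length")
    if (c <= 0).any():
        raise StatsError("counts must be positive")
    return round_half_up(float(np.sum(m * c) / np.sum(c)), 1)


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass(frozen=True)
class ICCResult:
    icc_value: float
    model_label: str
    ci95: tuple[float, float]
    mean_squares: dict = field(default_factory=dict, compare=False)


def icc(replicate_matrix, flavor: str = "ICC2", alpha: float = 0.05) -> ICCResult:
    """ANOVA-based intraclass correlation of an (n subjects x k raters) matrix.

    Flavors: ``ICC1`` (one-way random), ``ICC2`` (two-way random effects,
    absolute agreement, single measures -- the default, the standard choice
    for a two-rater reliability study) and ``ICC3`` (two-way mixed,
    consistency).  Confidence intervals follow the Shrout-Fleiss F-based
    formulas; the underlying mean squares are exposed on the result.
    """
    Y = np.asarray(replicate_matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 5 or Y.shape[1] < 2:
        raise StatsError("need a matrix of >= 5 subjects by >= 2 raters/sessions")
    if np.ptp(Y) == 0 or np.isclose(Y.var(axis=0), 0).all():
        raise StatsError("degenerate (constant) replicate matrix")
    n, k = Y.shape
    grand = Y.mean()
    row = Y.mean(axis=1)
    col = Y.mean(axis=0)
    ss_rows = k * np.sum((row - grand) ** 2)
    ss_cols = n * np.sum((col - grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_cols + ss_err) / (n * (k - 1))
    ms = {"MSR": msr, "MSC": msc, "MSE": mse, "MSW": msw}

    if flavor == "ICC1":
        val = (msr - msw) / (msr + (k - 1) * msw)
        f = msr / msw
        fl = f / sps.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        fu = f * sps.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        label = "one-way random, single measures"
    elif flavor == "ICC3":
        val = (msr - mse) / (msr + (k - 1) * mse)
        f = msr / mse
        df2 = (n - 1) * (k - 1)
        fl = f / sps.f.ppf(1 - alpha / 2, n - 1, df2)
        fu = f * sps.f.ppf(1 - alpha / 2, df2, n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        label = "two-way mixed, consistency, single measures"
    elif flavor == "ICC2":
        val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        label = "two-way random, absolute agreement, single measures"
        if mse <= 1e-12 * msr:  # perfect agreement: the F-based CI degenerates
            return ICCResult(icc_value=float(val), model_label=label,
                             ci95=(float(val), float(val)), mean_squares=ms)
        # Shrout & Fleiss CI for ICC(2,1)
        fj = msc / mse
        a = k * val / (n * (1 - val))
        b = 1 + k * val * (n - 1) / (n * (1 - val))
        v = (a * fj + b) ** 2 / (
            (a * fj) ** 2 / (k - 1) + b**2 / ((n - 1) * (k - 1))
        )
        f_star1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_star2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_star1 * mse) / (
            f_star1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_star2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_star2 * msr
        )
    else:
        raise StatsError(f"unknown ICC flavor {flavor!r}")
    return ICCResult(icc_value=float(val), model_label=label,
                     ci95=(float(lo), float(hi)), mean_squares=ms)


# ---------------------------------------------------------------------------
# forced-entry multiple regression


@dataclass(frozen=True)
class RegressionFit:
    """Forced-entry OLS fit of FA on (AW, sex) with the study's diagnostics."""

    coef: dict
    se: dict
    std_beta: dict
    p_values: dict
    ci95: dict
    r_squared: float
    adj_r_squared: float
    f_stat: float
    f_df: tuple[int, int]
    f_pvalue: float
    durbin_watson: float
    residuals: np.ndarray = field(repr=False, compare=False)
    outlier_flags: np.ndarray = field(repr=False, compare=False)
    n: int = 0

    def table(self) -> pd.DataFrame:
        """Regression table: B, SE B, standardized beta, P, 95% CI."""
        rows = []
        for name in ("const", "aw", "sex"):
            rows.append({
                "variable": {"const": "Constant", "aw": "Anterior wall angle",
                             "sex": "Sex"}[name],
                "B": self.coef[name],
                "SE B": self.se[name],
                "beta": self.std_beta[name],
                "P value": self.p_values[name],
                "CI lower": self.ci95[name][0],
                "CI upper": self.ci95[name][1],
            })
        return pd.DataFrame(rows)


def ols_forced(y, aw, sex) -> RegressionFit:
    """Forced-entry OLS of ``y`` on the AW angle and sex (0=female, 1=male).

    Both predictors enter simultaneously (no selection).  Standardized
    betas are B * sd(x)/sd(y); the outlier screen flags standardized
    residuals beyond +/-3 SD.
    """
    y = np.asarray(y, dtype=float)
    aw = np.asarray(aw, dtype=float)
    sex = np.asarray(sex, dtype=float)
    n = len(y)
    if n <= 3:
        raise StatsError("need n > k + 1 = 3 observations")
    X = np.column_stack([aw, sex])
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < 3:
        bad = "sex" if np.ptp(sex) == 0 else "aw"
        raise StatsError(f"design matrix is rank deficient (column {bad!r})")
    model = sm.OLS(y, sm.add_constant(pd.DataFrame({"aw": aw, "sex": sex})))
    res = model.fit()
    names = {"const": "const", "aw": "aw", "sex": "sex"}
    sd_y = y.std(ddof=1)
    std_beta = {"const": 0.0,
                "aw": float(res.params["aw"] * aw.std(ddof=1) / sd_y),
                "sex": float(res.params["sex"] * sex.std(ddof=1) / sd_y)}
    ci = res.conf_int(alpha=0.05)
    resid = np.asarray(res.resid)
    std_resid = resid / resid.std(ddof=1)
    return RegressionFit(
        coef={k: float(res.params[v]) for k, v in names.items()},
        se={k: float(res.bse[v]) for k, v in names.items()},
        std_beta=std_beta,
        p_values={k: float(res.pvalues[v]) for k, v in names.items()},
        ci95={k: (float(ci.loc[v, 0]), float(ci.loc[v, 1])) for k, v in names.items()},
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        f_df=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue),
        durbin_watson=float(_dw(resid)),
        residuals=resid,
        outlier_flags=np.abs(std_resid) > 3.0,
        n=n,
    )


# ---------------------------------------------------------------------------
# prediction equations


@dataclass(frozen=True)
class PredictionModel:
    """FA-prediction equations: full precision plus rounded display forms.

    The rounded sex-specific equations use half-up rounding at one decimal:
    FA_male = slope * AW + male_intercept, FA_female = slope * AW +
    female_intercept.
    """

    coef_const: float
    coef_aw: float
    coef_sex: float

    @property
    def rounded_slope(self) -> float:
        return round_half_up(self.coef_aw, 1)

    @property
    def male_intercept(self) -> float:
        return self.coef_const + self.coef_sex

    @property
    def female_intercept(self) -> float:
        return self.coef_const

    @property
    def rounded_male_intercept(self) -> float:
        return round_half_up(self.male_intercept, 1)

    @property
    def rounded_female_intercept(self) -> float:
        return round_half_up(self.female_intercept, 1)

    def equations(self) -> dict:
        def eq(intercept):
            sign = "+" if intercept >= 0 else "−"
            return f"FA = AW × {self.rounded_slope:.1f} {sign} {abs(intercept):.1f}"

        return {"male": eq(self.rounded_male_intercept),
                "female": eq(self.rounded_female_intercept)}


def make_prediction_model(fit: RegressionFit | dict) -> PredictionModel:
    """Sex-specific prediction equations from a forced-entry fit.

    With sex coded 0 = female / 1 = male, the female intercept is the model
    constant and the male intercept is constant + sex effect.
    """
    coef = fit.coef if isinstance(fit, RegressionFit) else fit
    return PredictionModel(coef_const=float(coef["const"]),
                           coef_aw=float(coef["aw"]),
                           coef_sex=float(coef["sex"]))


def predict_fa(aw, sex, model: PredictionModel, rounded: bool = False):
    """Predicted FA (degrees) for an AW angle and sex ('male'/'female' or 0/1)."""
    aw = np.asarray(aw, dtype=float)
    if isinstance(sex, str):
        male = np.asarray(sex.lower() == "male")
    else:
        male = np.asarray(sex).astype(bool)
    if rounded:
        icpt = np.where(male, model.rounded_male_intercept, model.rounded_female_intercept)
        out = model.rounded_slope * aw + icpt
    else:
        out = model.coef_const + model.coef_aw * aw + model.coef_sex * male
    return float(out) if out.ndim == 0 else out


def error_gt10_fraction(cohort: pd.DataFrame, model: PredictionModel,
                        threshold: float = 10.0) -> float:
    """Fraction of hips whose rounded-equation prediction errs by more than 10 deg.

    The comparison is a strict inequality: an error of exactly 10.0 deg does
    not count as exceeding.
    """
    if len(cohort) == 0:
        raise StatsError("empty cohort")
    pred = predict_fa(cohort["aw"].to_numpy(),
                      (cohort["sex"] == "male").to_numpy(), model, rounded=True)
    err = np.abs(cohort["fa"].to_numpy() - pred)
    return float(np.mean(err > threshold))


# ---------------------------------------------------------------------------
# cohort-level bundle


def analyze_cohort(cohort: pd.DataFrame) -> dict:
    """Study-style analysis bundle for a cohort table.

    Returns group summaries by sex and by group, correlations, normality
    checks, the forced-entry regression with diagnostics, the prediction
    model and the >10-degree-error fraction.
    """
    out: dict = {"n_hips": int(len(cohort))}
    males = cohort[cohort["sex"] == "male"]
    females = cohort[cohort["sex"] == "female"]
    out["by_sex"] = {
        var: group_compare(males[var], females[var])
        for var in ("fa", "aw", "nsa")
    }
    onfh = cohort[cohort["group"] == "ONFH"]
    normal = cohort[cohort["group"] == "normal"]
    if len(onfh) >= 2 and len(normal) >= 2:
        out["by_group"] = {
            var: group_compare(onfh[var], normal[var])
            for var in ("fa", "aw", "nsa")
        }
    out["pearson"] = {
        "fa_vs_aw": pearson_r(cohort["fa"], cohort["aw"]),
        "fa_vs_nsa": pearson_r(cohort["fa"], cohort["nsa"]),
    }
    out["shapiro"] = {
        var: normality_gate(cohort[var]) for var in ("fa", "aw", "nsa")
    }
    fit = ols_forced(cohort["fa"], cohort["aw"], cohort["sex_code"])
    model = make_prediction_model(fit)
    out["fit"] = fit
    out["model"] = model
    out["equations"] = model.equations()
    out["error_gt10_fraction"] = error_gt10_fraction(cohort, model)
    out["outlier_count"] = int(fit.outlier_flags.sum())
    return out
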