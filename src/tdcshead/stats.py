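"""Group-comparison battery: covariate-adjusted regressions with Cohen's
f-squared, rank/independence/normality tests, Bonferroni correction, and the
minimum-detectable-effect sensitivity analysis.

Conventions follow the analysis this package replicates: group is coded
control = 0 / comparison = 1, sex male = 1 / female = 0, regressions adjust
for age and sex, and Cohen's f^2 for the group term is the R^2-increment
form f^2 = (R2_full - R2_reduced) / (1 - R2_full) with the reduced model
dropping only the group column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps


class DataError(ValueError):
    pass


class CollinearityError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    """Group-term summary of one covariate-adjusted linear regression."""

    outcome: str
    contrast: str
    estimate: float
    se: float
    t: float
    p: float
    f2: float
    n: int
    covariates: tuple

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "contrast": self.contrast,
            "estimate": self.estimate,
            "se": self.se,
            "t": self.t,
            "p": self.p,
            "f2": self.f2,
            "n": self.n,
            "covariates": ",".join(self.covariates),
        }


@dataclass(frozen=True)
class TestResult:
    """One demographic test (W = Mann-Whitney/Wilcoxon rank-sum in the R
    reporting convention, X2 = chi-squared independence, D = one-sample KS)."""

    name: str
    statistic: float
    p: float
    n: tuple


def _design(table: pd.DataFrame, group_pair, covariates):
    g0, g1 = group_pair
    sub = table[table["group"].isin(group_pair)].copy()
    counts = sub["group"].value_counts()
    if counts.get(g0, 0) < 2 or counts.get(g1, 0) < 2:
        raise DataError(f"need >= 2 subjects per group, got {dict(counts)}")
    sub["group_code"] = (sub["group"] == g1).astype(float)
    cols = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = (sub["sex"] == "male").astype(float)
        else:
            if cov not in sub.columns:
                raise DataError(f"missing covariate column {cov!r}")
            cols[cov] = sub[cov].astype(float)
    X = pd.DataFrame({"group_code": sub["group_code"], **cols}, index=sub.index)
    return sub, X


def fit_group_model(
    table: pd.DataFrame,
    outcome: str,
    group_pair=("control", "psychosis"),
    covariates=("age", "sex"),
) -> RegressionResult:
    """OLS of outcome ~ group + covariates; reports the group coefficient.

    Raises :class:`CollinearityError` on a rank-deficient design and
    :class:`DataError` on missing columns or undersized groups.
    """
    if outcome not in table.columns:
        raise DataError(f"missing outcome column {outcome!r}")
    sub, X = _design(table, group_pair, covariates)
    y = sub[outcome].astype(float).to_numpy()
    if np.isnan(y).any():
        raise DataError(f"outcome {outcome!r} contains missing values")
    Xc = sm.add_constant(X.to_numpy())
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise CollinearityError(
            f"design matrix for {outcome!r} is rank deficient "
            f"(columns: const, {', '.join(X.columns)})"
        )
    full = sm.OLS(y, Xc).fit()
    reduced = sm.OLS(y, Xc[:, [0] + list(range(2, Xc.shape[1]))]).fit()
    f2 = cohens_f2(full.rsquared, reduced.rsquared)
    return RegressionResult(
        outcome=outcome,
        contrast=f"{group_pair[0]}_vs_{group_pair[1]}",
        estimate=float(full.params[1]),
        se=float(full.bse[1]),
        t=float(full.tvalues[1]),
        p=float(full.pvalues[1]),
        f2=f2,
        n=len(y),
        covariates=tuple(covariates),
    )


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """f^2 = (R2_full - R2_reduced) / (1 - R2_full)."""
    if not 0 <= r2_full < 1:
        raise ValueError(f"R2_full must be in [0, 1), got {r2_full}")
    if r2_reduced < 0 or r2_reduced > r2_full + 1e-12:
        raise ValueError(
            f"R2_reduced must be in [0, R2_full], got {r2_reduced} > {r2_full}"
        )
    return float(max(r2_full - r2_reduced, 0.0) / (1.0 - r2_full))


def f2_power(
    f2: float, n_total: int, n_predictors: int, df_test: int = 1,
    alpha: float = 0.05, lambda_convention: str = "n_total",
) -> float:
    """Power of the partial F test of `df_test` terms at effect size f^2.

    The noncentrality is lambda = f^2 * N (total-sample convention, default)
    or f^2 * (df_denominator + df_test + 1); both are in common software use.
    """
    df2 = n_total - n_predictors - 1
    if df2 <= 0:
        raise ValueError("non-positive denominator degrees of freedom")
    if lambda_convention == "n_total":
        lam = f2 * n_total
    elif lambda_convention == "df_denom":
        lam = f2 * (df2 + df_test + 1)
    else:
        raise ValueError(f"unknown lambda convention {lambda_convention!r}")
    crit = sps.f.isf(alpha, df_test, df2)
    return float(sps.ncf.sf(crit, df_test, df2, lam))


def min_detectable_f2(
    n_total: int, n_predictors: int, df_test: int = 1,
    alpha: float = 0.05, power: float = 0.80,
    lambda_convention: str = "n_total",
) -> float:
    """Smallest f^2 the design detects at the requested power (noncentral-F
    inversion by monotone root finding)."""
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if n_total <= n_predictors + 1:
        raise ValueError("sample too small for the predictor count")

    def gap(f2):
        return f2_power(f2, n_total, n_predictors, df_test, alpha,
                        lambda_convention) - power

    hi = 0.1
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("requested power unattainable for this design")
    return float(optimize.brentq(gap, 1e-12, hi, xtol=1e-12))


@dataclass(frozen=True)
class BonferroniAlpha:
    raw: float
    printed: float
    m: int


def bonferroni_alpha(family_alpha: float, m: int) -> BonferroniAlpha:
    """Per-test alpha = family alpha / m, with the value rounded to one
    significant figure alongside (the precision it is conventionally
    reported at, e.g. 0.05/16 -> 0.003)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    raw = family_alpha / m
    exponent = int(np.floor(np.log10(raw)))
    printed = round(raw, -exponent)
    return BonferroniAlpha(raw=float(raw), printed=float(printed), m=int(m))


def rank_sum_test(x, y) -> TestResult:
    """Two-sample Wilcoxon rank-sum; W reported as the Mann-Whitney U of the
    first sample (the R ``wilcox.test`` convention).  Exact p for small
    untied samples, otherwise normal approximation with tie correction and
    continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("need >= 2 observations per sample")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult("W", float(res.statistic), float(res.pvalue), (len(x), len(y)))


def chi2_independence(table_2x2) -> TestResult:
    """Chi-squared test of independence (Yates-corrected, as R does for 2x2)."""
    arr = np.asarray(table_2x2, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DataError("chi-squared table has an empty margin")
    stat, p, _dof, _exp = sps.chi2_contingency(arr, correction=True)
    return TestResult("X2", float(stat), float(p), tuple(int(v) for v in arr.sum(axis=1)))


def ks_normality(x, reference: str = "fitted") -> TestResult:
    """One-sample Kolmogorov-Smirnov D against a normal reference.

    ``reference="fitted"`` uses the sample mean/SD; ``"standard"`` tests
    against N(0, 1) directly (an unstandardised variable then gives D near
    1, which is how D = 1 arises for raw age or BMI)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise DataError("need >= 2 observations")
    if reference == "fitted":
        args = (x.mean(), x.std(ddof=1))
    elif reference == "standard":
        args = (0.0, 1.0)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    res = sps.kstest(x, "norm", args=args)
    return TestResult("D", float(res.statistic), float(res.pvalue), (len(x),))


def demographic_tests(
    table: pd.DataFrame,
    group_pair=("control", "psychosis"),
    continuous=("age", "bmi"),
    categorical="sex",
) -> dict:
    """The demographic battery: rank-sum per continuous variable, chi-squared
    for the categorical one, and a KS normality check per continuous
    variable (against N(0,1), flagging non-standardised scales)."""
    g0, g1 = group_pair
    a = table[table["group"] == g0]
    b = table[table["group"] == g1]
    if len(a) < 2 or len(b) < 2:
        raise DataError("need >= 2 subjects per group")
    out = {}
    for var in continuous:
        out[f"ranksum_{var}"] = rank_sum_test(a[var], b[var])
        out[f"ks_{var}"] = ks_normality(
            pd.concat([a[var], b[var]]).to_numpy(), reference="standard"
        )
    ct = pd.crosstab(
        table.loc[table["group"].isin(group_pair), "group"],
        table.loc[table["group"].isin(group_pair), categorical],
    ).to_numpy()
    out[f"chi2_{categorical}"] = chi2_independence(ct)
    return out


def group_comparison_table(
    table: pd.DataFrame,
    outcomes,
    contrasts=(("control", "psychosis"), ("control", "relative")),
    covariates=("age", "sex"),
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """One regression row per outcome x contrast, Bonferroni-corrected over
    the whole family (the analysis battery is 8 outcomes x 2 contrasts = 16
    tests, hence the 0.05/16 = 0.003 threshold)."""
    rows = []
    for outcome in outcomes:
        for pair in contrasts:
            rows.append(fit_group_model(table, outcome, pair, covariates).to_dict())
    df = pd.DataFrame(rows)
    corr = bonferroni_alpha(family_alpha, len(df))
    df["alpha_corrected"] = corr.raw
    df["significant_corrected"] = df["p"] < corr.raw
    df["significant_uncorrected"] = df["p"] < family_alpha
    return df
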