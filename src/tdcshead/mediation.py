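"""Causal mediation analysis with linear models and a pairs bootstrap.

Two covariate-adjusted linear models are fitted:

    mediator ~ treatment + covariates            (treatment coefficient a)
    outcome  ~ treatment + mediator + covariates (mediator b, treatment c')

Without a treatment-by-mediator interaction the average causal mediation
effect is the product ACME = a * b, the average direct effect is ADE = c',
and for OLS fits with a common covariate set the total effect (the
treatment coefficient of outcome ~ treatment + covariates) decomposes
exactly as total = ACME + ADE.  Uncertainty comes from a nonparametric
bootstrap: subjects are resampled with replacement as whole rows, both
models refitted, and percentile intervals and two-sided bootstrap p-values
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import DataError


class DesignError(ValueError):
    pass


class UndefinedProportionError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class MediationResult:
    """ACME / ADE / total-effect estimates with bootstrap intervals."""

    treatment: str
    mediator: str
    outcome: str
    acme: EffectEstimate
    ade: EffectEstimate
    total: EffectEstimate
    n: int
    n_boot: int
    seed: int
    covariates: tuple

    def to_dict(self) -> dict:
        d = {"treatment": self.treatment, "mediator": self.mediator,
             "outcome": self.outcome, "n": self.n, "n_boot": self.n_boot}
        for name in ("acme", "ade", "total"):
            eff = getattr(self, name)
            d.update({f"{name}": eff.estimate, f"{name}_ci_low": eff.ci_low,
                      f"{name}_ci_high": eff.ci_high, f"{name}_p": eff.p})
        d["proportion_mediated_pct"] = proportion_mediated(self)
        return d


def _lstsq_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    # normal equations; designs here are tiny and well-conditioned
    return np.linalg.solve(X.T @ X, X.T @ y)


def _boot_p(draws: np.ndarray, n_boot: int) -> float:
    """Two-sided percentile bootstrap p, floored at 2/n_boot."""
    frac_le = np.mean(draws <= 0.0)
    frac_ge = np.mean(draws >= 0.0)
    return float(min(1.0, max(2.0 * min(frac_le, frac_ge), 2.0 / n_boot)))


def mediate(
    table: pd.DataFrame,
    mediator: str,
    outcome: str,
    treatment: str = "group",
    treatment_levels=("control", "psychosis"),
    covariates=("age", "sex"),
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Product-of-coefficients mediation with nonparametric bootstrap CIs.

    `treatment` must be two-level (coded 0/1 in the order of
    `treatment_levels`); mediator and outcome are continuous columns.
    """
    if n_boot < 100:
        raise DesignError("n_boot < 100 gives unusable percentile intervals")
    sub = table[table[treatment].isin(treatment_levels)]
    levels = sub[treatment].unique()
    if len(levels) < 2:
        raise DesignError(
            f"treatment {treatment!r} has a single level {list(levels)} "
            f"in the data"
        )
    if len(sub) < 20:
        raise DataError(f"need >= 20 subjects, got {len(sub)}")
    for col in (mediator, outcome):
        if col not in sub.columns:
            raise DataError(f"missing column {col!r}")

    t = (sub[treatment] == treatment_levels[1]).to_numpy(dtype=float)
    m = sub[mediator].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    covs = []
    for cov in covariates:
        if cov == "sex":
            covs.append((sub["sex"] == "male").to_numpy(dtype=float))
        else:
            covs.append(sub[cov].to_numpy(dtype=float))
    n = len(sub)
    ones = np.ones(n)
    Xm = np.column_stack([ones, t] + covs)            # mediator model
    Xy = np.column_stack([ones, t, m] + covs)         # outcome model

    def effects(idx):
        a = _lstsq_coef(Xm[idx], m[idx])[1]
        cy = _lstsq_coef(Xy[idx], y[idx])
        c_prime, b = cy[1], cy[2]
        acme = a * b
        return acme, c_prime, acme + c_prime

    all_idx = np.arange(n)
    acme0, ade0, tot0 = effects(all_idx)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 3))
    for i in range(n_boot):
        draws[i] = effects(rng.integers(0, n, size=n))
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2], axis=0)

    def eff(point, col):
        return EffectEstimate(float(point), float(lo[col]), float(hi[col]),
                              _boot_p(draws[:, col], n_boot))

    return MediationResult(
        treatment=treatment,
        mediator=mediator,
        outcome=outcome,
        acme=eff(acme0, 0),
        ade=eff(ade0, 1),
        total=eff(tot0, 2),
        n=n,
        n_boot=n_boot,
        seed=seed,
        covariates=tuple(covariates),
    )


def proportion_mediated(result: MediationResult) -> float:
    """100 * ACME / total from the point estimates.

    When ACME and the total effect have opposite signs the signed ratio is
    returned as-is (negative percentage) -- interpret with care.
    """
    if result.total.estimate == 0:
        raise UndefinedProportionError("total effect is zero; proportion undefined")
    return float(100.0 * result.acme.estimate / result.total.estimate)


def classify_mediation(result: MediationResult, alpha: float = 0.05) -> str:
    """'full' if the indirect path is significant and the direct path is
    not; 'partial' if both are; 'none' if the indirect path is not."""
    if result.acme.p >= alpha:
        return "none"
    return "full" if result.ade.p >= alpha else "partial"


def mediation_table(
    table: pd.DataFrame,
    analyses,
    treatment_levels=("control", "psychosis"),
    covariates=("age", "sex"),
    n_boot: int = 1000,
    seed: int = 0,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """One mediation row per (mediator, outcome) pair, Bonferroni-corrected
    over the family (12 analyses at 0.05/12 = 0.004 in the standard
    battery), with full/partial/none classification at the corrected alpha.
    """
    from .stats import bonferroni_alpha

    rows = []
    for i, (mediator, outcome) in enumerate(analyses):
        res = mediate(
            table, mediator, outcome,
            treatment_levels=treatment_levels, covariates=covariates,
            n_boot=n_boot, seed=seed + i,
        )
        row = res.to_dict()
        rows.append(row)
    df = pd.DataFrame(rows)
    corr = bonferroni_alpha(family_alpha, len(df))
    df["alpha_corrected"] = corr.raw
    df["acme_significant_corrected"] = df["acme_p"] < corr.raw
    df["classification"] = [
        classify_mediation(
            _result_from_row(r), alpha=corr.raw
        ) for r in rows
    ]
    return df


def _result_from_row(row: dict) -> MediationResult:
    def eff(name):
        return EffectEstimate(row[name], row[f"{name}_ci_low"],
                              row[f"{name}_ci_high"], row[f"{name}_p"])

    return MediationResult(
        treatment=row["treatment"], mediator=row["mediator"],
        outcome=row["outcome"], acme=eff("acme"), ade=eff("ade"),
        total=eff("total"), n=row["n"], n_boot=row["n_boot"], seed=0,
        covariates=(),
    )
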