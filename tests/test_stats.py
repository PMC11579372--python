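"""Regression battery, effect sizes, sensitivity analysis, rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdcshead.stats import (
    BonferroniAlpha,
    CollinearityError,
    bonferroni_alpha,
    chi2_independence,
    cohens_f2,
    demographic_tests,
    f2_power,
    fit_group_model,
    ks_normality,
    min_detectable_f2,
    rank_sum_test,
)


def _toy_cohort(n_per_group, group_effect, noise_sd, seed, age_effect=0.0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = np.repeat(["control", "psychosis"], n_per_group)
    code = (group == "psychosis").astype(float)
    age = rng.normal(40, 12, n)
    sex = rng.random(n) < 0.5
    y = group_effect * code + age_effect * age + rng.normal(0, noise_sd, n)
    return pd.DataFrame({
        "group": group, "age": age,
        "sex": np.where(sex, "male", "female"), "y": y,
    })


class TestGroupRegression:
    def test_recovers_known_group_effect(self):
        table = _toy_cohort(250, group_effect=-0.03, noise_sd=0.05, seed=0)
        res = fit_group_model(table, "y")
        assert abs(res.estimate - (-0.03)) < 3 * res.se
        assert res.t == pytest.approx(res.estimate / res.se, rel=1e-9)
        assert res.n == 500

    def test_estimate_matches_normal_equations_oracle(self):
        table = _toy_cohort(100, group_effect=0.5, noise_sd=1.0, seed=1)
        res = fit_group_model(table, "y")
        X = np.column_stack([
            np.ones(len(table)),
            (table["group"] == "psychosis").astype(float),
            table["age"],
            (table["sex"] == "male").astype(float),
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ table["y"].to_numpy())
        assert res.estimate == pytest.approx(beta[1], rel=1e-9)

    def test_null_when_outcome_is_pure_age(self):
        # outcome carried entirely by a covariate: the group term is null
        # (noise residualised against the design keeps the fit
        # non-degenerate while leaving the group coefficient exactly zero)
        # NB: the noise seed must differ from the cohort seed -- the first
        # draw of the cohort stream is the age column itself
        rng = np.random.default_rng(99)
        table = _toy_cohort(250, group_effect=0.0, noise_sd=1.0, seed=2)
        X = np.column_stack([
            np.ones(len(table)),
            (table["group"] == "psychosis").astype(float),
            table["age"],
            (table["sex"] == "male").astype(float),
        ])
        e = rng.normal(0, 0.1, len(table))
        e -= X @ np.linalg.lstsq(X, e, rcond=None)[0]
        table["y"] = table["age"] + e
        res = fit_group_model(table, "y")
        assert abs(res.estimate) < 1e-9
        assert res.p > 0.9

    def test_duplicated_covariate_rejected(self):
        table = _toy_cohort(50, 0.1, 1.0, seed=3)
        table["age2"] = table["age"]
        with pytest.raises(CollinearityError):
            fit_group_model(table, "y", covariates=("age", "age2", "sex"))


class TestCohensF2:
    def test_arithmetic(self):
        assert cohens_f2(0.5, 0.4) == pytest.approx(0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.99))
    def test_identical_r2_gives_zero(self, r2):
        assert cohens_f2(r2, r2) == 0.0

    def test_invalid_domains(self):
        with pytest.raises(ValueError):
            cohens_f2(1.0, 0.5)
        with pytest.raises(ValueError):
            cohens_f2(0.3, 0.5)

    def test_matches_rss_oracle(self):
        # recompute f^2 from residual sums of squares on a random dataset
        rng = np.random.default_rng(7)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = X @ np.array([1.0, 0.4, 0.2, 0.0]) + rng.normal(0, 1, n)

        def rss(A):
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            return ((y - A @ beta) ** 2).sum()

        tss = ((y - y.mean()) ** 2).sum()
        r2_full = 1 - rss(X) / tss
        r2_red = 1 - rss(X[:, [0, 2, 3]]) / tss
        expect = (r2_full - r2_red) / (1 - r2_full)
        assert cohens_f2(r2_full, r2_red) == pytest.approx(expect, rel=1e-12)


class TestSensitivity:
    def test_control_vs_psychosis_design(self):
        # 43 controls + 136 patients, group+age+sex, alpha .05, power .80
        assert round(min_detectable_f2(179, 3), 2) == 0.04

    def test_control_vs_relatives_design(self):
        assert round(min_detectable_f2(116, 3), 2) == 0.07

    def test_monotone_decreasing_in_n(self):
        vals = [min_detectable_f2(n, 3) for n in (60, 120, 240, 480)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_power_roundtrip(self):
        f2 = min_detectable_f2(179, 3, power=0.80)
        assert f2_power(f2, 179, 3) == pytest.approx(0.80, abs=1e-6)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_f2(4, 3)


class TestBonferroni:
    def test_printed_precision(self):
        assert bonferroni_alpha(0.05, 16).printed == 0.003
        assert bonferroni_alpha(0.05, 12).printed == 0.004
        assert bonferroni_alpha(0.05, 1).raw == 0.05

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 500))
    def test_raw_value_and_monotonicity(self, m):
        res = bonferroni_alpha(0.05, m)
        assert isinstance(res, BonferroniAlpha)
        assert res.raw == pytest.approx(0.05 / m)
        assert res.raw <= 0.05

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestRankTests:
    def test_identical_samples_near_null_expectation(self):
        x = np.arange(20, dtype=float)
        res = rank_sum_test(x + 0.25, x + 0.75)  # interleaved, no ties
        assert res.statistic == pytest.approx(200.0, abs=15)  # n1*n2/2 = 200
        assert res.p > 0.5

    def test_exact_p_matches_enumeration_oracle(self):
        # two samples of size 4: enumerate all C(8,4) rank splits
        x = np.array([1.3, 2.1, 0.4, 3.3])
        y = np.array([2.9, 4.1, 5.0, 1.9])
        res = rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1
        u_obs = ranks[:4].sum() - 4 * 5 / 2
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            u = ranks[list(combo)].sum() - 4 * 5 / 2
            total += 1
            if min(u, 16 - u) <= min(u_obs, 16 - u_obs):
                count += 1
        assert res.statistic == pytest.approx(u_obs)
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_balanced_table_independent(self):
        res = chi2_independence([[25, 25], [25, 25]])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_ks_flags_unstandardised_scale(self):
        rng = np.random.default_rng(0)
        ages = rng.normal(40, 12, 150)
        raw = ks_normality(ages, reference="standard")
        fitted = ks_normality(ages, reference="fitted")
        assert raw.statistic > 0.99          # D = 1 against N(0,1)
        assert fitted.statistic < 0.2

    def test_demographic_battery_shapes(self):
        from tdcshead.cohort import simulate_cohort

        table = simulate_cohort(43, 136, 0, seed=11)
        out = demographic_tests(table)
        assert set(out) == {"ranksum_age", "ranksum_bmi", "ks_age", "ks_bmi",
                            "chi2_sex"}
        assert all(0 <= r.p <= 1 for r in out.values())


class TestTypeIError:
    def test_null_rejection_rate_near_alpha(self):
        # 2000 null cohorts of n = 200: the group test should reject at
        # 5% +- 1.5 percentage points
        rejections = 0
        n_sim = 2000
        for seed in range(n_sim):
            table = _toy_cohort(100, group_effect=0.0, noise_sd=1.0, seed=seed)
            if fit_group_model(table, "y").p < 0.05:
                rejections += 1
        rate = rejections / n_sim
        assert 0.035 <= rate <= 0.065
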