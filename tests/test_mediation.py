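"""Mediation engine: identities, null behaviour, coverage, classification."""

import numpy as np
import pandas as pd
import pytest

from tdcshead.mediation import (
    DesignError,
    EffectEstimate,
    MediationResult,
    UndefinedProportionError,
    classify_mediation,
    mediate,
    proportion_mediated,
)


def make_data(n, a, b, direct, noise_sd, seed, group_levels=("control", "psychosis")):
    """Linear mediation generator: m = a*t + e, y = b*m + direct*t + e."""
    rng = np.random.default_rng(seed)
    t = np.repeat([0.0, 1.0], n // 2)
    age = rng.normal(40, 10, n)
    sex = rng.random(n) < 0.5
    m = a * t + rng.normal(0, noise_sd, n)
    y = b * m + direct * t + rng.normal(0, noise_sd, n)
    return pd.DataFrame({
        "group": np.where(t > 0, group_levels[1], group_levels[0]),
        "age": age, "sex": np.where(sex, "male", "female"),
        "mediator": m, "outcome": y,
    })


def _fake_result(acme_p, ade_p, acme=1.0, ade=0.5):
    def eff(v, p):
        return EffectEstimate(v, v - 1, v + 1, p)

    return MediationResult(
        treatment="group", mediator="m", outcome="y",
        acme=eff(acme, acme_p), ade=eff(ade, ade_p),
        total=eff(acme + ade, 0.01), n=100, n_boot=1000, seed=0, covariates=(),
    )


class TestMediate:
    def test_total_equals_acme_plus_ade_exactly(self):
        table = make_data(200, a=1.0, b=0.5, direct=0.5, noise_sd=1.0, seed=0)
        res = mediate(table, "mediator", "outcome", n_boot=200, seed=1)
        assert res.total.estimate == pytest.approx(
            res.acme.estimate + res.ade.estimate, rel=1e-9
        )

    def test_total_matches_group_regression(self):
        from tdcshead.stats import fit_group_model

        table = make_data(300, a=1.0, b=0.5, direct=0.2, noise_sd=1.0, seed=2)
        res = mediate(table, "mediator", "outcome", n_boot=200, seed=1)
        reg = fit_group_model(table, "outcome")
        assert res.total.estimate == pytest.approx(reg.estimate, rel=1e-6)

    def test_null_mediator_path_covers_zero(self):
        table = make_data(500, a=1.0, b=0.0, direct=0.5, noise_sd=1.0, seed=3)
        res = mediate(table, "mediator", "outcome", n_boot=500, seed=2)
        boot_se = (res.acme.ci_high - res.acme.ci_low) / 3.92
        assert abs(res.acme.estimate) < 3 * boot_se
        assert res.acme.ci_low <= 0 <= res.acme.ci_high

    def test_point_estimates_match_closed_form_oracle(self):
        # product-of-coefficients by hand from two normal-equation fits
        table = make_data(240, a=0.8, b=0.6, direct=0.3, noise_sd=0.7, seed=4)
        res = mediate(table, "mediator", "outcome", n_boot=200, seed=0)
        t = (table["group"] == "psychosis").to_numpy(float)
        sexn = (table["sex"] == "male").to_numpy(float)
        Xm = np.column_stack([np.ones(len(table)), t, table["age"], sexn])
        Xy = np.column_stack([np.ones(len(table)), t, table["mediator"],
                              table["age"], sexn])
        a_hat = np.linalg.lstsq(Xm, table["mediator"], rcond=None)[0][1]
        cy = np.linalg.lstsq(Xy, table["outcome"], rcond=None)[0]
        assert res.acme.estimate == pytest.approx(a_hat * cy[2], rel=1e-9)
        assert res.ade.estimate == pytest.approx(cy[1], rel=1e-9)

    def test_seed_determinism(self):
        table = make_data(100, a=1.0, b=0.5, direct=0.5, noise_sd=1.0, seed=5)
        r1 = mediate(table, "mediator", "outcome", n_boot=300, seed=7)
        r2 = mediate(table, "mediator", "outcome", n_boot=300, seed=7)
        assert r1 == r2

    def test_identity_holds_in_every_bootstrap_draw(self):
        # re-run the bootstrap by hand and verify the decomposition per draw
        table = make_data(120, a=1.0, b=0.5, direct=0.5, noise_sd=1.0, seed=6)
        t = (table["group"] == "psychosis").to_numpy(float)
        sexn = (table["sex"] == "male").to_numpy(float)
        Xm = np.column_stack([np.ones(len(table)), t, table["age"], sexn])
        Xy = np.column_stack([np.ones(len(table)), t, table["mediator"],
                              table["age"], sexn])
        Xt = np.column_stack([np.ones(len(table)), t, table["age"], sexn])
        rng = np.random.default_rng(0)
        for _ in range(25):
            idx = rng.integers(0, len(table), len(table))
            a_hat = np.linalg.lstsq(Xm[idx], table["mediator"].to_numpy()[idx],
                                    rcond=None)[0][1]
            cy = np.linalg.lstsq(Xy[idx], table["outcome"].to_numpy()[idx],
                                 rcond=None)[0]
            tot = np.linalg.lstsq(Xt[idx], table["outcome"].to_numpy()[idx],
                                  rcond=None)[0][1]
            assert tot == pytest.approx(a_hat * cy[2] + cy[1], rel=1e-8)

    def test_single_level_treatment_rejected(self):
        table = make_data(100, 1.0, 0.5, 0.5, 1.0, seed=7)
        table["group"] = "control"
        with pytest.raises(DesignError, match="single level"):
            mediate(table, "mediator", "outcome", n_boot=200, seed=0)

    def test_tiny_bootstrap_rejected(self):
        table = make_data(100, 1.0, 0.5, 0.5, 1.0, seed=8)
        with pytest.raises(DesignError, match="n_boot"):
            mediate(table, "mediator", "outcome", n_boot=50, seed=0)

    def test_ci_coverage_of_known_effects(self):
        # a=1, b=0.5, direct=0.5, n=500: nominal-95% percentile intervals
        # should cover the true ACME=0.5 and ADE=0.5 in >= 90% of replicates
        n_rep = 60
        cover_acme = cover_ade = 0
        for rep in range(n_rep):
            table = make_data(500, a=1.0, b=0.5, direct=0.5, noise_sd=1.0,
                              seed=1000 + rep)
            res = mediate(table, "mediator", "outcome", n_boot=300, seed=rep)
            cover_acme += res.acme.ci_low <= 0.5 <= res.acme.ci_high
            cover_ade += res.ade.ci_low <= 0.5 <= res.ade.ci_high
        assert cover_acme / n_rep >= 0.90
        assert cover_ade / n_rep >= 0.90


class TestProportionAndClassification:
    def test_printed_table_example(self):
        # ACME 1.01 with ADE 0.775 -> 56.6% of the 1.785 total
        res = _fake_result(0.001, 0.001, acme=1.01, ade=0.775)
        assert proportion_mediated(res) == pytest.approx(56.58, abs=0.01)

    def test_zero_acme_gives_zero_percent(self):
        res = _fake_result(0.5, 0.01, acme=0.0, ade=0.7)
        assert proportion_mediated(res) == 0.0

    def test_full_mediation_gives_hundred_percent(self):
        res = _fake_result(0.001, 0.9, acme=0.8, ade=0.0)
        assert proportion_mediated(res) == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        res = _fake_result(0.5, 0.5, acme=0.5, ade=-0.5)
        with pytest.raises(UndefinedProportionError):
            proportion_mediated(res)

    def test_classification_rules(self):
        assert classify_mediation(_fake_result(0.001, 0.18)) == "full"
        assert classify_mediation(_fake_result(0.001, 0.001)) == "partial"
        assert classify_mediation(_fake_result(0.5, 0.001)) == "none"
        assert classify_mediation(_fake_result(0.5, 0.9)) == "none"


class TestNullCalibration:
    def test_false_positive_rate_bounded(self):
        # a = b = 0: the ACME test should reject at alpha=.05 in <= 7%
        n_sim = 150
        rejections = 0
        for sim in range(n_sim):
            table = make_data(200, a=0.0, b=0.0, direct=0.0, noise_sd=1.0,
                              seed=5000 + sim)
            res = mediate(table, "mediator", "outcome", n_boot=300, seed=sim)
            rejections += res.acme.p < 0.05
        assert rejections / n_sim <= 0.07
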