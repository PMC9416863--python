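"""Synthetic cohort generator: determinism, calibration, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from dualfactor import (
    CategoricalTarget,
    CohortConfig,
    ConfigError,
    assign_weights_and_strata,
    calibrate_items,
    discretization_attenuation,
    fit_icc,
    generate_cohort,
    invert_spearman_brown,
    rho_for_target_d,
    score_pipeline,
    spearman_brown,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_students": 10, "n_schools": 20},
            {"icc_school": 1.2},
            {"cor_swb_pth": 0.3},
            {"missing_rate": 1.0},
            {"weight_dispersion": -0.1},
            {"skew_strength": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            CohortConfig(**kwargs)

    def test_infeasible_effect_size_rejected(self):
        tgt = {"sex": CategoricalTarget(("A", "B"), (0.5, 0.5), 12.0)}
        with pytest.raises(ConfigError):
            CohortConfig(categorical_targets=tgt)


class TestItemCalibration:
    def test_spearman_brown_examples(self):
        assert spearman_brown(0.49, 4) == pytest.approx(0.7935, abs=5e-4)
        assert spearman_brown(0.0, 4) == 0.0
        assert invert_spearman_brown(0.91, 4) == pytest.approx(0.7165, abs=5e-4)

    def test_calibrated_alpha_targets(self):
        calib = calibrate_items(0.49, 4, levels=5)
        assert calib.alpha_continuous == pytest.approx(0.7935, abs=5e-4)
        assert calib.alpha_discrete < calib.alpha_continuous  # attenuation
        family = calibrate_items(invert_spearman_brown(0.91, 4), 4, levels=5)
        assert family.alpha_continuous == pytest.approx(0.91, abs=1e-3)

    def test_zero_correlation_items(self):
        calib = calibrate_items(0.0, 5, levels=5)
        assert calib.loading == 0.0 and calib.score_factor_cor == 0.0

    def test_invalid_r_bar(self):
        with pytest.raises(ConfigError):
            calibrate_items(1.0, 4, 5)

    def test_monte_carlo_alpha_matches_prediction(self):
        """Discretized items realize the attenuation-corrected alpha."""
        from dualfactor.scales import cronbach_alpha

        rng = np.random.default_rng(77)
        n, k, r = 40_000, 4, 0.49
        calib = calibrate_items(r, k, levels=5)
        f = rng.standard_normal(n)
        X = calib.loading * f[:, None] + np.sqrt(1 - r) * rng.standard_normal((n, k))
        codes = np.searchsorted([-0.8416, -0.2533, 0.2533, 0.8416], X)  # quintile cuts
        assert cronbach_alpha(codes) == pytest.approx(calib.alpha_discrete, abs=0.02)

    def test_attenuation_factor_properties(self):
        a3 = discretization_attenuation(3)
        a5 = discretization_attenuation(5)
        a11 = discretization_attenuation(11)
        assert 0.8 < a3 < a5 < a11 < 1.0
        # closed form for tertiles: cor = 2*phi(z_{1/3}) / sqrt(2/3) ... ~0.891
        assert a3 == pytest.approx(0.8908, abs=1e-3)


class TestRhoCalibration:
    def test_quartile_closed_form_against_simulation(self):
        """Brute-force oracle: bivariate normal + quartile split realizes d."""
        rng = np.random.default_rng(123)
        n = 400_000
        for d_target in (0.3, 0.8, 1.6):
            rho = rho_for_target_d(d_target, (0.25, 0.25, 0.25, 0.25))
            y = rng.standard_normal(n)
            c = rho * y + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            q25, q75 = np.quantile(c, [0.25, 0.75])
            top, bot = y[c > q75], y[c <= q25]
            d_real = (top.mean() - bot.mean()) / np.sqrt(
                (top.var(ddof=1) + bot.var(ddof=1)) / 2
            )
            assert d_real == pytest.approx(d_target, abs=0.02)

    def test_zero_and_negative_targets(self):
        assert rho_for_target_d(0.0, (0.5, 0.5)) == 0.0
        with pytest.raises(ConfigError):
            rho_for_target_d(-0.5, (0.5, 0.5))


class TestWeights:
    def test_zero_dispersion_gives_unit_weights(self):
        rng = np.random.default_rng(0)
        w = assign_weights_and_strata(
            np.repeat("ON", 100), np.repeat(7, 100), 0.0, rng
        )
        np.testing.assert_array_equal(w, np.ones(100))

    def test_mean_exactly_one(self, small_cohort):
        table, _ = small_cohort
        assert table["weight"].mean() == pytest.approx(1.0, abs=1e-12)
        assert (table["weight"] > 0).all()

    def test_weighted_close_to_unweighted(self, scored_panel):
        """Weights are independent of mental health by construction."""
        from dualfactor import weighted_mean_sd

        v = scored_panel["mh_score"].dropna()
        w = scored_panel.loc[v.index, "weight"]
        wm, _ = weighted_mean_sd(v, w)
        assert wm == pytest.approx(v.mean(), abs=5 * 10 / np.sqrt(len(v)))


class TestGeneratedCohort:
    def test_same_seed_byte_identical(self):
        cfg = CohortConfig(n_students=600, n_schools=12, seed=42)
        t1, _ = generate_cohort(cfg)
        t2, _ = generate_cohort(cfg)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_different_seed_differs(self):
        t1, _ = generate_cohort(CohortConfig(n_students=600, n_schools=12, seed=1))
        t2, _ = generate_cohort(CohortConfig(n_students=600, n_schools=12, seed=2))
        assert t1.to_csv(index=False) != t2.to_csv(index=False)

    def test_missingness_rate(self):
        cfg = CohortConfig(n_students=4000, n_schools=80, missing_rate=0.05, seed=9)
        table, _ = generate_cohort(cfg)
        items = [c for c in table.columns if c not in (
            "student_id", "school_id", "weight", "age_years", "sex", "region", "grade")]
        rate = table[items].isna().to_numpy().mean()
        n_cells = len(table) * len(items)
        assert rate == pytest.approx(0.05, abs=4 * np.sqrt(0.05 * 0.95 / n_cells))

    def test_latent_correlation_structure(self, small_cohort):
        _, truth = small_cohort
        per = truth.per_student
        c = np.corrcoef(per["W"], per["P"])[0, 1]
        assert c == pytest.approx(-0.5, abs=0.06)

    def test_zero_icc_cohort_recovers_zero(self):
        cfg = CohortConfig(n_students=8000, n_schools=160, icc_school=0.0, seed=31)
        table, _ = generate_cohort(cfg)
        panel = score_pipeline(table).panel
        comps = fit_icc(panel["mh_score"], panel["school_id"])
        assert comps.icc < 0.01

    def test_monotone_dose_response(self, scored_panel):
        """Generated ordinal covariates give monotone mean scores."""
        from dualfactor import bin_quartiles

        panel = scored_panel[scored_panel["mh_score"].notna()]
        bins = bin_quartiles(panel["family_support"], panel["weight"])
        means = panel.groupby(bins, observed=True)["mh_score"].mean()
        assert list(means.index) == ["High", "Q2", "Q3", "Low"]
        assert means.is_monotonic_decreasing

        srh_means = panel.groupby("self_rated_health", observed=True)["mh_score"].mean()
        assert (
            srh_means["Excellent"] > srh_means["Good"] > srh_means["Fair/poor"]
        )

    def test_realized_d_matches_target_in_sample(self, small_cohort):
        """The generator's own calibration: hopelessness d on the measured z."""
        table, truth = small_cohort
        z = truth.per_student["measured_mh_z"].to_numpy()
        # ground-truth assignment (pre-missingness) via the latent column
        g = truth.per_student["latent_hopeless"]
        yes = z[g.rank(pct=True) <= 0.264 + 1e-9]
        no = z[g.rank(pct=True) > 0.264 + 1e-9]
        d = (no.mean() - yes.mean()) / np.sqrt((no.var(ddof=1) + yes.var(ddof=1)) / 2)
        assert d == pytest.approx(1.43, abs=0.02)

    def test_demographics_consistent(self, small_cohort):
        table, _ = small_cohort
        assert table["age_years"].between(11, 16).all()
        assert set(table["sex"]) <= {"Male", "Female"}
        assert table["grade"].between(6, 10).all()
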