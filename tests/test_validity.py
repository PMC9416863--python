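"""Weighted descriptives, binning, effect sizes, clustered comparisons."""

import numpy as np
import pandas as pd
import pytest

from dualfactor import (
    AnalysisError,
    BinningError,
    CovariateSpec,
    bin_quartiles,
    build_effect_table,
    cohens_d,
    cohens_d_pooled_n,
    complete_case_filter,
    fit_clustered_comparison,
    fit_icc,
    icc,
    minimal_detectable_difference,
    published_reference_table,
    skewness,
    weighted_mean_sd,
    weighted_quantile,
)


class TestWeightedMeanSD:
    def test_equal_weights_match_ordinary_moments(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3, 2, 500)
        m, s = weighted_mean_sd(x, np.ones_like(x))
        assert m == pytest.approx(x.mean())
        assert s == pytest.approx(x.std(ddof=0))

    def test_hand_arithmetic(self):
        m, _ = weighted_mean_sd([0.0, 3.0], [2.0, 1.0])
        assert m == pytest.approx(1.0)

    def test_duplication_equals_weight_doubling(self):
        x = np.array([1.0, 4.0, 9.0])
        m1, s1 = weighted_mean_sd(np.r_[x, [4.0]], np.ones(4))
        m2, s2 = weighted_mean_sd(x, np.array([1.0, 2.0, 1.0]))
        assert (m1, s1) == pytest.approx((m2, s2))

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(AnalysisError):
            weighted_mean_sd([1.0, 2.0], [1.0, 0.0])


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        x = np.array([1.0, 2.0, 5.0])
        assert skewness(np.r_[x, -x]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computation(self):
        # m2 = 0.1875, m3 = 0.09375 -> g1 = 1.1547
        assert skewness([0.0, 0.0, 0.0, 1.0]) == pytest.approx(1.1547, abs=1e-4)

    def test_left_tail_negative(self):
        x = np.r_[np.linspace(-1, 1, 101), [-8.0, -9.0]]
        assert skewness(x) < 0

    def test_zero_variance_errors(self):
        with pytest.raises(AnalysisError):
            skewness([2.0, 2.0, 2.0])


class TestBinQuartiles:
    def test_symmetric_case(self):
        values = np.arange(1.0, 9.0)
        bins = bin_quartiles(values)
        expected = {1: "Low", 2: "Low", 3: "Q3", 4: "Q3", 5: "Q2", 6: "Q2", 7: "High", 8: "High"}
        assert dict(zip(values, bins)) == {k: v for k, v in expected.items()}

    def test_constant_vector_errors(self):
        with pytest.raises(BinningError):
            bin_quartiles(np.ones(10))

    def test_heavily_tied_scale_monotone(self):
        """Ties make bins unequal but membership stays monotone in value."""
        rng = np.random.default_rng(4)
        values = np.minimum(rng.poisson(12, 2000), 16).astype(float)  # pile-up at 16
        bins = bin_quartiles(values)
        rank = {"Low": 0, "Q3": 1, "Q2": 2, "High": 3}
        ranks = np.array([rank[b] for b in bins])
        order = np.argsort(values, kind="mergesort")
        assert (np.diff(ranks[order]) >= 0).all()
        # brute force: every member of a higher bin outscores every lower-bin member
        assert values[ranks == 3].min() > values[ranks == 2].max()

    def test_weighted_cutpoints(self):
        # weight mass concentrated low pushes the quartile cuts down:
        # cum fractions .227/.455/.682/.909 -> cuts at 2, 3, 4
        values = np.arange(1.0, 9.0)
        w = np.array([10.0, 10, 10, 10, 1, 1, 1, 1])
        bins = bin_quartiles(values, w)
        assert list(bins) == ["Low", "Low", "Q3", "Q2", "High", "High", "High", "High"]

    def test_weighted_quantile_definition(self):
        q = weighted_quantile(np.arange(1.0, 9.0), [0.25, 0.5, 0.75])
        np.testing.assert_array_equal(q, [2.0, 4.0, 6.0])


class TestCohensD:
    def test_reference_effect_sizes(self):
        # family support High vs Low, and Male vs Female, from the published
        # validation table
        assert cohens_d(56.0, 7.6, 41.5, 10.0) == pytest.approx(1.63, abs=0.005)
        assert cohens_d(51.6, 8.8, 48.7, 10.5) == pytest.approx(0.30, abs=0.005)

    def test_equal_means_zero(self):
        assert cohens_d(50.0, 9.0, 50.0, 11.0) == 0.0

    def test_antisymmetric(self):
        assert cohens_d(56.0, 7.6, 41.5, 10.0) == pytest.approx(
            -cohens_d(41.5, 10.0, 56.0, 7.6)
        )

    def test_nweighted_variant_differs(self):
        d_n = cohens_d_pooled_n(56.0, 7.6, 5242, 41.5, 10.0, 3904)
        assert d_n == pytest.approx(1.67, abs=0.005)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(AnalysisError):
            cohens_d(50.0, 0.0, 40.0, 10.0)


class TestICC:
    def test_examples(self):
        assert icc(0.0, 5.0) == 0.0
        assert icc(3.8, 96.2) == pytest.approx(0.038)
        assert icc(7.0, 7.0) == pytest.approx(0.5)

    def test_negative_variance_rejected(self):
        with pytest.raises(AnalysisError):
            icc(-1.0, 5.0)


class TestMDD:
    def test_power_bounds(self):
        assert minimal_detectable_difference(6283, 6283) == pytest.approx(0.50, abs=0.005)
        assert minimal_detectable_difference(251, 251) == pytest.approx(2.50, abs=0.01)

    def test_sqrt_scaling(self):
        one = minimal_detectable_difference(400, 400)
        four = minimal_detectable_difference(1600, 1600)
        assert four == pytest.approx(one / 2)

    def test_invalid_alpha(self):
        with pytest.raises(AnalysisError):
            minimal_detectable_difference(100, 100, alpha=1.5)


class TestCompleteCases:
    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": ["x", "y"]})
        kept, report = complete_case_filter(df, ["a", "b"], attrition_vars=())
        pd.testing.assert_frame_equal(kept, df)

    def test_counting_and_report_shape(self):
        df = pd.DataFrame(
            {
                "mh": [1.0] * 7 + [np.nan] * 3,
                "age_years": np.arange(10.0),
                "sex": ["Male", "Female"] * 5,
                "relative_affluence": ["Average"] * 10,
                "self_rated_health": ["Good"] * 10,
            }
        )
        kept, report = complete_case_filter(df, ["mh"])
        assert len(kept) == 7
        assert len(report) == 4

    def test_all_dropped_errors(self):
        df = pd.DataFrame({"a": [np.nan, np.nan]})
        with pytest.raises(AnalysisError):
            complete_case_filter(df, ["a"], attrition_vars=())

    def test_null_attrition_calibration(self):
        """MCAR exclusion: attrition p-values uniform, >0.05 ~95% of the time."""
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(150):
            n = 400
            df = pd.DataFrame(
                {
                    "y": rng.standard_normal(n),
                    "age_years": rng.integers(11, 16, n).astype(float),
                    "sex": np.where(rng.random(n) < 0.5, "Male", "Female"),
                }
            )
            df.loc[rng.random(n) < 0.25, "y"] = np.nan  # MCAR
            _, rep = complete_case_filter(df, ["y"], attrition_vars=("age_years", "sex"))
            pvals.extend(rep["p_value"].dropna().tolist())
        frac = np.mean(np.array(pvals) > 0.05)
        assert 0.90 <= frac <= 0.985


class TestClusteredComparison:
    @staticmethod
    def _simulate(n=4000, s=80, icc_true=0.10, beta=(0.0, -1.0, -2.0), seed=0):
        rng = np.random.default_rng(seed)
        school = np.repeat(np.arange(s), n // s)
        tau = np.sqrt(icc_true / (1 - icc_true))
        g = rng.integers(0, 3, n)
        y = (
            np.array(beta)[g]
            + tau * rng.standard_normal(s)[school]
            + rng.standard_normal(n)
        )
        return pd.DataFrame(
            {
                "mh_score": y,
                "grp": np.array(["Ref", "Mid", "Lowest"])[g],
                "school_id": school,
                "age_band": rng.integers(0, 5, n).astype(str),
                "sex": rng.integers(0, 2, n).astype(str),
            }
        )

    def test_detects_group_effects_and_trend(self):
        df = self._simulate()
        cc = fit_clustered_comparison(df, group="grp", levels=["Ref", "Mid", "Lowest"])
        assert cc.reference == "Ref"
        assert cc.p_by_group["Mid"] < 1e-6
        assert cc.p_by_group["Lowest"] < 1e-6
        assert cc.p_trend < 1e-6

    def test_variance_components_recover_icc(self):
        # average over replicates: a single 80-school draw has ~0.02 SE on
        # the icc plus the chi2 noise of the realized school-effect variance
        iccs = [
            fit_clustered_comparison(
                self._simulate(beta=(0.0, 0.0, 0.0), seed=s),
                group="grp",
                levels=["Ref", "Mid", "Lowest"],
            ).components.icc
            for s in range(5)
        ]
        assert np.mean(iccs) == pytest.approx(0.10, abs=0.025)

    def test_needs_two_schools(self):
        df = self._simulate().assign(school_id=0)
        with pytest.raises(AnalysisError):
            fit_clustered_comparison(df, group="grp")

    def test_fit_icc_zero_when_no_clustering(self):
        rng = np.random.default_rng(8)
        comps = fit_icc(rng.standard_normal(2000), rng.integers(0, 40, 2000))
        assert comps.icc < 0.01


class TestEffectTable:
    def test_percentages_sum_to_100(self, scored_panel):
        filtered, _ = complete_case_filter(
            scored_panel,
            ["mh_score", "family_support", "peer_support", "sex", "age_years"],
            attrition_vars=(),
        )
        et = build_effect_table(
            filtered,
            covariates=[
                CovariateSpec("Family support", "family_support", kind="quartile"),
                CovariateSpec("Sex", "sex", levels=("Male", "Female"), trend=False),
            ],
            fit_models=False,
        )
        for _, block in et.groupby("covariate"):
            assert block["pct"].sum() == pytest.approx(100.0, abs=0.2)
            assert block["reference"].sum() == 1
            ref_rows = block[block["reference"]]
            assert ref_rows["cohens_d"].isna().all()
            assert ref_rows["p_adjusted"].isna().all()

    def test_single_group_covariate_errors(self, scored_panel):
        panel = scored_panel.assign(const="A")
        with pytest.raises(AnalysisError, match="no contrast"):
            build_effect_table(
                panel,
                covariates=[CovariateSpec("Const", "const", levels=("A",))],
                fit_models=False,
            )

    def test_empty_subgroup_errors(self, scored_panel):
        with pytest.raises(AnalysisError):
            build_effect_table(
                scored_panel, subgroup=pd.Series(False, index=scored_panel.index)
            )

    def test_subgroup_restriction_attenuates_effects(self, scored_panel):
        """Truncating to the healthiest quadrant shrinks every |d|."""
        filtered, _ = complete_case_filter(
            scored_panel,
            ["mh_score", "family_support", "teacher_support", "sex", "age_years"],
            attrition_vars=(),
        )
        covs = [
            CovariateSpec("Family support", "family_support", kind="quartile"),
            CovariateSpec("Teacher support", "teacher_support", kind="quartile"),
        ]
        full = build_effect_table(filtered, covariates=covs, fit_models=False)
        healthy = filtered["dual_factor_group"].astype(object) == "Mentally Healthy"
        sub = build_effect_table(
            filtered, covariates=covs, subgroup=healthy, fit_models=False
        )
        f = full[~full.reference].set_index(["covariate", "group"])["cohens_d"]
        s = sub[~sub.reference].set_index(["covariate", "group"])["cohens_d"]
        assert (s.abs() < f.abs().reindex(s.index)).all()


def test_published_reference_table_is_consistent():
    ref = published_reference_table()
    for (_, cov), block in ref.groupby(["table", "covariate"]):
        assert block["pct"].sum() == pytest.approx(100.0, abs=0.3), cov
        assert block["cohens_d"].isna().sum() == 1  # exactly one reference row
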