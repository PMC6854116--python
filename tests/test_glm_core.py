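import numpy as np
import pandas as pd
import pytest

from invrisk.exceptions import FitError
from invrisk.glm_core import (
    DesignSpec,
    Term,
    aicc,
    akaike_weights,
    fit_logistic,
    inv_logit,
    logit,
    lr_test,
    nagelkerke_r2,
    parse_term,
    predict_prob,
    rank_models,
)

CONGENER_DESIGN = DesignSpec(
    "high_impact", (Term("shared_genus", "categorical", "no"),), "Shared genus")
NULL_DESIGN = DesignSpec("high_impact", (), "Null model")

# AICc columns as published for the congener candidate set
TABLE4_AICC = {"Shared genus": 98.778, "Null model": 103.908,
               "Shared family": 104.958}
TABLE3_AICC = [109.547, 114.765, 114.929, 115.567, 116.849,
               116.863, 118.605, 119.142, 121.842, 124.834]
TABLE2_DELTAS = [0.000, 0.603, 1.168, 1.486, 2.765, 2.997, 3.426, 3.483,
                 5.031, 7.343, 8.627, 21.331]


class TestLogitUtilities:
    def test_mutual_inverses(self):
        p = np.concatenate([[1e-12, 1 - 1e-12],
                            np.linspace(0.001, 0.999, 101)])
        np.testing.assert_allclose(inv_logit(logit(p)), p, atol=1e-12)

    def test_zero_coefficients_give_half(self):
        assert inv_logit(0.0) == 0.5


class TestFitLogistic:
    def test_reconstructed_congener_counts_reproduce_published_fit(
            self, congener_counts_data):
        model = fit_logistic(CONGENER_DESIGN, congener_counts_data)
        assert model.params["intercept"] == pytest.approx(-2.180, abs=5e-4)
        assert model.params["shared_genus.yes"] == pytest.approx(-2.124, abs=5e-4)
        assert model.k_params == 2 and model.n == 203

    def test_two_group_fit_matches_closed_form_log_odds(self):
        """MLE on a single binary predictor equals group log-odds exactly."""
        rng = np.random.default_rng(7)
        for n1, s1, n2, s2 in [(128, 13, 75, 1), (20, 5, 30, 12), (9, 4, 7, 2)]:
            df = pd.DataFrame({
                "g": ["a"] * n1 + ["b"] * n2,
                "y": [1] * s1 + [0] * (n1 - s1) + [1] * s2 + [0] * (n2 - s2),
            }).sample(frac=1, random_state=rng.integers(1000)).reset_index(drop=True)
            design = DesignSpec("y", (Term("g", "categorical", "a"),))
            model = fit_logistic(design, df)
            assert model.params["intercept"] == pytest.approx(
                logit(s1 / n1), abs=1e-6)
            assert model.params["g.b"] == pytest.approx(
                logit(s2 / n2) - logit(s1 / n1), abs=1e-6)

    def test_intercept_only_closed_form(self, congener_counts_data):
        model = fit_logistic(NULL_DESIGN, congener_counts_data)
        assert model.params["intercept"] == pytest.approx(np.log(14 / 189), abs=1e-8)

    def test_all_zero_response_is_degenerate(self):
        df = pd.DataFrame({"y": [0] * 20, "x": range(20)})
        with pytest.raises(FitError, match="degenerate"):
            fit_logistic(DesignSpec("y", (Term("x"),)), df)

    def test_rank_deficiency_names_aliased_terms(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.integers(0, 2, 40),
                           "x1": rng.normal(size=40)})
        df["x2"] = 2.0 * df["x1"]
        with pytest.raises(FitError, match="aliased"):
            fit_logistic(DesignSpec("y", (Term("x1"), Term("x2"))), df)

    def test_separation_flagged_not_fatal(self):
        df = pd.DataFrame({"y": [0] * 10 + [1] * 10,
                           "x": list(range(10)) + list(range(20, 30))})
        model = fit_logistic(DesignSpec("y", (Term("x"),)), df)
        assert model.separation_flag

    def test_ridge_stabilizer_shrinks_separated_fit(self):
        df = pd.DataFrame({"y": [0] * 10 + [1] * 10,
                           "x": list(range(10)) + list(range(20, 30))})
        plain = fit_logistic(DesignSpec("y", (Term("x"),)), df)
        ridged = fit_logistic(DesignSpec("y", (Term("x"),)), df, ridge=1e-2)
        assert abs(ridged.params["x"]) < abs(plain.params["x"])

    def test_parameter_recovery_within_three_se(self):
        """Coefficients of the generating model are inside +/-3 SE in
        nearly all replicates at n=2000."""
        rng = np.random.default_rng(42)
        truth = {"intercept": -2.0, "x": 0.8}
        design = DesignSpec("y", (Term("x"),))
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            x = rng.normal(size=2000)
            p = inv_logit(truth["intercept"] + truth["x"] * x)
            df = pd.DataFrame({"x": x, "y": rng.random(2000) < p})
            df["y"] = df["y"].astype(int)
            m = fit_logistic(design, df)
            se = dict(zip(m.columns, m.standard_errors))
            if all(abs(m.params[k] - truth[k]) <= 3 * se[k] for k in truth):
                hits += 1
        assert hits / n_rep >= 0.93


class TestAicc:
    def test_published_congener_aicc_values(self, congener_counts_data):
        model = fit_logistic(CONGENER_DESIGN, congener_counts_data)
        null = fit_logistic(NULL_DESIGN, congener_counts_data)
        assert aicc(model.loglik, 2, 203) == pytest.approx(98.778, abs=5e-4)
        assert aicc(null.loglik, 1, 203) == pytest.approx(103.908, abs=5e-4)

    def test_converges_to_aic_for_large_n(self):
        ll, k = -50.0, 3
        aic = -2 * ll + 2 * k
        assert aicc(ll, k, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(FitError):
            aicc(-10.0, 5, 6)

    def test_monotone_in_loglik_and_k(self):
        assert aicc(-10, 2, 50) < aicc(-11, 2, 50)
        assert aicc(-10, 2, 50) < aicc(-10, 3, 50)


class TestAkaikeWeights:
    def test_published_congener_top_weight(self):
        w = akaike_weights(list(TABLE4_AICC.values()))
        assert w[0] == pytest.approx(0.89, abs=0.005)

    def test_published_host_trait_top_weight(self):
        w = akaike_weights(TABLE3_AICC)
        assert w[0] == pytest.approx(0.79, abs=0.005)

    def test_single_model_weight_one(self):
        assert akaike_weights([42.0]).tolist() == [1.0]

    def test_shift_invariance_and_normalization(self):
        scores = [100.0, 101.3, 105.7, 99.2]
        w = akaike_weights(scores)
        np.testing.assert_allclose(w, akaike_weights([s + 37.0 for s in scores]))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestRankModels:
    def test_confidence_set_from_published_insect_deltas(self):
        """The published insect-trait dAICc column puts exactly four
        models (voltinism; voltinism+repro+dispersal; repro; null) in
        the dAICc <= 2 confidence set."""
        in_set = [d <= 2.0 for d in TABLE2_DELTAS]
        assert sum(in_set) == 4 and in_set[:4] == [True] * 4

    def test_ranking_on_fitted_models(self, congener_counts_data):
        df = congener_counts_data.copy()
        rng = np.random.default_rng(3)
        df["noise"] = rng.normal(size=len(df))
        ranking = rank_models(
            [CONGENER_DESIGN, NULL_DESIGN,
             DesignSpec("high_impact", (Term("noise"),), "Noise")], df)
        assert ranking.best.design.label() == "Shared genus"
        assert ranking.entries[0].delta == 0.0
        assert sum(e.weight for e in ranking.entries) == pytest.approx(1.0)
        assert [e.aicc for e in ranking.entries] == sorted(
            e.aicc for e in ranking.entries)
        assert ranking.confidence_set == (ranking.entries[0],)

    def test_identical_models_share_weight(self, congener_counts_data):
        twin = DesignSpec("high_impact",
                          (Term("shared_genus", "categorical", "no"),), "Twin")
        ranking = rank_models([CONGENER_DESIGN, twin], congener_counts_data)
        assert [e.weight for e in ranking.entries] == pytest.approx([0.5, 0.5])

    def test_failed_candidate_dropped_with_warning(self, congener_counts_data):
        bad = DesignSpec("high_impact", (Term("absent_column"),), "Broken")
        with pytest.warns(UserWarning, match="dropping candidate"):
            ranking = rank_models([CONGENER_DESIGN, bad], congener_counts_data)
        assert len(ranking.entries) == 1


class TestNagelkerke:
    def test_published_congener_r2(self, congener_counts_data):
        model = fit_logistic(CONGENER_DESIGN, congener_counts_data)
        null = fit_logistic(NULL_DESIGN, congener_counts_data)
        assert nagelkerke_r2(model, null) == pytest.approx(0.09, abs=0.005)

    def test_null_vs_itself_is_zero(self, congener_counts_data):
        null = fit_logistic(NULL_DESIGN, congener_counts_data)
        assert nagelkerke_r2(null, null) == pytest.approx(0.0, abs=1e-12)

    def test_near_separating_model_approaches_one(self):
        df = pd.DataFrame({"y": [0] * 50 + [1] * 50,
                           "x": list(np.linspace(-4, -0.5, 50))
                           + list(np.linspace(0.5, 4, 50))})
        model = fit_logistic(DesignSpec("y", (Term("x"),)), df)
        null = fit_logistic(DesignSpec("y", ()), df)
        assert nagelkerke_r2(model, null) > 0.9


class TestLrTest:
    def test_full_equals_nested_gives_zero(self, congener_counts_data):
        m = fit_logistic(CONGENER_DESIGN, congener_counts_data)
        res = lr_test(m, m)
        assert res.G2 == 0.0 and res.p_value == 1.0

    def test_non_nested_rejected(self, congener_counts_data):
        df = congener_counts_data.copy()
        df["x"] = np.arange(len(df))
        a = fit_logistic(DesignSpec("high_impact", (Term("x"),)), df)
        b = fit_logistic(CONGENER_DESIGN, df)
        with pytest.raises(FitError, match="not nested"):
            lr_test(a, b)

    def test_interaction_power_and_df(self):
        """A generating interaction of 2.0 at n=500 is detected by the
        G2 test in the vast majority of replicates."""
        rng = np.random.default_rng(5)
        nested = DesignSpec("y", (Term("x"), Term("g", "categorical", "a")))
        full = DesignSpec("y", (Term("x"), Term("g", "categorical", "a"),
                                Term("xg")))
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            x = rng.normal(size=500)
            g = rng.choice(["a", "b"], 500)
            xg = x * (g == "b")
            p = inv_logit(-1.0 + 0.5 * x + 0.3 * (g == "b") + 2.0 * xg)
            df = pd.DataFrame({"x": x, "g": g, "xg": xg,
                               "y": (rng.random(500) < p).astype(int)})
            res = lr_test(fit_logistic(nested, df), fit_logistic(full, df))
            assert res.df == 1
            rejections += res.p_value < 0.05
        assert rejections / n_rep > 0.8


class TestPredict:
    def test_published_congener_probabilities(self):
        from invrisk.submodels import published_congener_model
        model = published_congener_model()
        assert predict_prob(model, {"shared_genus": "no"}) == pytest.approx(
            0.102, abs=5e-4)
        assert predict_prob(model, {"shared_genus": "yes"}) == pytest.approx(
            0.013, abs=5e-4)

    def test_published_host_trait_probability(self):
        from invrisk.submodels import published_host_traits_model
        model = published_host_traits_model()
        p = predict_prob(model, {"shade_tolerance": "high",
                                 "drought_tolerance": "moderate"})
        assert p == pytest.approx(0.259, abs=5e-4)

    def test_unknown_level_rejected(self):
        from invrisk.submodels import published_congener_model
        with pytest.raises(FitError, match="unknown level"):
            predict_prob(published_congener_model(), {"shared_genus": "maybe"})


class TestTermParsing:
    @pytest.mark.parametrize("text,kind,ref", [
        ("wood_density", "continuous", None),
        ("shade_tolerance(cat,ref=low)", "categorical", "low"),
        ("divergence_time_mya(log10)", "log10", None),
    ])
    def test_round_trip(self, text, kind, ref):
        term = parse_term(text)
        assert term.kind == kind and term.reference == ref

    def test_categorical_without_reference_rejected(self):
        with pytest.raises(FitError):
            Term("x", "categorical")
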