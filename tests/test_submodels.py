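import numpy as np
import pandas as pd
import pytest

from invrisk.census_io import HostRecord, InsectRecord
from invrisk.exceptions import FitError, ValidationError
from invrisk.submodels import (
    AvailabilityContext,
    applicable_submodels,
    assign_congener_status,
    build_candidate_sets,
    fit_host_evolution,
    host_trait_probability_grid,
    load_published_coefficients,
    predict_guild_risk,
    published_guild_model,
)


class TestCandidateSets:
    def test_set_sizes_match_published_tables(self):
        sets = build_candidate_sets()
        assert len(sets["insect"]) == 12
        assert len(sets["host"]) == 10
        assert len(sets["congener"]) == 3

    def test_insect_set_contains_three_trait_model(self):
        sets = build_candidate_sets()
        labels = {d.label(): d for d in sets["insect"]}
        target = labels["Voltinism + Reproductive Strategy + Dispersal"]
        assert target.k_nominal == 5

    def test_host_set_contains_shade_drought_model(self):
        sets = build_candidate_sets()
        labels = {d.label(): d for d in sets["host"]}
        assert labels["Shade tolerance + Drought tolerance"].k_nominal == 6

    def test_congener_set_has_no_global_model(self):
        labels = [d.label() for d in build_candidate_sets()["congener"]]
        assert labels == ["Shared genus", "Null model", "Shared family"]

    def test_null_and_global_present_in_insect_and_host_sets(self):
        sets = build_candidate_sets()
        for family in ("insect", "host"):
            labels = [d.label() for d in sets[family]]
            assert "Null model" in labels and "Global model" in labels


class TestGuildRiskPrediction:
    def test_published_folivore_risk_at_peak_window(self):
        model = published_guild_model("folivore")
        assert predict_guild_risk(model, 2.5) == pytest.approx(0.767, abs=0.005)

    def test_published_sap_feeder_vertex_near_sixteen(self):
        model = published_guild_model("sap_feeder")
        assert model.peak_divergence_mya == pytest.approx(
            10 ** (84.472 / (2 * 35.803)), rel=1e-12)
        assert 15.0 < model.peak_divergence_mya < 16.0

    def test_sap_feeder_risk_vanishes_at_deep_divergence(self):
        model = published_guild_model("sap_feeder")
        assert predict_guild_risk(model, 310.0) < 1e-27

    def test_folivore_peak_location_and_height(self):
        model = published_guild_model("folivore")
        assert model.peak_divergence_mya == pytest.approx(2.66, abs=0.01)
        assert model.peak_probability == pytest.approx(0.769, abs=0.001)

    @pytest.mark.parametrize("guild", ["folivore", "sap_feeder"])
    def test_unimodal_in_log_divergence(self, guild):
        model = published_guild_model(guild)
        t = np.logspace(0, np.log10(340), 400)
        p = predict_guild_risk(model, t)
        peak = np.argmax(p)
        assert np.all(np.diff(p[: peak + 1]) > 0)
        assert np.all(np.diff(p[peak:]) < 0)

    def test_nonpositive_divergence_rejected(self):
        model = published_guild_model("folivore")
        with pytest.raises(ValidationError):
            predict_guild_risk(model, 0.0)


class TestFitHostEvolution:
    def test_recovers_generating_vertex_for_folivores(self):
        """Quadratic fits on data simulated from the published folivore
        curve put the most dangerous divergence in the published
        1.5-5 my window (median over replicates)."""
        truth = published_guild_model("folivore")
        rng = np.random.default_rng(6)
        vertices = []
        for _ in range(200):
            t = 10.0 ** rng.uniform(0, np.log10(340), 49)
            p = predict_guild_risk(truth, t)
            df = pd.DataFrame({
                "guild": "folivore", "divergence_time_mya": t,
                "high_impact": (rng.random(49) < p).astype(int)})
            try:
                model = fit_host_evolution(df, "folivore")
            except FitError:
                continue
            if model.beta2 < 0:
                vertices.append(model.peak_divergence_mya)
        assert 1.5 <= np.median(vertices) <= 5.0

    def test_guild_without_high_impact_cases_refused(self):
        df = pd.DataFrame({
            "guild": ["gall_maker"] * 30,
            "divergence_time_mya": np.linspace(1, 100, 30),
            "high_impact": 0})
        with pytest.raises(FitError, match="gall_maker"):
            fit_host_evolution(df, "gall_maker")

    def test_single_class_folivore_response_refused(self):
        df = pd.DataFrame({
            "guild": ["folivore"] * 30,
            "divergence_time_mya": np.linspace(1, 100, 30),
            "high_impact": 0})
        with pytest.raises(FitError, match="single-class"):
            fit_host_evolution(df, "folivore")

    def test_degenerate_single_divergence_value_rejected(self):
        df = pd.DataFrame({
            "guild": ["sap_feeder"] * 30,
            "divergence_time_mya": 16.0,
            "high_impact": [0, 1] * 15})
        with pytest.raises(FitError, match="aliased|rank"):
            fit_host_evolution(df, "sap_feeder")


class TestHostTraitGrid:
    def test_published_span(self):
        grid = host_trait_probability_grid()
        assert len(grid) == 12
        assert grid["probability"].min() == pytest.approx(0.014, abs=5e-4)
        assert grid["probability"].max() == pytest.approx(0.259, abs=5e-4)

    def test_extremes_at_expected_cells(self):
        grid = host_trait_probability_grid().set_index(
            ["shade_tolerance", "drought_tolerance"])
        assert grid["probability"].idxmax() == ("high", "moderate")
        assert grid["probability"].idxmin() == ("low", "high")


class TestCongenerStatus:
    @staticmethod
    def _insect(genus="adelges", family="adelgidae"):
        return InsectRecord("bug", "hemiptera", family, genus, "sap_feeder",
                            "univoltine", "asexual", "passive", "asia",
                            "pest", 1, ("B",))

    @staticmethod
    def _host(genera):
        return HostRecord("A", "high", "low", "slow", 0.4, "fine", "none",
                          tuple(genera))

    def test_shared_genus(self):
        status = assign_congener_status(
            self._insect(), self._host([("adelges", "adelgidae")]))
        assert status.relation == "shared_genus"
        assert status.shared_family

    def test_shared_family_only(self):
        status = assign_congener_status(
            self._insect(), self._host([("pineus", "adelgidae")]))
        assert status.relation == "shared_family_only"
        assert not status.shared_genus

    def test_empty_native_list_is_none(self):
        assert assign_congener_status(self._insect(), self._host([])).relation == "none"

    def test_missing_family_label_rejected(self):
        with pytest.raises(ValidationError, match="family"):
            assign_congener_status(self._insect(), self._host([("pineus", "")]))

    def test_monotone_under_list_growth(self):
        """Adding genera never moves a pair away from shared_genus."""
        order = {"none": 0, "shared_family_only": 1, "shared_genus": 2}
        base = [("pineus", "adelgidae")]
        grown = base + [("adelges", "adelgidae"), ("cinara", "aphididae")]
        before = assign_congener_status(self._insect(), self._host(base))
        after = assign_congener_status(self._insect(), self._host(grown))
        assert order[after.relation] >= order[before.relation]


class TestAvailability:
    CONTEXT = AvailabilityContext(
        excluded_hosts=frozenset({"poor_host"}),
        pairs_without_divergence=frozenset({("i2", "good_host")}))

    def test_folivore_with_everything_gets_all_three(self):
        subs = applicable_submodels(
            {"insect_id": "i1", "host_id": "good_host"}, self.CONTEXT, "folivore")
        assert set(subs) == {"host_traits", "host_evolution", "insect_evolution"}

    def test_wood_borer_has_no_divergence_model(self):
        subs = applicable_submodels(
            {"insect_id": "i1", "host_id": "good_host"}, self.CONTEXT, "wood_borer")
        assert set(subs) == {"host_traits", "insect_evolution"}

    def test_sap_feeder_on_excluded_host(self):
        subs = applicable_submodels(
            {"insect_id": "i1", "host_id": "poor_host"}, self.CONTEXT, "sap_feeder")
        assert set(subs) == {"host_traits", "host_evolution"}

    def test_pair_without_divergence_data(self):
        subs = applicable_submodels(
            {"insect_id": "i2", "host_id": "good_host"}, self.CONTEXT, "sap_feeder")
        assert set(subs) == {"host_traits", "insect_evolution"}


class TestPublishedCoefficients:
    def test_fixture_matches_declared_values(self):
        coeffs = load_published_coefficients()
        fol = coeffs["host_evolution"]["folivore"]
        assert (fol["intercept"], fol["log10_divergence"],
                fol["log10_divergence_sq"]) == (-0.515, 8.073, -9.495)
        sap = coeffs["host_evolution"]["sap_feeder"]
        assert (sap["intercept"], sap["log10_divergence"],
                sap["log10_divergence_sq"]) == (-51.824, 84.472, -35.803)
        assert coeffs["insect_evolution"]["shared_genus"] == -2.124
        assert coeffs["overall_baseline"] == 0.072

    def test_unknown_guild_rejected(self):
        with pytest.raises(FitError, match="guild"):
            published_guild_model("wood_borer")
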