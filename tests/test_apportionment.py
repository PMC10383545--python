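"""Factor labelling, explained variation, shares and summary statistics."""

import numpy as np
import pandas as pd
import pytest

from sourcerisk import apportionment as app
from sourcerisk.health_risk import risk_series
from sourcerisk.receptor_model import FactorModel
from sourcerisk.speciation_io import SpeciesTable
from sourcerisk.synthetic_data import (default_sources, generate_contributions,
                                       generate_profiles)
from sourcerisk.speciation_io import DEFAULT_SPECIES


def _model(G, F, columns):
    return FactorModel(G=np.asarray(G, float), F=np.asarray(F, float),
                       Q=0.0, Qexp=None, n_iter=1, converged=True, seed=0,
                       columns=list(columns))


@pytest.fixture(scope="module")
def truth_model():
    """A model built from the exact default-campaign ground truth."""
    sources = default_sources()
    F = generate_profiles(sources, DEFAULT_SPECIES, seed=0)
    G = generate_contributions(400, sources, seed=1)
    return _model(G, F, DEFAULT_SPECIES), [s.name for s in sources]


class TestExplainedVariation:
    def test_single_factor_owns_every_species(self):
        m = _model([[1.0], [2.0]], [[0.5, 0.5]], ["A", "B"])
        ev = app.explained_variation(m)
        np.testing.assert_allclose(ev.to_numpy(), 1.0)

    def test_zero_loading_gives_zero_share(self):
        m = _model(np.ones((3, 2)), [[1.0, 0.0], [0.5, 0.5]], ["A", "B"])
        ev = app.explained_variation(m)
        assert ev.loc[0, "B"] == 0.0

    def test_shares_sum_to_one_per_species(self, truth_model):
        model, _ = truth_model
        ev = app.explained_variation(model)
        np.testing.assert_allclose(ev.sum(axis=0), 1.0, atol=1e-9)


class TestLabelFactors:
    def test_default_rules_recover_all_seven_sources(self, truth_model):
        model, names = truth_model
        labels = app.label_factors(model, app.default_tracer_rules())
        assert [labels[k] for k in range(7)] == names

    def test_empty_rule_list_leaves_all_unassigned(self, truth_model):
        model, _ = truth_model
        labels = app.label_factors(model, [])
        assert set(labels.values()) == {"unassigned"}

    def test_single_factor_single_rule(self):
        m = _model([[1.0]], [[0.9, 0.1]], ["V", "OC"])
        labels = app.label_factors(m, [app.TracerRule("heavy_oil", ["V"])])
        assert labels == {0: "heavy_oil"}

    def test_permutation_invariance(self, truth_model):
        model, names = truth_model
        p = np.random.default_rng(0).permutation(7)
        permuted = _model(model.G[:, p], model.F[p], DEFAULT_SPECIES)
        labels = app.label_factors(permuted, app.default_tracer_rules())
        assert [labels[i] for i in range(7)] == [names[j] for j in p]

    def test_rule_without_required_species_rejected(self):
        with pytest.raises(ValueError):
            app.TracerRule("x", [])


class TestMassShares:
    def test_single_factor_is_100_percent(self):
        m = _model([[2.0], [3.0]], [[0.6, 0.4]], ["A", "B"])
        shares = app.mass_shares(m)
        assert shares.iloc[0] == pytest.approx(100.0)

    def test_shares_sum_to_100(self, truth_model):
        model, names = truth_model
        labels = {k: names[k] for k in range(7)}
        shares = app.mass_shares(model, DEFAULT_SPECIES, labels=labels)
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)


class TestRiskShares:
    def _combined_model(self, f_conv_owner):
        """Two factors; metals and conv columns carried as requested."""
        idx = pd.date_range("2018-11-01", periods=6, freq="h")
        table = SpeciesTable(pd.DataFrame(
            {m: np.linspace(5, 10, 6) for m in ("Cr", "Ni", "As", "Cd")},
            index=idx))
        risk = risk_series(table)
        cols = ["Cr", "Ni", "As", "Cd"] + \
            [f"ILCR_conv_{m}" for m in ("Cr", "Ni", "As", "Cd")] + \
            [f"HQ_conv_{m}" for m in ("Cr", "Ni", "As", "Cd")]
        F = np.zeros((2, len(cols)))
        F[0, :4] = 0.25                      # factor 0 carries all metal mass
        F[f_conv_owner, 4:] = 1.0 / 8        # conv columns on the chosen factor
        G = np.ones((6, 2))
        return _model(G, F, cols), risk

    def test_conv_basis_gives_all_risk_to_conv_carrier(self):
        model, risk = self._combined_model(f_conv_owner=1)
        ilcr, hq = app.risk_shares(model, risk, basis="conv_ev")
        assert ilcr.iloc[1] == pytest.approx(100.0)
        assert hq.iloc[1] == pytest.approx(100.0)
        assert ilcr.attrs["basis"] == "conv_ev"

    def test_metal_basis_gives_all_risk_to_metal_carrier(self):
        model, risk = self._combined_model(f_conv_owner=1)
        ilcr, hq = app.risk_shares(model, risk, basis="metal_ev")
        assert ilcr.iloc[0] == pytest.approx(100.0)

    def test_equal_loadings_give_equal_shares(self):
        model, risk = self._combined_model(f_conv_owner=1)
        model.F[:, :] = model.F.sum(axis=0) / 2  # split everything evenly
        ilcr, hq = app.risk_shares(model, risk)
        np.testing.assert_allclose(ilcr.to_numpy(), 50.0, atol=1e-9)

    def test_model_without_pseudo_species_directed_to_combined_fit(self):
        m = _model(np.ones((3, 1)), [[1.0]], ["Cr"])
        idx = pd.date_range("2018-11-01", periods=3, freq="h")
        risk = risk_series(SpeciesTable(pd.DataFrame(
            {mname: [5.0] * 3 for mname in ("Cr", "Ni", "As", "Cd")}, index=idx)))
        with pytest.raises(ValueError, match="combined"):
            app.risk_shares(m, risk)


class TestLifetimeIndex:
    def test_equal_conversions_sum_to_8c(self, small_campaign):
        table, _, _ = small_campaign
        risk = risk_series(table)
        c = 3.0
        for frame in (risk.hq_conv, risk.ilcr_conv):
            frame.iloc[:, :] = c
        idx = app.lifetime_risk_index(risk)
        np.testing.assert_allclose(idx.to_numpy(), 8 * c)

    def test_length_matches_sample_count(self, small_campaign):
        table, _, _ = small_campaign
        idx = app.lifetime_risk_index(risk_series(table))
        assert len(idx) == table.n_samples
        assert (idx >= 0).all()


class TestSummaryStatistics:
    def test_constant_series_has_zero_sd_and_tight_range(self):
        idx = pd.date_range("2018-11-01", periods=5, freq="h")
        t = SpeciesTable(pd.DataFrame({"Fe": [4.0] * 5}, index=idx))
        s = app.summary_statistics(t)["per_species"]
        assert s.loc["Fe", "sd"] == 0.0
        assert s.loc["Fe", "min"] == s.loc["Fe", "max"] == s.loc["Fe", "mean"]

    def test_equal_means_split_inorganic_share_evenly(self):
        idx = pd.date_range("2018-11-01", periods=4, freq="h")
        t = SpeciesTable(pd.DataFrame({"Fe": [2.0] * 4, "Si": [2.0] * 4},
                                      index=idx))
        share = app.summary_statistics(t)["inorganic_share_pct"]
        np.testing.assert_allclose(share, 50.0)

    def test_element_ranking_ordered_by_descending_mean(self):
        idx = pd.date_range("2018-11-01", periods=3, freq="h")
        t = SpeciesTable(pd.DataFrame({"Ca": [1.0] * 3, "Fe": [3.0] * 3,
                                       "Si": [2.0] * 3}, index=idx))
        ranking = app.summary_statistics(t)["element_ranking"]
        assert list(ranking.index) == ["Fe", "Si", "Ca"]
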