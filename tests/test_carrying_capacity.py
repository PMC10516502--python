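"""Carrying-capacity model, validation and rarefaction."""

import numpy as np
import pandas as pd
import pytest

from paleocoex.carrying_capacity import (
    CCParams,
    HerbivoreSpecies,
    NPP_KG_M2_TO_KG_KM2,
    PCOM,
    assign_size_class,
    delta_bias_correct,
    estimate_cc,
    predicted_density,
    rarefy_richness,
    validate_cc,
)
from paleocoex.npp import NPPSeries


def _flat_npp(value=0.3, n=50):
    t = np.arange(55.0, 55.0 - n * 0.5, -0.5)
    return NPPSeries("r", t, np.full(n, value))


class TestSizeClasses:
    @pytest.mark.parametrize(
        "mass,expected",
        [(19.9, "small"), (20.0, "medium"), (300.0, "medium"), (301.0, "large"),
         (1.0, "small"), (95.0, "medium")],
    )
    def test_boundaries(self, mass, expected):
        assert assign_size_class(mass) == expected

    def test_sub_kilogram_rejected(self):
        with pytest.raises(ValueError, match="below 1 kg"):
            assign_size_class(0.5)

    def test_species_class_consistency_enforced(self):
        with pytest.raises(ValueError, match="conflicts"):
            HerbivoreSpecies("x", 50.0, size_class="large")


class TestDeltaBiasCorrect:
    def test_identity_when_sim_equals_obs(self):
        past = np.array([1.0, 2.0, 3.0])
        assert np.allclose(delta_bias_correct(past, 5.0, 5.0, "additive"), past)
        assert np.allclose(delta_bias_correct(past, 5.0, 5.0, "multiplicative"), past)

    def test_constant_additive_shift(self):
        past = np.array([-3.0, 0.0, 4.0])
        out = delta_bias_correct(past, 10.0, 12.0, "additive")
        assert np.allclose(out, past + 2.0)

    def test_multiplicative_ratio_and_zero_preserved(self):
        past = np.array([0.0, 10.0, 40.0])
        out = delta_bias_correct(past, 20.0, 30.0, "multiplicative")
        assert np.allclose(out, past * 1.5)
        assert out[0] == 0.0

    def test_multiplicative_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="positive observed"):
            delta_bias_correct(np.ones(3), 10.0, 0.0, "multiplicative")


class TestEstimateCC:
    def test_zero_npp_gives_zero_cc(self):
        pcom = PCOM("r", [HerbivoreSpecies("deer", 100.0)])
        est = estimate_cc(_flat_npp(0.0), pcom, CCParams(n_draws=20))
        assert est.species["mean"].sum() == 0.0
        assert est.size_classes["mean"].sum() == 0.0

    def test_single_species_closed_form(self):
        params = CCParams(n_draws=50)
        pcom = PCOM("r", [HerbivoreSpecies("horse", 100.0)])
        est = estimate_cc(_flat_npp(0.3), pcom, params)
        expected = params.f * (0.3 * NPP_KG_M2_TO_KG_KM2) ** params.beta
        assert est.species.loc["horse", "mean"] == pytest.approx(expected)
        assert est.class_mean("medium") == pytest.approx(expected)

    def test_homogeneity_in_npp(self):
        params = CCParams(n_draws=20)
        pcom = PCOM(
            "r",
            [HerbivoreSpecies("ibex", 55.0), HerbivoreSpecies("bison", 600.0)],
        )
        e1 = estimate_cc(_flat_npp(0.2), pcom, params)
        e2 = estimate_cc(_flat_npp(0.4), pcom, params)
        # beta = 1: doubling NPP doubles every species' CC
        assert np.allclose(2 * e1.species["mean"], e2.species["mean"])

    def test_size_class_additivity_exact(self):
        params = CCParams(n_draws=20)
        species = [
            HerbivoreSpecies("marmot", 5.5),
            HerbivoreSpecies("ibex", 55.0),
            HerbivoreSpecies("red_deer", 160.0),
            HerbivoreSpecies("bison", 600.0),
        ]
        est = estimate_cc(_flat_npp(), PCOM("r", species), params)
        for cls in ("small", "medium", "large"):
            members = est.species[est.species["size_class"] == cls]
            assert est.class_mean(cls) == pytest.approx(members["mean"].sum())

    def test_monotone_in_npp(self):
        params = CCParams(n_draws=10)
        pcom = PCOM("r", [HerbivoreSpecies("deer", 100.0), HerbivoreSpecies("hare", 3.0)])
        t = np.arange(55.0, 30.0, -0.5)
        rng = np.random.default_rng(0)
        base = 0.2 + 0.05 * rng.random(t.size)
        lo = estimate_cc(NPPSeries("a", t, base), pcom, params)
        hi = estimate_cc(NPPSeries("b", t, base + 0.05), pcom, params)
        assert (hi.species["mean"] >= lo.species["mean"]).all()

    def test_ci_ordering_and_shrinkage(self):
        pcom = PCOM("r", [HerbivoreSpecies("deer", 100.0)])
        few = estimate_cc(_flat_npp(), pcom, CCParams(n_draws=40, seed=1))
        many = estimate_cc(_flat_npp(), pcom, CCParams(n_draws=400, seed=1))
        for est in (few, many):
            row = est.species.iloc[0]
            assert row["ll"] <= row["mean"] <= row["ul"]
        # CI endpoints stabilize (median-of-draws spread shrinks); widths
        # should not blow up with more draws
        w_few = few.species.iloc[0]["ul"] - few.species.iloc[0]["ll"]
        w_many = many.species.iloc[0]["ul"] - many.species.iloc[0]["ll"]
        assert w_many <= 1.5 * w_few

    def test_empty_pcom_rejected(self):
        with pytest.raises(ValueError, match="non-empty species"):
            PCOM("r", [])


class TestValidateCC:
    def _tables(self, noise_sd, seed=0, n_parks=30, n_species=10):
        rng = np.random.default_rng(seed)
        params = CCParams()
        masses = rng.uniform(2, 900, n_species)
        rows_p, rows_o = [], []
        for p in range(n_parks):
            for s in range(n_species):
                pred = predicted_density(masses[s], params)
                rows_p.append({"park": f"p{p}", "species": f"sp{s}", "density": pred})
                rows_o.append(
                    {
                        "park": f"p{p}",
                        "species": f"sp{s}",
                        "density": pred * rng.lognormal(0.0, noise_sd),
                    }
                )
        return pd.DataFrame(rows_p), pd.DataFrame(rows_o)

    def test_perfect_prediction(self):
        pred, obs = self._tables(noise_sd=0.0)
        obs["density"] = pred["density"]
        out = validate_cc(pred, obs)
        assert out["pooled_r"] == pytest.approx(1.0)
        assert (out["per_park"]["r"] > 0.999).all()

    def test_noisy_allometry_recovered(self):
        rs = []
        for seed in range(10):
            pred, obs = self._tables(noise_sd=0.5, seed=seed)
            rs.append(validate_cc(pred, obs)["pooled_r"])
        assert all(0.4 <= r <= 0.95 for r in rs)

    def test_shuffled_observations_null(self):
        rs = []
        for seed in range(10):
            pred, obs = self._tables(noise_sd=0.2, seed=seed)
            rng = np.random.default_rng(seed)
            obs["density"] = rng.permutation(obs["density"].to_numpy())
            rs.append(validate_cc(pred, obs)["pooled_r"])
        assert abs(np.mean(rs)) < 0.15

    def test_small_parks_skipped(self, caplog):
        pred, obs = self._tables(noise_sd=0.1, n_parks=2, n_species=2)
        with caplog.at_level("WARNING"):
            out = validate_cc(pred, obs)
        assert out["per_park"].empty


class TestRarefaction:
    def test_single_shared_species(self):
        inc = pd.DataFrame({"sp1": [1] * 8}, index=[f"L{i}" for i in range(8)])
        out = rarefy_richness(inc, target_units=100, n_bootstrap=100)
        assert out["observed_richness"] == 1
        assert out["extrapolated_richness"] == 1.0
        assert out["ci"] == (1.0, 1.0)

    def test_extrapolation_never_below_observed(self):
        rng = np.random.default_rng(3)
        inc = pd.DataFrame((rng.random((15, 12)) < 0.3).astype(int))
        out = rarefy_richness(inc, target_units=100, n_bootstrap=100)
        assert out["extrapolated_richness"] >= out["observed_richness"]

    def test_interpolation_below_observed_units(self):
        rng = np.random.default_rng(4)
        inc = pd.DataFrame((rng.random((30, 10)) < 0.5).astype(int))
        out = rarefy_richness(inc, target_units=10, n_bootstrap=50)
        obs = out["observed_richness"]
        assert out["extrapolated_richness"] <= obs + 1e-9

    def test_planted_pool_coverage(self):
        """20 species at detection 0.3 over 100 levels: the extrapolated CI
        should cover the true pool size in nearly every replicate."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            inc = pd.DataFrame((rng.random((100, 20)) < 0.3).astype(int))
            out = rarefy_richness(inc, target_units=200, n_bootstrap=100, seed=seed)
            lo, hi = out["ci"]
            hits += lo - 0.5 <= 20 <= hi + 0.5
        assert hits >= 18

    def test_empty_incidence_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            rarefy_richness(pd.DataFrame(columns=["a"]), 10)
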