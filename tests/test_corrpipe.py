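"""Kendall machinery against brute-force oracles, posterior-tau behaviour,
soil lookups, and the D95-driven size profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_tau_b
from veindemog import corrpipe as cp
from veindemog import demogfit as dg
from veindemog import synthgen as sg


class TestKendallTau:
    def test_perfect_concordance_and_discordance(self):
        assert cp.kendall_tau([1, 2, 3], [10, 20, 30])[0] == 1.0
        assert cp.kendall_tau([1, 2, 3], [3, 2, 1])[0] == -1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 15))
        x = rng.integers(0, 5, n).astype(float)  # heavy ties
        y = rng.integers(0, 5, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            x[0] += 1
            y[0] += 1
        tau, _ = cp.kendall_tau(x, y)
        assert tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    def test_vectorized_columns_match_scalar(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 6, 20).astype(float)
        Y = rng.integers(0, 6, (20, 7)).astype(float)
        many = cp.tau_b_many(x, Y)
        for k in range(7):
            expected = cp.kendall_tau(x, Y[:, k])[0]
            if np.isnan(expected):
                assert np.isnan(many[k])
            else:
                assert many[k] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_flagged_nan(self):
        assert np.isnan(cp.kendall_tau([1.0], [2.0])[0])
        assert np.isnan(cp.kendall_tau([1, 1, 1], [1, 2, 3])[0])

    def test_pairwise_deletion_of_missing(self):
        x = [1.0, 2.0, np.nan, 4.0]
        y = [1.0, np.nan, 3.0, 4.0]
        tau, _ = cp.kendall_tau(x, y)  # only rows 0 and 3 are complete
        assert tau == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-20, 20), min_size=4, max_size=20, unique=True), st.integers(0, 3))
    def test_invariant_under_monotone_transforms(self, xs, which):
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        y = rng.standard_normal(len(xs))
        x = np.asarray(xs, dtype=float)
        transforms = [np.exp, lambda v: v**3, lambda v: 5 * v - 2, lambda v: np.arctan(v)]
        t0 = cp.kendall_tau(x, y)[0]
        t1 = cp.kendall_tau(transforms[which](x), y)[0]
        assert t1 == pytest.approx(t0, abs=1e-12)


class TestPartialKendall:
    def test_uncorrelated_control_changes_nothing(self):
        # tau_xz = tau_yz = 0 by construction
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 3, 2, 4])
        z = np.array([1.0, 4, 4, 1])
        assert cp.partial_kendall(x, y, z) == pytest.approx(cp.kendall_tau(x, y)[0])

    def test_control_identical_to_y_degenerate(self):
        y = np.array([1.0, 2, 3, 4, 5])
        x = np.array([2.0, 1, 4, 3, 5])
        assert np.isnan(cp.partial_kendall(x, y, y))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_closed_form_composition(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.standard_normal((3, 10))
        t_xy = cp.kendall_tau(x, y)[0]
        t_xz = cp.kendall_tau(x, z)[0]
        t_yz = cp.kendall_tau(y, z)[0]
        expected = (t_xy - t_xz * t_yz) / math.sqrt((1 - t_xz**2) * (1 - t_yz**2))
        assert cp.partial_kendall(x, y, z) == pytest.approx(expected, abs=1e-12)


class TestTauPosterior:
    def test_point_mass_posterior_has_zero_width(self):
        rng = np.random.default_rng(0)
        rates = pd.DataFrame(np.tile(rng.standard_normal(10), (50, 1)), columns=[f"s{i}" for i in range(10)])
        trait = pd.Series(rng.standard_normal(10), index=rates.columns)
        td = cp.tau_posterior(trait, rates)
        assert td.q025 == td.q975 == td.median
        assert np.unique(td.tau_draws).size == 1

    def test_median_is_median_of_draws(self):
        rng = np.random.default_rng(1)
        rates = pd.DataFrame(rng.standard_normal((200, 12)), columns=[f"s{i}" for i in range(12)])
        trait = pd.Series(rng.standard_normal(12), index=rates.columns)
        td = cp.tau_posterior(trait, rates)
        assert td.median == pytest.approx(np.median(td.tau_draws))
        assert ((td.tau_draws >= -1) & (td.tau_draws <= 1)).all()

    def test_all_missing_trait_flagged_empty(self):
        rates = pd.DataFrame(np.random.default_rng(2).standard_normal((20, 5)), columns=list("abcde"))
        trait = pd.Series([np.nan] * 5, index=rates.columns)
        td = cp.tau_posterior(trait, rates)
        assert td.n_species == 0 and not td.significant and np.isnan(td.median)

    def test_monotone_trait_with_point_mass_rates_significant(self):
        rates = pd.DataFrame(np.tile(np.arange(15.0), (30, 1)), columns=[f"s{i}" for i in range(15)])
        trait = pd.Series(np.arange(15.0) ** 2, index=rates.columns)
        td = cp.tau_posterior(trait, rates)
        assert td.median == 1.0 and td.significant


class TestMatrices:
    @pytest.fixture()
    def traits(self):
        params = sg.gen_species_params(30, seed=9)
        return sg.gen_trait_table(params, seed=9)

    def test_trait_trait_symmetric_with_nan_diagonal(self, traits):
        cm = cp.trait_trait_matrix(traits)
        pd.testing.assert_frame_equal(cm.tau, cm.tau.T)
        assert cm.tau.to_numpy()[np.diag_indices(len(cm.tau))].tolist() == [pytest.approx(np.nan, nan_ok=True)] * len(cm.tau)

    def test_cells_equal_pairwise_kendall(self, traits):
        cm = cp.trait_trait_matrix(traits)
        for a, b in [("VLA", "DV"), ("WD", "Hmax"), ("Nmass", "SLA")]:
            tau, p = cp.kendall_tau(traits[a], traits[b])
            assert cm.tau.loc[a, b] == pytest.approx(tau, abs=1e-12)
            assert cm.p.loc[a, b] == pytest.approx(p, abs=1e-12)

    def test_cell_n_counts_complete_pairs(self, traits):
        cm = cp.trait_trait_matrix(traits)
        n = (traits["WD"].notna() & traits["Nmass"].notna()).sum()
        assert cm.n.loc["WD", "Nmass"] == n

    def test_constant_soil_column_flagged(self, traits):
        env = pd.DataFrame({"pH_water": 7.0}, index=traits.index)
        cm = cp.trait_soil_matrix(traits, env)
        assert cm.tau["pH_water"].isna().all()

    def test_soil_column_equal_to_trait_gives_unit_tau(self, traits):
        env = pd.DataFrame({"AV_N": traits["VLA"]})
        cm = cp.trait_soil_matrix(traits, env)
        assert cm.tau.loc["VLA", "AV_N"] == 1.0

    def test_stars_thresholds(self, traits):
        cm = cp.trait_trait_matrix(traits)
        stars = cm.stars()
        sig = cm.p < 0.05
        assert ((stars != "") == sig.fillna(False)).all().all()


class TestSpeciesEnvMeans:
    def test_constant_field_gives_constant_means(self, small_community):
        _, _, cen = small_community
        grid = sg.gen_soil_grid(25, 25, mean=3.0, sd=0.0, seed=0, variable="OC")
        env = cp.species_env_means(cen, grid)
        assert np.allclose(env["OC"], 3.0)

    def test_half_open_cell_convention(self):
        vals = np.arange(12.0).reshape(3, 4)  # values[iy, ix]
        grid = sg.SoilGrid("pH_water", vals, cell_size_m=20.0)
        cen = pd.DataFrame(
            {"tree_id": [0], "species": ["spA"], "x_m": [25.0], "y_m": [3.0], "d1_cm": [2.0],
             "t1_yr": [0.0], "t2_yr": [5.0], "status": [1]}
        )
        env = cp.species_env_means(cen, grid)
        assert env.loc["spA", "pH_water"] == vals[0, 1]  # cell (ix=1, iy=0)

    def test_outside_grid_names_tree(self):
        grid = sg.SoilGrid("OC", np.zeros((2, 2)), cell_size_m=20.0)
        cen = pd.DataFrame(
            {"tree_id": [77], "species": ["spA"], "x_m": [41.0], "y_m": [3.0]}
        )
        with pytest.raises(ValueError, match="77"):
            cp.species_env_means(cen, grid)

    def test_matches_bruteforce_lookup(self, small_community):
        _, _, cen = small_community
        grid = sg.gen_soil_grid(25, 25, mean=5.0, sd=1.0, seed=3, variable="AV_P")
        env = cp.species_env_means(cen, grid)
        sub = cen[cen.species == "sp003"]
        manual = np.mean(
            [grid.values[int(r.y_m // 20), int(r.x_m // 20)] for r in sub.itertuples()]
        )
        assert env.loc["sp003", "AV_P"] == pytest.approx(manual, rel=1e-12)


def degenerate_growth_draws(params, n_draws=5):
    """Point-mass 'posterior' equal to the true parameters."""
    sp = np.tile(params[["r1", "r2"]].to_numpy()[None, None], (1, n_draws, 1, 1))
    return dg.PosteriorDraws(
        model="growth", species=list(params.index), param_names=["r1", "r2"],
        species_draws=sp,
        hyper_mean_draws=np.tile(params[["r1", "r2"]].mean().to_numpy()[None, None], (1, n_draws, 1)),
        hyper_sd_draws=np.zeros((1, n_draws, 2)),
    )


def d95_table(values, species):
    return pd.DataFrame({"d95_cm": values, "n_trees": 10, "d_max_cm": np.asarray(values) * 1.1},
                        index=pd.Index(species, name="species"))


class TestSizeProfile:
    def make_traits(self, params, rng):
        # trait strictly increasing in r1; Hmax shuffled until provably
        # uncorrelated so no partial control is triggered
        n = len(params)
        while True:
            hmax = pd.Series(rng.permutation(n).astype(float), index=params.index, name="Hmax")
            _, p = cp.kendall_tau(hmax, np.exp(2 * params["r1"]))
            if p > 0.3:
                break
        return pd.DataFrame({"VLA": np.exp(2 * params["r1"]), "Hmax": hmax}, index=params.index)

    def test_constant_d95_fixed_species_count_and_length(self):
        params = sg.gen_species_params(25, seed=41)
        draws = degenerate_growth_draws(params)
        d95 = d95_table([30.0] * 25, params.index)
        traits = self.make_traits(params, np.random.default_rng(0))
        prof = cp.size_profile(traits, draws, None, d95, cp.ProfileConfig(min_species=20))
        vla = prof[prof.trait == "VLA"]
        assert vla.ref_d.max() == 29.0 and len(vla) == 29
        assert (vla.n_species == 25).all()

    def test_profile_ends_when_species_drop_below_minimum(self):
        params = sg.gen_species_params(25, seed=42)
        draws = degenerate_growth_draws(params)
        # 19 species have D95 > 6; 25 have D95 > 5
        d95_vals = [50.0] * 19 + [5.5] * 6
        d95 = d95_table(d95_vals, params.index)
        traits = self.make_traits(params, np.random.default_rng(1))
        prof = cp.size_profile(traits, draws, None, d95, cp.ProfileConfig(min_species=20))
        assert prof[prof.trait == "VLA"].ref_d.max() == 5.0

    def test_noise_free_link_gives_unit_tau_everywhere(self):
        # r2 identical across species so rate ranking equals r1 ranking at all D
        h = sg.CommunityHyperparams(r1_sd=0.03, r2_mean=-0.01, r2_sd=0.0)
        params = sg.gen_species_params(24, h, seed=43)
        draws = degenerate_growth_draws(params)
        d95 = d95_table(np.linspace(25, 60, 24), params.index)
        traits = self.make_traits(params, np.random.default_rng(2))
        prof = cp.size_profile(traits, draws, None, d95, cp.ProfileConfig(min_species=20))
        vla = prof[prof.trait == "VLA"]
        assert (vla.median_tau == 1.0).all()
        assert (vla.significant).all()
        assert (np.diff(vla.n_species) <= 0).all()

    def test_partial_control_engages_for_correlated_trait(self):
        params = sg.gen_species_params(22, seed=44)
        draws = degenerate_growth_draws(params)
        d95 = d95_table([40.0] * 22, params.index)
        # Hmax strongly monotone in r1 -> the r1-linked trait is correlated
        # with Hmax, so the pipeline must partial it out
        traits = pd.DataFrame(
            {"VLA": np.exp(2 * params["r1"]), "Hmax": 10 + 50 * params["r1"]},
            index=params.index,
        )
        prof = cp.size_profile(traits, draws, None, d95, cp.ProfileConfig(min_species=20))
        vla = prof[prof.trait == "VLA"]
        assert (vla.control == "Hmax").all()
        hm = prof[prof.trait == "Hmax"]
        assert hm.control.isna().all()  # never partialled against itself


class TestLargeStatured:
    def test_all_species_mask(self):
        params = sg.gen_species_params(10, seed=1)
        traits = sg.gen_trait_table(params, seed=1)
        mask, _ = cp.large_statured_subset(traits, k=len(traits), k_chem=3)
        assert mask.reindex(traits["Hmax"].dropna().index).all()

    def test_single_tallest(self):
        params = sg.gen_species_params(10, seed=2)
        traits = sg.gen_trait_table(params, seed=2)
        mask, _ = cp.large_statured_subset(traits, k=1)
        assert mask.sum() == 1
        assert traits.loc[mask, "Hmax"].iloc[0] == traits["Hmax"].max()

    def test_matches_sort_and_slice_oracle(self):
        params = sg.gen_species_params(30, seed=3)
        traits = sg.gen_trait_table(params, seed=3)
        mask, chem = cp.large_statured_subset(traits, k=20, k_chem=15)
        expected = set(traits["Hmax"].sort_values(ascending=False).index[:20])
        assert set(traits.index[mask]) == expected
        assert chem.sum() == 15 and (chem & ~mask).sum() == 0
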