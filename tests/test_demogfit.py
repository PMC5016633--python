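"""Recovery of known demographic parameters, closed-form rate surfaces, the
D95 size rule, and MCMC diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from veindemog import demogfit as dg
from veindemog import synthgen as sg

SHORT = dg.MCMCConfig(chains=2, iterations=2500, burnin=1200, thin=3, seed=7)


def hyper_zero_sd(**kw):
    zeros = {f"{p}_sd": 0.0 for p in ("r1", "r2", "m1", "m2", "m3")}
    zeros.update({"m2_mean": 0.0, "m3_mean": 0.0, "sigma_obs": 0.0})
    zeros.update(kw)
    return sg.CommunityHyperparams(**zeros)


def make_draws(r1, r2, model="growth"):
    """Point-mass posterior (1 chain x 1 draw) for closed-form checks."""
    r1 = np.atleast_1d(np.asarray(r1, dtype=float))
    r2 = np.atleast_1d(np.asarray(r2, dtype=float))
    j = r1.size
    sp = np.stack([r1, r2], axis=-1)[None, None]
    names = ["r1", "r2"] if model == "growth" else ["m1", "m2"]
    return dg.PosteriorDraws(
        model=model,
        species=[f"sp{i:03d}" for i in range(j)],
        param_names=["r1", "r2"],
        species_draws=sp,
        hyper_mean_draws=sp.mean(axis=2),
        hyper_sd_draws=np.zeros((1, 1, 2)),
    )


class TestFitGrowth:
    def test_single_species_parameter_recovery(self):
        h = hyper_zero_sd(r1_mean=0.08, r2_mean=-0.02, sigma_obs=0.001, m1_mean=math.log(1e-9))
        params = sg.gen_species_params(1, h, seed=21)
        cen = sg.gen_census(params, 2000, 5.0, hyper=h, seed=21)
        d = dg.fit_growth(cen, dg.GrowthModelSpec(mcmc=SHORT))
        for p, truth in (("r1", 0.08), ("r2", -0.02)):
            draws = d.param(p).iloc[:, 0]
            lo, hi = draws.quantile([0.025, 0.975])
            assert lo <= truth <= hi
            assert abs(draws.median() - truth) < 0.01

    def test_zero_slope_hypermean_covers_zero(self):
        h = sg.CommunityHyperparams(r1_mean=0.08, r1_sd=0.03, r2_mean=0.0, r2_sd=0.0, sigma_obs=0.02)
        params = sg.gen_species_params(10, h, seed=22)
        cen = sg.gen_census(params, 150, 5.0, hyper=h, seed=22)
        d = dg.fit_growth(cen, dg.GrowthModelSpec(mcmc=SHORT))
        mu_r2 = d.hyper_mean_draws[:, :, 1].ravel()
        lo, hi = np.quantile(mu_r2, [0.025, 0.975])
        assert lo <= 0.0 <= hi

    def test_posterior_concentrates_on_ols_when_noise_vanishes(self):
        h = hyper_zero_sd(r1_mean=0.1, r2_mean=-0.03, sigma_obs=1e-4, m1_mean=math.log(1e-9))
        params = sg.gen_species_params(1, h, seed=23)
        cen = sg.gen_census(params, 500, 5.0, hyper=h, seed=23)
        surv = cen[cen.status == 1]
        # OLS of RGR on ln D1
        y = (np.log(surv.d2_cm) - np.log(surv.d1_cm)) / 5.0
        X = np.column_stack([np.ones(len(surv)), np.log(surv.d1_cm)])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        d = dg.fit_growth(cen, dg.GrowthModelSpec(mcmc=SHORT))
        assert d.param("r1").iloc[:, 0].median() == pytest.approx(ols[0], abs=5e-4)
        assert d.param("r2").iloc[:, 0].median() == pytest.approx(ols[1], abs=5e-4)

    def test_nonpositive_interval_rejected_before_sampling(self, small_community):
        _, _, cen = small_community
        bad = cen.copy()
        bad.loc[bad.index[0], "t2_yr"] = bad.loc[bad.index[0], "t1_yr"]
        with pytest.raises(ValueError, match="interval"):
            dg.fit_growth(bad)

    def test_sparse_species_excluded_with_warning(self, small_community):
        _, _, cen = small_community
        lonely = cen.iloc[[0]].assign(species="spLONE", status=1)
        with pytest.warns(UserWarning, match="spLONE"):
            d = dg.fit_growth(pd.concat([cen, lonely]), dg.GrowthModelSpec(
                mcmc=dg.MCMCConfig(chains=2, iterations=200, burnin=100, thin=1, seed=0)))
        assert "spLONE" not in d.species

    def test_reproducible_under_seed(self, small_community):
        _, _, cen = small_community
        cfg = dg.GrowthModelSpec(mcmc=dg.MCMCConfig(chains=2, iterations=400, burnin=200, thin=2, seed=5))
        d1 = dg.fit_growth(cen, cfg)
        d2 = dg.fit_growth(cen, cfg)
        assert np.array_equal(d1.species_draws, d2.species_draws)


class TestFitMortality:
    def test_constant_hazard_recovery(self):
        h = hyper_zero_sd(m1_mean=math.log(0.05))
        params = sg.gen_species_params(1, h, seed=31)
        cen = sg.gen_census(params, 3000, 5.0, hyper=h, seed=31)
        d = dg.fit_mortality(cen, dg.MortalityModelSpec(mcmc=SHORT))
        m5 = dg.mortality_at_size(d, 5.0).iloc[:, 0]
        lo, hi = m5.quantile([0.025, 0.975])
        assert lo <= 0.05 <= hi
        assert abs(m5.median() - 0.05) / 0.05 < 0.25

    def test_no_deaths_bounded_by_rule_of_three(self):
        # all survive: the hazard posterior should sit below ~3/(n dt)
        n, dt = 2000, 5.0
        cen = pd.DataFrame(
            {
                "tree_id": np.arange(n),
                "species": "spA",
                "d1_cm": np.full(n, 5.0),
                "d2_cm": np.full(n, 5.5),
                "t1_yr": 0.0,
                "t2_yr": dt,
                "status": 1,
            }
        )
        d = dg.fit_mortality(cen, dg.MortalityModelSpec(mcmc=SHORT))
        m5 = dg.mortality_at_size(d, 5.0).iloc[:, 0]
        assert m5.median() < 3.0 / (n * dt)

    def test_survival_probabilities_in_unit_interval(self, small_community):
        _, _, cen = small_community
        d = dg.fit_mortality(cen, dg.MortalityModelSpec(
            mcmc=dg.MCMCConfig(chains=2, iterations=600, burnin=300, thin=3, seed=1)))
        for ref_d in (1.0, 5.0, 20.0):
            p = np.exp(-dg.mortality_at_size(d, ref_d).to_numpy() * 5.0)
            assert ((p > 0) & (p <= 1)).all()

    def test_bad_status_rejected(self, small_community):
        _, _, cen = small_community
        bad = cen.copy()
        bad.loc[bad.index[0], "status"] = 2
        with pytest.raises(ValueError, match="status"):
            dg.fit_mortality(bad)

    def test_zero_death_species_retained(self, small_community):
        _, _, cen = small_community
        immortal = cen[cen.species == "sp001"].copy()
        immortal["species"] = "spIMM"
        immortal["status"] = 1
        immortal["d2_cm"] = immortal["d2_cm"].fillna(immortal["d1_cm"])
        d = dg.fit_mortality(pd.concat([cen, immortal]), dg.MortalityModelSpec(
            mcmc=dg.MCMCConfig(chains=2, iterations=400, burnin=200, thin=2, seed=2)))
        assert "spIMM" in d.species


class TestRateSurfaces:
    def test_growth_at_unit_diameter_is_intercept(self):
        d = make_draws([0.1, 0.2], [-0.5, 0.3])
        out = dg.growth_at_size(d, 1.0)
        assert np.allclose(out.to_numpy(), [[0.1, 0.2]])

    def test_growth_flat_when_slope_zero(self):
        d = make_draws([0.1], [0.0])
        assert dg.growth_at_size(d, 3.0).iloc[0, 0] == dg.growth_at_size(d, 30.0).iloc[0, 0]

    def test_growth_closed_form(self):
        d = make_draws([0.1], [-0.02])
        assert dg.growth_at_size(d, math.e**2).iloc[0, 0] == pytest.approx(0.06)

    def test_mortality_closed_form_and_positivity(self, small_community):
        _, _, cen = small_community
        # hand-built draws: M = exp(m1 + m2 ln D + m3 D)
        sp = np.array([[[[math.log(0.02), 1.0, 0.0]]]])
        d = dg.PosteriorDraws(
            model="mortality", species=["spA"], param_names=["m1", "m2", "m3"],
            species_draws=sp, hyper_mean_draws=sp[:, :, 0], hyper_sd_draws=np.zeros((1, 1, 3)),
        )
        assert dg.mortality_at_size(d, math.e).iloc[0, 0] == pytest.approx(0.02 * math.e)
        assert (dg.mortality_at_size(d, 40.0).to_numpy() > 0).all()

    def test_nonpositive_reference_diameter_rejected(self):
        d = make_draws([0.1], [0.0])
        with pytest.raises(ValueError):
            dg.growth_at_size(d, 0.0)
        with pytest.raises(ValueError):
            dg.growth_at_size(d, -1.0)


class TestD95:
    def test_integer_1_to_100(self):
        cen = pd.DataFrame(
            {"species": "spA", "d1_cm": np.arange(1.0, 101.0), "t1_yr": 0.0, "t2_yr": 5.0, "status": 1}
        )
        out = dg.compute_d95(cen)
        # subpopulation rule: Dmax=100 -> keep D >= 10, i.e. {10..100}, 91 trees
        assert out.loc["spA", "n_trees"] == 91
        # type-7 quantile of {10..100} at 0.95: h = 85.5 -> 95.5
        assert out.loc["spA", "d95_cm"] == pytest.approx(95.5)

    def test_constant_diameters(self):
        cen = pd.DataFrame({"species": "spA", "d1_cm": [7.0] * 5, "t1_yr": 0.0, "t2_yr": 5.0, "status": 1})
        assert dg.compute_d95(cen).loc["spA", "d95_cm"] == 7.0

    def test_single_tree(self):
        cen = pd.DataFrame({"species": "spA", "d1_cm": [3.3], "t1_yr": 0.0, "t2_yr": 5.0, "status": 1})
        assert dg.compute_d95(cen).loc["spA", "d95_cm"] == pytest.approx(3.3)

    def test_d95_never_exceeds_maximum(self, small_community):
        _, _, cen = small_community
        out = dg.compute_d95(cen)
        assert (out["d95_cm"] <= out["d_max_cm"] + 1e-12).all()


class TestDiagnose:
    @staticmethod
    def _draws_from(chains_arr):
        c, d = chains_arr.shape
        sp = chains_arr[:, :, None, None] * np.ones((1, 1, 1, 2))
        return dg.PosteriorDraws(
            model="growth", species=["spA"], param_names=["r1", "r2"],
            species_draws=sp, hyper_mean_draws=sp[:, :, 0], hyper_sd_draws=np.abs(sp[:, :, 0]) + 1.0,
        )

    def test_iid_chains_converged(self):
        rng = np.random.default_rng(0)
        d = self._draws_from(rng.standard_normal((3, 400)))
        rep = dg.diagnose(d)
        assert (rep["rhat"] < 1.01).all()
        assert not rep["flagged"].any()

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((2, 400))
        arr[1] += 5.0
        rep = dg.diagnose(self._draws_from(arr))
        assert rep[rep.species == "spA"]["flagged"].all()

    def test_mismatched_chain_shapes_rejected(self):
        with pytest.raises(ValueError):
            dg.PosteriorDraws(
                model="growth", species=["spA"], param_names=["r1", "r2"],
                species_draws=np.zeros((2, 10, 1, 2)),
                hyper_mean_draws=np.zeros((2, 5, 2)),  # wrong draw count
                hyper_sd_draws=np.zeros((2, 10, 2)),
            )

    def test_single_chain_warns_and_reports_ess(self):
        rng = np.random.default_rng(2)
        d = self._draws_from(rng.standard_normal((1, 400)))
        with pytest.warns(UserWarning, match="single chain"):
            rep = dg.diagnose(d)
        assert rep["rhat"].isna().all()
        assert (rep["ess_bulk"] > 0).all()
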