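"""Hierarchical Bayesian models of size-dependent tree growth and mortality.

Two models, each with species-level parameters drawn from community-level
(hyper) normal distributions:

* **Growth** — relative growth rate of tree *i* of species *j* is linear in
  log diameter, ``R_i = r1_j + r2_j ln D1_i``, and the second-census log
  diameter is ``ln D2_i ~ Normal(ln D1_i + R_i (t2_i - t1_i), sigma_obs²)``.
  Only surviving trees contribute.
* **Mortality** — survival through the census interval is Bernoulli with
  ``p_i = exp(-M_i (t2_i - t1_i))`` and log-hazard
  ``ln M_i = m1_j + m2_j ln D1_i + m3_j D1_i`` (the D term lets the hazard
  turn upward again for large stems). All trees contribute.

Priors are weakly informative and overridable: hypermeans Normal(0, 10²),
hyper-SDs half-Cauchy(2.5), sigma_obs half-Cauchy(2.5).

Sampling is adaptive random-walk Metropolis-within-Gibbs: species-level
parameters, hyper-SDs and sigma_obs take scalar random-walk steps with
proposal scales tuned during burn-in toward a 0.44 acceptance rate;
hypermeans are conjugate normal draws. Species-level updates are vectorized
across species (the species blocks are conditionally independent), which is
what keeps short-chain replicate fits cheap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GrowthModelSpec",
    "MCMCConfig",
    "MortalityModelSpec",
    "PosteriorDraws",
    "compute_d95",
    "diagnose",
    "fit_growth",
    "fit_mortality",
    "growth_at_size",
    "mortality_at_size",
]

_ADAPT_BATCH = 50


@dataclass(frozen=True)
class MCMCConfig:
    """Chain configuration. ``draws per chain = (iterations - burnin) / thin``."""

    chains: int = 3
    iterations: int = 20_000
    burnin: int = 10_000
    thin: int = 10
    seed: int = 0
    target_accept: float = 0.44
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if not (self.iterations > self.burnin >= 0):
            raise ValueError("require iterations > burnin >= 0")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass(frozen=True)
class GrowthModelSpec:
    """Priors and MCMC settings for the growth model."""

    hypermean_prior_mean: float = 0.0
    hypermean_prior_sd: float = 10.0
    hypersd_scale: float = 2.5
    sigma_obs_scale: float = 2.5
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)


@dataclass(frozen=True)
class MortalityModelSpec:
    """Priors and MCMC settings for the mortality model."""

    hypermean_prior_mean: float = 0.0
    hypermean_prior_sd: float = 10.0
    hypersd_scale: float = 2.5
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)


@dataclass
class PosteriorDraws:
    """Posterior samples from one fitted model.

    ``species_draws`` has shape (chains, draws, n_species, n_params) with
    parameter order ``param_names``; ``hyper_mean_draws`` / ``hyper_sd_draws``
    are (chains, draws, n_params); ``sigma_obs_draws`` (growth only) is
    (chains, draws). Demographic rates at any reference diameter are
    deterministic functions of these draws (:func:`growth_at_size`,
    :func:`mortality_at_size`).
    """

    model: str
    species: list[str]
    param_names: list[str]
    species_draws: np.ndarray
    hyper_mean_draws: np.ndarray
    hyper_sd_draws: np.ndarray
    sigma_obs_draws: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        sd = np.asarray(self.species_draws, dtype=float)
        if sd.ndim != 4:
            raise ValueError("species_draws must be (chains, draws, species, params)")
        c, d, j, k = sd.shape
        if j != len(self.species) or k != len(self.param_names):
            raise ValueError("species_draws shape inconsistent with labels")
        for name in ("hyper_mean_draws", "hyper_sd_draws"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (c, d, k):
                raise ValueError(f"{name} must have shape {(c, d, k)}, got {arr.shape}")
            setattr(self, name, arr)
        if self.sigma_obs_draws is not None:
            so = np.asarray(self.sigma_obs_draws, dtype=float)
            if so.shape != (c, d):
                raise ValueError(f"sigma_obs_draws must have shape {(c, d)}")
            self.sigma_obs_draws = so
        if not np.isfinite(sd).all():
            raise ValueError("non-finite posterior draws")
        self.species_draws = sd

    @property
    def n_chains(self) -> int:
        return self.species_draws.shape[0]

    @property
    def n_draws(self) -> int:
        """Total draws pooled over chains."""
        return self.species_draws.shape[0] * self.species_draws.shape[1]

    def stacked(self) -> np.ndarray:
        """Species draws pooled over chains: (total draws, n_species, n_params)."""
        c, d, j, k = self.species_draws.shape
        return self.species_draws.reshape(c * d, j, k)

    def param(self, name: str) -> pd.DataFrame:
        """Pooled draws of one species-level parameter: draws × species."""
        k = self.param_names.index(name)
        return pd.DataFrame(self.stacked()[:, :, k], columns=self.species)

    def to_tidy(self) -> pd.DataFrame:
        """Tidy long format: chain, iteration, species, parameter, value.

        Hyperparameters appear with species ``_community`` (``<p>_mean``,
        ``<p>_sd``) and sigma_obs as parameter ``sigma_obs``.
        """
        c, d, j, k = self.species_draws.shape
        chains = np.repeat(np.arange(c), d)
        iters = np.tile(np.arange(d), c)
        frames = []
        for kk, pname in enumerate(self.param_names):
            for jj, sp in enumerate(self.species):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": chains,
                            "iteration": iters,
                            "species": sp,
                            "parameter": pname,
                            "value": self.species_draws[:, :, jj, kk].ravel(),
                        }
                    )
                )
            for arr, suffix in ((self.hyper_mean_draws, "_mean"), (self.hyper_sd_draws, "_sd")):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": chains,
                            "iteration": iters,
                            "species": "_community",
                            "parameter": pname + suffix,
                            "value": arr[:, :, kk].ravel(),
                        }
                    )
                )
        if self.sigma_obs_draws is not None:
            frames.append(
                pd.DataFrame(
                    {
                        "chain": chains,
                        "iteration": iters,
                        "species": "_community",
                        "parameter": "sigma_obs",
                        "value": self.sigma_obs_draws.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# data preparation

_REQUIRED = ["species", "d1_cm", "t1_yr", "t2_yr", "status"]


def _validate_census(census: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in census.columns]
    if missing:
        raise ValueError(f"census table missing columns: {missing}")
    dt = census["t2_yr"].to_numpy(float) - census["t1_yr"].to_numpy(float)
    if (dt <= 0).any():
        raise ValueError("census interval t2 - t1 must be > 0 for every tree")
    status = census["status"].to_numpy()
    if not np.isin(status, [0, 1]).all():
        raise ValueError("status must be 0 (died) or 1 (survived)")
    if (census["d1_cm"].to_numpy(float) <= 0).any():
        raise ValueError("d1_cm must be positive")
    return census


def _halfcauchy_logpdf(x: float, scale: float) -> float:
    return -math.log1p((x / scale) ** 2)  # constant dropped


# ---------------------------------------------------------------------------
# shared sampler machinery


class _AdaptiveScales:
    """Per-parameter RW proposal scales with batched burn-in adaptation."""

    def __init__(self, shape, init):
        self.log_scale = np.full(shape, math.log(init))
        self.accepts = np.zeros(shape)
        self.n_batches = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def record(self, accepted):
        self.accepts += accepted

    def adapt(self, target):
        self.n_batches += 1
        rate = self.accepts / _ADAPT_BATCH
        delta = min(0.25, 1.0 / math.sqrt(self.n_batches))
        self.log_scale += np.where(rate > target, delta, -delta)
        self.accepts = np.zeros_like(self.accepts)


def _run_hier_chain(model, cfg: MCMCConfig, rng: np.random.Generator):
    """Generic hierarchical sweep over one chain.

    ``model`` supplies: K (params/species), J (species), init(), species
    log-likelihood as a function of a candidate column, and optional
    auxiliary scale parameter (sigma_obs) machinery. Returns stored arrays.
    """
    K, J = model.K, model.J
    beta, aux = model.init(rng)
    mu = beta.mean(axis=0)
    tau = np.maximum(beta.std(axis=0, ddof=0), 1e-3)

    sc_beta = _AdaptiveScales((J, K), cfg.init_scale)
    sc_shift = _AdaptiveScales((K,), cfg.init_scale)
    sc_scale = _AdaptiveScales((K,), 0.3)
    sc_tau = _AdaptiveScales((K,), 0.5)
    sc_aux = _AdaptiveScales((), 0.5) if model.has_aux else None

    n_keep = (cfg.iterations - cfg.burnin) // cfg.thin
    out_beta = np.empty((n_keep, J, K))
    out_mu = np.empty((n_keep, K))
    out_tau = np.empty((n_keep, K))
    out_aux = np.empty(n_keep) if model.has_aux else None

    hp_mean, hp_sd = model.hypermean_prior_mean, model.hypermean_prior_sd
    kept = 0
    for it in range(cfg.iterations):
        # --- species-level parameters: centered moves, all species at once
        sc_beta.accepts += model.species_sweep(mu, tau, sc_beta.scale, aux, rng)
        # --- joint translation of a whole species column with its hypermean
        # (breaks the slow random walk of strongly shrunk columns)
        sc_shift.accepts += model.shift_sweep(mu, sc_shift.scale, aux, rng)
        # --- joint rescaling of a column's deviations with its hyper-SD
        # (breaks the funnel between a weakly identified column and its SD)
        sc_scale.accepts += model.scale_sweep(mu, tau, sc_scale.scale, aux, rng)
        beta = model.beta

        # --- hypermeans: conjugate normal draw
        for k in range(K):
            prec = J / tau[k] ** 2 + 1.0 / hp_sd**2
            mean = (beta[:, k].sum() / tau[k] ** 2 + hp_mean / hp_sd**2) / prec
            mu[k] = mean + rng.standard_normal() / math.sqrt(prec)

        # --- hyper-SDs: RW on log scale, half-Cauchy prior
        for k in range(K):
            lt = math.log(tau[k])
            lt_p = lt + sc_tau.scale[k] * rng.standard_normal()
            ss = float(((beta[:, k] - mu[k]) ** 2).sum())
            def _lp(l):
                t = math.exp(l)
                return -J * l - ss / (2.0 * t * t) + _halfcauchy_logpdf(t, model.hypersd_scale) + l
            if math.log(rng.random()) < _lp(lt_p) - _lp(lt):
                tau[k] = math.exp(lt_p)
                sc_tau.accepts[k] += 1

        # --- auxiliary observation scale (growth only)
        if model.has_aux:
            aux_new, accepted = model.update_aux(aux, sc_aux.scale, rng)
            aux = aux_new
            sc_aux.accepts += accepted

        if it < cfg.burnin:
            if (it + 1) % _ADAPT_BATCH == 0:
                sc_beta.adapt(cfg.target_accept)
                sc_shift.adapt(cfg.target_accept)
                sc_scale.adapt(cfg.target_accept)
                sc_tau.adapt(cfg.target_accept)
                if sc_aux is not None:
                    sc_aux.adapt(cfg.target_accept)
        elif (it - cfg.burnin) % cfg.thin == cfg.thin - 1 and kept < n_keep:
            out_beta[kept] = beta
            out_mu[kept] = mu
            out_tau[kept] = tau
            if out_aux is not None:
                out_aux[kept] = aux
            kept += 1

    return out_beta[:kept], out_mu[:kept], out_tau[:kept], (out_aux[:kept] if out_aux is not None else None)


class _GrowthModel:
    """Growth likelihood via per-species sufficient statistics.

    With y = ln D2 - ln D1, x = ln D1, w = Δt and residual
    e = y - (r1 + r2 x) w, the species sum of squares is a quadratic form in
    (r1, r2) with six precomputed coefficients, so every Metropolis step is
    O(1) per species regardless of tree count.
    """

    K = 2
    has_aux = True

    def __init__(self, census: pd.DataFrame, spec: GrowthModelSpec):
        self.hypermean_prior_mean = spec.hypermean_prior_mean
        self.hypermean_prior_sd = spec.hypermean_prior_sd
        self.hypersd_scale = spec.hypersd_scale
        self.sigma_scale = spec.sigma_obs_scale

        surv = census[(census["status"] == 1) & census["d2_cm"].notna()].copy()
        counts = surv.groupby("species").size()
        ok = counts[counts >= 2].index
        dropped = sorted(set(census["species"].unique()) - set(ok))
        if dropped:
            warnings.warn(f"species excluded from growth fit (<2 survivors): {dropped}", stacklevel=3)
        if len(ok) == 0:
            raise ValueError("no species with >= 2 survivors")
        surv = surv[surv["species"].isin(ok)]
        self.species = sorted(ok)
        self.J = len(self.species)

        y = np.log(surv["d2_cm"].to_numpy(float)) - np.log(surv["d1_cm"].to_numpy(float))
        x = np.log(surv["d1_cm"].to_numpy(float))
        w = surv["t2_yr"].to_numpy(float) - surv["t1_yr"].to_numpy(float)
        sp_idx = pd.Categorical(surv["species"], categories=self.species).codes
        J = self.J

        def seg(v):
            return np.bincount(sp_idx, weights=v, minlength=J)

        self.n_j = np.bincount(sp_idx, minlength=J).astype(float)
        self.Syy = seg(y * y)
        self.Syw = seg(y * w)
        self.Syxw = seg(y * x * w)
        self.Sww = seg(w * w)
        self.Sxww = seg(x * w * w)
        self.Sxxww = seg(x * x * w * w)
        self.N = float(len(surv))
        self._beta = None  # current state, kept for delta evaluation
        self._sse = None

    def _sse_of(self, b1, b2):
        return (
            self.Syy
            - 2.0 * b1 * self.Syw
            - 2.0 * b2 * self.Syxw
            + b1 * b1 * self.Sww
            + 2.0 * b1 * b2 * self.Sxww
            + b2 * b2 * self.Sxxww
        )

    def init(self, rng):
        # per-species least squares (regularized for near-singular designs),
        # then chain-specific jitter so chains start overdispersed
        b = np.empty((self.J, 2))
        for j in range(self.J):
            A = np.array([[self.Sww[j], self.Sxww[j]], [self.Sxww[j], self.Sxxww[j]]])
            rhs = np.array([self.Syw[j], self.Syxw[j]])
            A[np.diag_indices(2)] += 1e-8 * (1.0 + A.diagonal())
            b[j] = np.linalg.solve(A, rhs)
        jit = np.maximum(b.std(axis=0, ddof=0), 1e-3)
        b += rng.normal(0.0, 0.5 * jit, size=b.shape)
        self._beta = b.copy()
        self._sse = self._sse_of(b[:, 0], b[:, 1])
        sse_tot = max(float(self._sse.sum()), 1e-12)
        sigma = math.sqrt(sse_tot / max(self.N, 1.0)) * math.exp(0.2 * rng.standard_normal())
        # likelihood-weighted mean of ln D per species: updating r2 along
        # r1 -> r1 - delta*xbar leaves RGR at the species' center unchanged,
        # decorrelating intercept and slope moves
        self.xbar = np.where(self.Sww > 0, self.Sxww / np.maximum(self.Sww, 1e-300), 0.0)
        return b, max(sigma, 1e-4)

    @property
    def beta(self):
        return self._beta

    def species_sweep(self, mu, tau, scales, sigma, rng):
        J = self.J
        acc_out = np.zeros((J, self.K))
        inv2sig2 = 1.0 / (2.0 * sigma * sigma)
        for k in range(self.K):
            delta = scales[:, k] * rng.standard_normal(J)
            b1, b2 = self._beta[:, 0], self._beta[:, 1]
            if k == 0:
                b1p, b2p = b1 + delta, b2
            else:
                b2p = b2 + delta
                b1p = b1 - delta * self.xbar
            sse_p = self._sse_of(b1p, b2p)
            d_ll = (self._sse - sse_p) * inv2sig2
            d_lp = ((b1 - mu[0]) ** 2 - (b1p - mu[0]) ** 2) / (2.0 * tau[0] ** 2) + (
                (b2 - mu[1]) ** 2 - (b2p - mu[1]) ** 2
            ) / (2.0 * tau[1] ** 2)
            acc = np.log(rng.random(J)) < d_ll + d_lp
            self._beta[acc, 0] = b1p[acc]
            self._beta[acc, 1] = b2p[acc]
            self._sse[acc] = sse_p[acc]
            acc_out[:, k] = acc
        return acc_out

    def shift_sweep(self, mu, scales, sigma, rng):
        acc_out = np.zeros(self.K)
        inv2sig2 = 1.0 / (2.0 * sigma * sigma)
        for k in range(self.K):
            d = float(scales[k]) * rng.standard_normal()
            b1 = self._beta[:, 0] + (d if k == 0 else 0.0)
            b2 = self._beta[:, 1] + (d if k == 1 else 0.0)
            sse_p = self._sse_of(b1, b2)
            d_ll = float((self._sse - sse_p).sum()) * inv2sig2
            mu_p = mu[k] + d
            d_lp = ((mu[k] - self.hypermean_prior_mean) ** 2 - (mu_p - self.hypermean_prior_mean) ** 2) / (
                2.0 * self.hypermean_prior_sd**2
            )
            if math.log(rng.random()) < d_ll + d_lp:
                self._beta[:, k] += d
                self._sse = sse_p
                mu[k] = mu_p
                acc_out[k] = 1.0
        return acc_out

    def scale_sweep(self, mu, tau, scales, sigma, rng):
        # beta_col -> mu + c (beta_col - mu), tau -> c tau; the species-prior
        # change and the Jacobian collapse to +ln c in the log accept ratio
        acc_out = np.zeros(self.K)
        inv2sig2 = 1.0 / (2.0 * sigma * sigma)
        for k in range(self.K):
            lc = float(scales[k]) * rng.standard_normal()
            c = math.exp(lc)
            cols = [self._beta[:, 0], self._beta[:, 1]]
            cols[k] = mu[k] + c * (cols[k] - mu[k])
            sse_p = self._sse_of(cols[0], cols[1])
            d_ll = float((self._sse - sse_p).sum()) * inv2sig2
            d_hc = _halfcauchy_logpdf(c * tau[k], self.hypersd_scale) - _halfcauchy_logpdf(tau[k], self.hypersd_scale)
            if math.log(rng.random()) < d_ll + d_hc + lc:
                self._beta[:, k] = cols[k]
                self._sse = sse_p
                tau[k] *= c
                acc_out[k] = 1.0
        return acc_out

    def update_aux(self, sigma, scale, rng):
        ls = math.log(sigma)
        ls_p = ls + float(scale) * rng.standard_normal()
        sse_tot = float(self._sse.sum())

        def _lp(l):
            s = math.exp(l)
            return -self.N * l - sse_tot / (2.0 * s * s) + _halfcauchy_logpdf(s, self.sigma_scale) + l

        if math.log(rng.random()) < _lp(ls_p) - _lp(ls):
            return math.exp(ls_p), 1.0
        return sigma, 0.0


class _MortalityModel:
    """Bernoulli-survival likelihood with log-hazard linear in (1, ln D, D).

    Trees are kept in flat arrays with a species index; a cached per-tree
    linear predictor makes each column update one vectorized pass over all
    trees plus a per-species segment sum.
    """

    K = 3
    has_aux = False

    def __init__(self, census: pd.DataFrame, spec: MortalityModelSpec):
        self.hypermean_prior_mean = spec.hypermean_prior_mean
        self.hypermean_prior_sd = spec.hypermean_prior_sd
        self.hypersd_scale = spec.hypersd_scale

        self.species = sorted(census["species"].unique())
        self.J = len(self.species)
        d1 = census["d1_cm"].to_numpy(float)
        self.feats = [np.ones_like(d1), np.log(d1), d1]
        self.w = census["t2_yr"].to_numpy(float) - census["t1_yr"].to_numpy(float)
        self.surv = census["status"].to_numpy(int) == 1
        self.sp_idx = pd.Categorical(census["species"], categories=self.species).codes.astype(np.intp)
        self._eta = None
        self._ll = None  # per-species log-likelihood

    def _tree_ll(self, eta):
        with np.errstate(over="ignore", under="ignore", divide="ignore"):
            lp = -np.exp(eta) * self.w  # log survival probability, <= 0
            ll = np.where(self.surv, lp, np.log(-np.expm1(np.minimum(lp, -1e-300))))
        return ll

    def _seg(self, v):
        return np.bincount(self.sp_idx, weights=v, minlength=self.J)

    def init(self, rng):
        df = pd.DataFrame({"sp": self.sp_idx, "s": self.surv, "w": self.w})
        g = df.groupby("sp")
        frac = g["s"].mean().to_numpy()
        wbar = g["w"].mean().to_numpy()
        n = g.size().to_numpy()
        frac = np.clip(frac, 1.0 / (2.0 * n), 1.0 - 1.0 / (2.0 * n))
        m1 = np.log(-np.log(frac) / wbar)
        beta = np.column_stack([m1, np.zeros(self.J), np.zeros(self.J)])
        # chain-specific overdispersed start
        beta[:, 0] += rng.normal(0.0, 0.3, self.J)
        beta[:, 1] += rng.normal(0.0, 0.05, self.J)
        beta[:, 2] += rng.normal(0.0, 0.02, self.J)
        self._beta = beta.copy()
        self._eta = beta[self.sp_idx, 0] + beta[self.sp_idx, 1] * self.feats[1] + beta[self.sp_idx, 2] * self.feats[2]
        self._ll = self._seg(self._tree_ll(self._eta))
        # Gram-Schmidt basis per species over the per-tree features
        # (1, ln D, D): ln D and D are strongly collinear over a stand's size
        # range, so raw coordinate moves crawl along a likelihood ridge.
        # Scalar moves in the orthogonalized basis, mapped back to (m1,m2,m3),
        # decorrelate the walk without changing the model parameterization.
        n_j = np.bincount(self.sp_idx, minlength=self.J).astype(float)
        x, D = self.feats[1], self.feats[2]
        self.xbar = self._seg(x) / n_j
        self.dbar = self._seg(D) / n_j
        xc = x - self.xbar[self.sp_idx]
        var_x = self._seg(xc * xc) / n_j
        cov_xd = self._seg(xc * (D - self.dbar[self.sp_idx])) / n_j
        self.gamma = np.where(var_x > 0, cov_xd / np.maximum(var_x, 1e-300), 0.0)
        self.fc1 = xc  # centered ln D
        self.fc2 = D - self.dbar[self.sp_idx] - self.gamma[self.sp_idx] * xc  # D residual on ln D
        return beta, None

    @property
    def beta(self):
        return self._beta

    def species_sweep(self, mu, tau, scales, aux, rng):
        J = self.J
        acc_out = np.zeros((J, self.K))
        for k in range(self.K):
            delta = scales[:, k] * rng.standard_normal(J)
            bp = self._beta.copy()
            if k == 0:
                deta = delta[self.sp_idx]
                bp[:, 0] += delta
            elif k == 1:
                deta = delta[self.sp_idx] * self.fc1
                bp[:, 1] += delta
                bp[:, 0] -= delta * self.xbar
            else:
                deta = delta[self.sp_idx] * self.fc2
                bp[:, 2] += delta
                bp[:, 1] -= delta * self.gamma
                bp[:, 0] -= delta * (self.dbar - self.gamma * self.xbar)
            ll_p = self._seg(self._tree_ll(self._eta + deta))
            d_lp = np.zeros(J)
            for c in range(self.K):
                d_lp += ((self._beta[:, c] - mu[c]) ** 2 - (bp[:, c] - mu[c]) ** 2) / (2.0 * tau[c] ** 2)
            acc = np.log(rng.random(J)) < (ll_p - self._ll) + d_lp
            take = acc[self.sp_idx]
            self._eta[take] += deta[take]
            self._beta[acc] = bp[acc]
            self._ll[acc] = ll_p[acc]
            acc_out[:, k] = acc
        return acc_out

    def shift_sweep(self, mu, scales, aux, rng):
        acc_out = np.zeros(self.K)
        ll_cur = float(self._ll.sum())
        for k in range(self.K):
            d = float(scales[k]) * rng.standard_normal()
            deta = d * self.feats[k]
            ll_p = self._seg(self._tree_ll(self._eta + deta))
            mu_p = mu[k] + d
            d_lp = ((mu[k] - self.hypermean_prior_mean) ** 2 - (mu_p - self.hypermean_prior_mean) ** 2) / (
                2.0 * self.hypermean_prior_sd**2
            )
            if math.log(rng.random()) < (float(ll_p.sum()) - ll_cur) + d_lp:
                self._eta += deta
                self._beta[:, k] += d
                self._ll = ll_p
                ll_cur = float(ll_p.sum())
                mu[k] = mu_p
                acc_out[k] = 1.0
        return acc_out

    def scale_sweep(self, mu, tau, scales, aux, rng):
        # same deviation-rescaling move as the growth model (see there)
        acc_out = np.zeros(self.K)
        for k in range(self.K):
            lc = float(scales[k]) * rng.standard_normal()
            c = math.exp(lc)
            dev = self._beta[:, k] - mu[k]
            deta = ((c - 1.0) * dev)[self.sp_idx] * self.feats[k]
            ll_p = self._seg(self._tree_ll(self._eta + deta))
            d_ll = float(ll_p.sum() - self._ll.sum())
            d_hc = _halfcauchy_logpdf(c * tau[k], self.hypersd_scale) - _halfcauchy_logpdf(tau[k], self.hypersd_scale)
            if math.log(rng.random()) < d_ll + d_hc + lc:
                self._eta += deta
                self._beta[:, k] = mu[k] + c * dev
                self._ll = ll_p
                tau[k] *= c
                acc_out[k] = 1.0
        return acc_out


def _collect_chains(model, cfg, model_name, param_names, seed_offset=0):
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(seed_offset,))
    child = ss.spawn(cfg.chains)
    betas, mus, taus, auxs = [], [], [], []
    for c in range(cfg.chains):
        rng = np.random.default_rng(child[c])
        b, m, t, a = _run_hier_chain(model, cfg, rng)
        betas.append(b)
        mus.append(m)
        taus.append(t)
        auxs.append(a)
    return PosteriorDraws(
        model=model_name,
        species=list(model.species),
        param_names=param_names,
        species_draws=np.stack(betas),
        hyper_mean_draws=np.stack(mus),
        hyper_sd_draws=np.stack(taus),
        sigma_obs_draws=np.stack(auxs) if model.has_aux else None,
        seed=cfg.seed,
    )


def fit_growth(census: pd.DataFrame, spec: GrowthModelSpec | None = None) -> PosteriorDraws:
    """Fit the hierarchical growth model to a census table.

    Only surviving trees enter the likelihood; species with fewer than two
    survivors are excluded with a warning.
    """
    spec = spec or GrowthModelSpec()
    census = _validate_census(census)
    if "d2_cm" not in census.columns:
        raise ValueError("census table missing d2_cm")
    model = _GrowthModel(census, spec)
    return _collect_chains(model, spec.mcmc, "growth", ["r1", "r2"], seed_offset=0)


def fit_mortality(census: pd.DataFrame, spec: MortalityModelSpec | None = None) -> PosteriorDraws:
    """Fit the hierarchical mortality model to a census table.

    Every tree (dead or alive) contributes; species with zero deaths are
    retained — the hierarchy shrinks their hazard toward the community mean.
    """
    spec = spec or MortalityModelSpec()
    census = _validate_census(census)
    model = _MortalityModel(census, spec)
    return _collect_chains(model, spec.mcmc, "mortality", ["m1", "m2", "m3"], seed_offset=1)


# ---------------------------------------------------------------------------
# posterior rate surfaces


def growth_at_size(draws: PosteriorDraws, ref_d: float) -> pd.DataFrame:
    """Draw-wise RGR at a reference diameter: R = r1 + r2 ln(ref_d).

    Returns draws × species (pooled over chains).
    """
    if ref_d <= 0:
        raise ValueError("reference diameter must be > 0")
    if draws.model != "growth":
        raise ValueError(f"expected growth draws, got {draws.model!r}")
    s = draws.stacked()
    r = s[:, :, 0] + s[:, :, 1] * math.log(ref_d)
    return pd.DataFrame(r, columns=draws.species)


def mortality_at_size(draws: PosteriorDraws, ref_d: float) -> pd.DataFrame:
    """Draw-wise hazard at a reference diameter:
    M = exp(m1 + m2 ln(ref_d) + m3 ref_d), strictly positive."""
    if ref_d <= 0:
        raise ValueError("reference diameter must be > 0")
    if draws.model != "mortality":
        raise ValueError(f"expected mortality draws, got {draws.model!r}")
    s = draws.stacked()
    m = np.exp(s[:, :, 0] + s[:, :, 1] * math.log(ref_d) + s[:, :, 2] * ref_d)
    return pd.DataFrame(m, columns=draws.species)


# ---------------------------------------------------------------------------
# D95 and diagnostics


def compute_d95(census: pd.DataFrame) -> pd.DataFrame:
    """Per-species 95th-percentile diameter of the large-stem subpopulation.

    For each species: Dmax = max first-census diameter; the subpopulation is
    every tree with D1 >= 0.1 Dmax (a guard against abundance-driven maxima);
    D95 is the 95th percentile of the subpopulation's D1 under linear
    interpolation between order statistics (R type-7, the numpy default).
    """
    _validate_census(census)
    rows = []
    for sp, grp in census.groupby("species"):
        d1 = grp["d1_cm"].to_numpy(float)
        dmax = float(d1.max())
        sub = d1[d1 >= 0.1 * dmax]
        rows.append(
            {
                "species": sp,
                "d95_cm": float(np.quantile(sub, 0.95)),
                "n_trees": int(sub.size),
                "d_max_cm": dmax,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def diagnose(draws: PosteriorDraws, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split R-hat and effective sample size for every parameter.

    Returns a frame (parameter, species, rhat, ess_bulk, flagged) with
    hyperparameters under species ``_community``. With a single chain R-hat
    is not defined; only ESS is reported, with a warning.
    """
    import arviz as az

    data = {}
    for kk, pname in enumerate(draws.param_names):
        data[pname] = draws.species_draws[:, :, :, kk]
        data[pname + "_mean"] = draws.hyper_mean_draws[:, :, kk]
        data[pname + "_sd"] = draws.hyper_sd_draws[:, :, kk]
    if draws.sigma_obs_draws is not None:
        data["sigma_obs"] = draws.sigma_obs_draws

    single = draws.n_chains < 2
    if single:
        warnings.warn("single chain: R-hat unavailable, reporting ESS only", stacklevel=2)
    ds = az.convert_to_dataset(data)
    ess = az.ess(ds)
    rhat = None if single else az.rhat(ds)

    rows = []
    for kk, pname in enumerate(draws.param_names):
        for jj, sp in enumerate(draws.species):
            rows.append((pname, sp, None if single else float(rhat[pname][jj]), float(ess[pname][jj])))
        for suffix in ("_mean", "_sd"):
            nm = pname + suffix
            rows.append((nm, "_community", None if single else float(rhat[nm]), float(ess[nm])))
    if draws.sigma_obs_draws is not None:
        rows.append(("sigma_obs", "_community", None if single else float(rhat["sigma_obs"]), float(ess["sigma_obs"])))
    out = pd.DataFrame(rows, columns=["parameter", "species", "rhat", "ess_bulk"])
    out["flagged"] = out["rhat"].notna() & (out["rhat"] > rhat_threshold)
    return out
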