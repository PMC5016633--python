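"""Rank-correlation machinery linking traits to demographic rates and soils.

The centerpiece is uncertainty propagation: species demographic rates at a
reference diameter come as posterior draws, and Kendall's tau between a trait
and the rate vector is computed *per draw*, giving a whole posterior
distribution of tau. A trait–rate correlation is called significant when the
equal-tailed 95% interval of that distribution excludes zero.

Profiles along stem diameter repeat this at reference diameters 1, 2, 3, …
cm. Species enter the comparison at a given reference diameter only if their
D95 (95th-percentile diameter of the large-stem subpopulation) exceeds it,
so short-statured species drop out as the reference grows; a profile stops
once fewer than ``min_species`` (default 20) remain.

Where a trait is itself correlated with maximum height (for growth) or wood
density (for mortality), the Kendall *partial* rank correlation removes that
covariate's effect; the trigger is recomputed from the trait–trait matrix
(P < 0.05) rather than hard-coded.

Tau is the tie-corrected tau-b throughout, matching ``cor.test``-style
implementations; missing trait values are handled by pairwise-complete
deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from . import demogfit
from .synthgen import SoilGrid

__all__ = [
    "CorrelationMatrix",
    "ProfileConfig",
    "TauDistribution",
    "kendall_tau",
    "large_statured_subset",
    "partial_kendall",
    "size_profile",
    "species_env_means",
    "tau_posterior",
    "trait_soil_matrix",
    "trait_trait_matrix",
]


# ---------------------------------------------------------------------------
# Kendall machinery


def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with a two-sided P-value.

    Missing values are removed pairwise. P uses exact enumeration for
    n <= 9 without ties, otherwise the standard normal approximation.
    Returns (nan, nan) when fewer than two complete pairs remain or either
    vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    method = "exact" if (n <= 9 and _no_ties(x) and _no_ties(y)) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return (float(res.statistic), float(res.pvalue))


def _no_ties(v: np.ndarray) -> bool:
    return np.unique(v).size == v.size


def tau_b_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Tau-b of ``x`` against each column of ``Y`` (n × m), vectorized.

    Rows with non-finite ``x`` must be removed by the caller; ``Y`` is
    assumed finite. Columns where either vector is constant give nan.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = x.size
    iu, ju = np.triu_indices(n, k=1)
    sx = np.sign(x[iu] - x[ju])  # (npairs,)
    SY = np.sign(Y[iu, :] - Y[ju, :])  # (npairs, m)
    s = sx @ SY
    n0 = iu.size
    tx = float(np.count_nonzero(sx == 0))
    ty = (SY == 0).sum(axis=0).astype(float)
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, s / denom, np.nan)


def partial_kendall(x, y, control) -> float:
    """Kendall partial rank correlation tau(x, y | control).

    Computed from the three pairwise tau-b values as
    (τ_xy − τ_xz τ_yz) / sqrt((1 − τ_xz²)(1 − τ_yz²)); undefined (nan) when
    either control correlation is ±1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    t_xy, _ = kendall_tau(x, y)
    t_xz, _ = kendall_tau(x, z)
    t_yz, _ = kendall_tau(y, z)
    return _partial_from_taus(t_xy, t_xz, t_yz)


def _partial_from_taus(t_xy, t_xz, t_yz, eps: float = 1e-10):
    # |tau| = 1 with either control leaves nothing to correlate: undefined
    denom2 = (1.0 - np.asarray(t_xz) ** 2) * (1.0 - np.asarray(t_yz) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (t_xy - t_xz * t_yz) / np.sqrt(denom2)
    return np.where(np.asarray(denom2) > eps, out, np.nan) if np.ndim(out) else (
        float(out) if denom2 > eps else float("nan")
    )


# ---------------------------------------------------------------------------
# posterior tau


@dataclass(frozen=True)
class TauDistribution:
    """Posterior distribution of Kendall tau for one trait × rate × diameter."""

    trait: str
    rate: str
    ref_d: float
    tau_draws: np.ndarray
    median: float
    q025: float
    q975: float
    significant: bool
    n_species: int
    control: str | None = None


def tau_posterior(
    trait: pd.Series,
    rate_draws: pd.DataFrame,
    include: pd.Series | None = None,
    control: pd.Series | None = None,
    trait_name: str = "trait",
    rate_name: str = "rate",
    ref_d: float = float("nan"),
) -> TauDistribution:
    """Posterior tau between a species trait and per-draw demographic rates.

    ``rate_draws`` is draws × species (as returned by
    :func:`veindemog.demogfit.growth_at_size`). For each posterior draw, tau
    (or the partial tau given ``control``) is computed across the included
    species; the 95% equal-tailed interval (type-7 quantiles) decides
    significance by strict exclusion of zero.
    """
    species = rate_draws.columns
    mask = pd.Series(True, index=species) if include is None else include.reindex(species).fillna(False).astype(bool)
    t = trait.reindex(species)
    mask &= t.notna()
    if control is not None:
        c = control.reindex(species)
        mask &= c.notna()
    used = species[mask.to_numpy()]
    n_sp = len(used)
    if n_sp < 2:
        return TauDistribution(
            trait=trait_name, rate=rate_name, ref_d=ref_d,
            tau_draws=np.array([]), median=float("nan"), q025=float("nan"),
            q975=float("nan"), significant=False, n_species=n_sp,
            control=None if control is None else getattr(control, "name", "control"),
        )
    tv = t[used].to_numpy(float)
    R = rate_draws[used].to_numpy(float).T  # species × draws
    taus = tau_b_many(tv, R)
    ctrl_name = None
    if control is not None:
        cv = c[used].to_numpy(float)
        t_xz, _ = kendall_tau(tv, cv)
        t_yz = tau_b_many(cv, R)
        taus = np.asarray(_partial_from_taus(taus, t_xz, t_yz), dtype=float)
        ctrl_name = getattr(control, "name", "control")
    finite = taus[np.isfinite(taus)]
    if finite.size == 0:
        med = q025 = q975 = float("nan")
        sig = False
    else:
        med = float(np.median(finite))
        q025 = float(np.quantile(finite, 0.025))
        q975 = float(np.quantile(finite, 0.975))
        sig = bool(q025 > 0.0 or q975 < 0.0)
    return TauDistribution(
        trait=trait_name, rate=rate_name, ref_d=ref_d, tau_draws=taus,
        median=med, q025=q025, q975=q975, significant=sig,
        n_species=n_sp, control=ctrl_name,
    )


# ---------------------------------------------------------------------------
# correlation matrices


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Kendall tau-b with P-values and per-cell sample sizes."""

    tau: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        """Significance stars: *** P<0.001, ** P<0.01, * P<0.05."""
        def star(p):
            if not np.isfinite(p):
                return ""
            return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""

        return self.p.map(star)


def _pairwise_matrix(left: pd.DataFrame, right: pd.DataFrame, square: bool) -> CorrelationMatrix:
    tau = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    p = tau.copy()
    n = pd.DataFrame(index=left.columns, columns=right.columns, dtype=int)
    for a in left.columns:
        for b in right.columns:
            xa = left[a].to_numpy(float)
            xb = right[b].to_numpy(float)
            ok = np.isfinite(xa) & np.isfinite(xb)
            n.loc[a, b] = int(ok.sum())
            if square and a == b:
                tau.loc[a, b] = np.nan  # self-correlation suppressed
                p.loc[a, b] = np.nan
                continue
            tau.loc[a, b], p.loc[a, b] = kendall_tau(xa, xb)
    return CorrelationMatrix(tau=tau, p=p, n=n)


def trait_trait_matrix(traits: pd.DataFrame) -> CorrelationMatrix:
    """Kendall tau-b between every pair of traits, pairwise-complete.

    Symmetric; the unit self-correlation is suppressed on the diagonal.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 species")
    return _pairwise_matrix(traits, traits, square=True)


def trait_soil_matrix(traits: pd.DataFrame, env: pd.DataFrame) -> CorrelationMatrix:
    """Kendall tau-b between each trait and each species-average soil variable."""
    if len(traits) < 2:
        raise ValueError("need at least 2 species")
    aligned = env.reindex(traits.index)
    return _pairwise_matrix(traits, aligned, square=False)


# ---------------------------------------------------------------------------
# soil environment


def species_env_means(census: pd.DataFrame, grids: SoilGrid | Iterable[SoilGrid]) -> pd.DataFrame:
    """Species-average soil environment.

    Each individual is mapped to the half-open grid cell containing its stem
    coordinates; the species value is the unweighted mean over its
    individuals. A stem outside the grid extent is an error naming the tree.
    """
    if isinstance(grids, SoilGrid):
        grids = [grids]
    grids = list(grids)
    x = census["x_m"].to_numpy(float)
    y = census["y_m"].to_numpy(float)
    out = {}
    for grid in grids:
        ex, ey = grid.extent_m
        bad = (x < 0) | (x >= ex) | (y < 0) | (y >= ey)
        if bad.any():
            tid = census.iloc[int(np.flatnonzero(bad)[0])]["tree_id"]
            raise ValueError(f"tree {tid!r} lies outside the {grid.variable} grid extent")
        ix = (x // grid.cell_size_m).astype(int)
        iy = (y // grid.cell_size_m).astype(int)
        vals = grid.values[iy, ix]
        out[grid.variable] = pd.Series(vals).groupby(census["species"].to_numpy()).mean()
    res = pd.DataFrame(out)
    res.index.name = "species_id"
    return res


# ---------------------------------------------------------------------------
# size profiles


@dataclass(frozen=True)
class ProfileConfig:
    """Settings for trait × rate profiles along reference diameter."""

    min_species: int = 20
    max_ref_d: float = 200.0
    alpha: float = 0.05  # trigger for partial control
    control: bool = True  # Hmax control for RGR, WD control for mortality
    partial_per_draw: bool = True  # False: partial tau on posterior-median rates
    growth_control: str = "Hmax"
    mortality_control: str = "WD"


def _controls_for(traits: pd.DataFrame, covariate: str, alpha: float) -> set[str]:
    """Traits whose trait–trait correlation with ``covariate`` has P < alpha."""
    if covariate not in traits.columns:
        warnings.warn(f"covariate {covariate!r} missing from trait table: partial control skipped", stacklevel=3)
        return set()
    hits = set()
    for t in traits.columns:
        if t == covariate:
            continue
        _, p = kendall_tau(traits[t], traits[covariate])
        if np.isfinite(p) and p < alpha:
            hits.add(t)
    return hits


def size_profile(
    traits: pd.DataFrame,
    growth_draws: demogfit.PosteriorDraws | None,
    mortality_draws: demogfit.PosteriorDraws | None,
    d95: pd.DataFrame,
    config: ProfileConfig | None = None,
) -> pd.DataFrame:
    """Tau profiles along reference diameter for every trait × rate pair.

    At each reference diameter D = 1, 2, 3, … cm, species with D95 > D are
    included; demographic-rate draws at D come from the posterior; tau (or
    the Hmax/WD-partialled tau, when the trait is correlated with the
    covariate at P < alpha) is computed per draw. A rate's profile ends at
    the last D with at least ``min_species`` included species.

    Returns a tidy frame: trait, rate, ref_d, median_tau, q025, q975,
    n_species, significant, control.
    """
    config = config or ProfileConfig()
    rate_specs = []
    if growth_draws is not None:
        rate_specs.append(("RGR", growth_draws, demogfit.growth_at_size, config.growth_control))
    if mortality_draws is not None:
        rate_specs.append(("mortality", mortality_draws, demogfit.mortality_at_size, config.mortality_control))
    if not rate_specs:
        raise ValueError("need growth and/or mortality draws")

    rows = []
    for rate_name, draws, at_size, covariate in rate_specs:
        controlled = _controls_for(traits, covariate, config.alpha) if config.control else set()
        species = [s for s in draws.species if s in d95.index]
        d95_vec = d95.loc[species, "d95_cm"]
        ref_d = 1.0
        while ref_d <= config.max_ref_d:
            included = d95_vec.index[(d95_vec > ref_d).to_numpy()]
            if len(included) < config.min_species:
                break
            rate_d = at_size(draws, ref_d)[list(included)]
            if not config.partial_per_draw:
                rate_med = rate_d.median(axis=0)
            include_mask = pd.Series(True, index=included)
            for trait_name in traits.columns:
                ctl = traits[covariate] if (trait_name in controlled and covariate in traits.columns) else None
                if ctl is not None and not config.partial_per_draw:
                    # median-rate mode: a point partial tau, no interval
                    td_tau = partial_kendall(
                        traits[trait_name].reindex(included), rate_med, ctl.reindex(included)
                    )
                    n_used = int(
                        (traits[trait_name].reindex(included).notna() & ctl.reindex(included).notna()).sum()
                    )
                    td = TauDistribution(
                        trait=trait_name, rate=rate_name, ref_d=ref_d,
                        tau_draws=np.array([td_tau]), median=td_tau, q025=td_tau,
                        q975=td_tau, significant=False, n_species=n_used,
                        control=covariate,
                    )
                else:
                    td = tau_posterior(
                        traits[trait_name], rate_d, include=include_mask, control=ctl,
                        trait_name=trait_name, rate_name=rate_name, ref_d=ref_d,
                    )
                rows.append(
                    {
                        "trait": trait_name,
                        "rate": rate_name,
                        "ref_d": ref_d,
                        "median_tau": td.median,
                        "q025": td.q025,
                        "q975": td.q975,
                        "n_species": len(included),
                        "significant": td.significant,
                        "control": td.control if ctl is not None else None,
                    }
                )
            ref_d += 1.0
    return pd.DataFrame(rows)


def large_statured_subset(traits: pd.DataFrame, k: int = 20, k_chem: int = 15) -> tuple[pd.Series, pd.Series]:
    """Masks for the top-k species by maximum height.

    Returns ``(mask, mask_chem)``; the smaller ``k_chem`` subset is intended
    for the leaf chemical traits (Nmass, Pmass), which are typically measured
    on fewer species. Ties in Hmax are broken by species id (ascending).
    """
    if "Hmax" not in traits.columns:
        raise ValueError("trait table has no Hmax column to rank by")
    hmax = traits["Hmax"].dropna()

    def top(kk: int) -> pd.Series:
        if kk >= len(hmax):
            if kk > len(hmax):
                warnings.warn(
                    f"requested top {kk} but only {len(hmax)} species have Hmax", stacklevel=3
                )
            chosen = hmax.index
        else:
            order = pd.DataFrame({"sp": hmax.index, "h": hmax.to_numpy()}).sort_values(
                ["h", "sp"], ascending=[False, True]
            )
            chosen = pd.Index(order["sp"].iloc[:kk])
        return pd.Series(traits.index.isin(chosen), index=traits.index)

    return top(k), top(k_chem)
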