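"""Synthetic forest-community inputs with known ground truth.

Every input the analysis pipeline consumes can be generated here:

* a species table of demographic parameters drawn from community-level
  (hyper) distributions — the ground truth for the hierarchical model;
* a two-census tree table simulated forward through the growth and survival
  equations the demographic model assumes;
* a species × trait table whose rank association with any demographic
  parameter is tunable (monotone link + noise + missingness);
* lattice-style binary vein images with analytically known geometry;
* pure-birth (Yule) phylogenies with Brownian-motion traits;
* spatially autocorrelated (squared-exponential) soil-variable grids.

The growth model is RGR linear in ln diameter, ``R_i = r1_j + r2_j ln D1_i``
with ``ln D2 = ln D1 + R_i (t2 - t1)``; survival is Bernoulli with
``p_i = exp(-M_i (t2 - t1))`` and log-hazard ``ln M_i = m1_j + m2_j ln D1_i
+ m3_j D1_i``. Simulation is the exact forward pass of those equations, so
fitted posteriors can be checked against known parameters.

All generators are reproducible: one root seed, with a fixed substream per
generator so adding a generator never perturbs another's draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import dendropy
import numpy as np
import pandas as pd

from . import _rng
from .veinmetrics import BinaryVeinImage

__all__ = [
    "CommunityHyperparams",
    "TraitLink",
    "TRAIT_COLUMNS",
    "default_trait_links",
    "gen_bm_traits",
    "gen_census",
    "gen_lattice_vein_image",
    "gen_phylo_with_bm",
    "gen_soil_grid",
    "gen_species_params",
    "gen_trait_table",
    "truncated_exponential",
    "SoilGrid",
]

PARAM_COLUMNS = ["r1", "r2", "m1", "m2", "m3"]

#: The twelve species traits of the standard trait table.
TRAIT_COLUMNS = [
    "VLA", "DA", "DV", "VADR", "LA", "SLA",
    "succulence", "thickness", "Nmass", "Pmass", "WD", "Hmax",
]


@dataclass(frozen=True)
class CommunityHyperparams:
    """Community-level means/SDs of the species demographic parameters.

    Units: r1 (yr⁻¹), r2 (yr⁻¹ per ln-cm), m1 (ln yr⁻¹), m2 (per ln-cm),
    m3 (cm⁻¹); ``sigma_obs`` is the SD of the ln-diameter observation error
    (ln-cm), applied to surviving trees' second-census diameters.

    Defaults describe a plausible humid-forest community: RGR around
    8 %·yr⁻¹ at 1 cm declining with size, hazard near 2 %·yr⁻¹ at 1 cm with
    a shallow U-shape in diameter, and a ~2 % diameter measurement error.
    """

    r1_mean: float = 0.08
    r1_sd: float = 0.03
    r2_mean: float = -0.01
    r2_sd: float = 0.005
    m1_mean: float = math.log(0.02)
    m1_sd: float = 0.5
    m2_mean: float = -0.2
    m2_sd: float = 0.15
    m3_mean: float = 0.01
    m3_sd: float = 0.01
    sigma_obs: float = 0.02

    def __post_init__(self) -> None:
        for name in ("r1_sd", "r2_sd", "m1_sd", "m2_sd", "m3_sd", "sigma_obs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


def gen_species_params(
    n_species: int, hyper: CommunityHyperparams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw per-species demographic parameters from the community distributions.

    Each of r1, r2, m1, m2, m3 is drawn independently Normal(mean, SD).
    Returns a frame indexed by ``species_id`` ('sp001', ...).
    """
    if n_species < 0:
        raise ValueError("n_species must be >= 0")
    hyper = hyper or CommunityHyperparams()
    rng = _rng.substream(seed, _rng.SPECIES_PARAMS)
    data = {
        p: rng.normal(getattr(hyper, f"{p}_mean"), getattr(hyper, f"{p}_sd"), size=n_species)
        for p in PARAM_COLUMNS
    }
    idx = pd.Index([f"sp{i + 1:03d}" for i in range(n_species)], name="species_id")
    return pd.DataFrame(data, index=idx)


def truncated_exponential(scale: float = 8.0, d_min: float = 1.0, d_max: float = 50.0) -> Callable:
    """Initial-diameter sampler: exponential truncated to [d_min, d_max] cm.

    Skewed toward small stems, like a real stand size structure.
    """
    if not (d_max > d_min >= 1.0):
        raise ValueError("require d_max > d_min >= 1 cm")

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        lo = 1.0 - math.exp(-(d_min - d_min) / scale)  # = 0
        hi = 1.0 - math.exp(-(d_max - d_min) / scale)
        u = rng.uniform(lo, hi, size)
        return d_min - scale * np.log1p(-u)

    return sample


def gen_census(
    params: pd.DataFrame,
    n_per_species: int,
    interval: float,
    hyper: CommunityHyperparams | None = None,
    seed: int = 0,
    d1_sampler: Callable | None = None,
    plot_x: float = 500.0,
    plot_y: float = 500.0,
    t1: float = 0.0,
    position_bias: Mapping[str, tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Simulate a two-census tree table from known species parameters.

    For each tree: ``R = r1 + r2 ln D1``; survival ~ Bernoulli(exp(-M Δt))
    with ``ln M = m1 + m2 ln D1 + m3 D1``; survivors get
    ``ln D2 = ln D1 + R Δt + Normal(0, sigma_obs)``; dead trees have no D2.
    Positions are uniform in the plot unless ``position_bias`` maps a species
    to a Gaussian habitat center ``(x, y, sd)`` (clipped to the plot), which
    is what makes trait–soil correlations non-null in experiments.
    """
    if interval <= 0:
        raise ValueError(f"census interval must be > 0, got {interval}")
    if n_per_species < 0:
        raise ValueError("n_per_species must be >= 0")
    hyper = hyper or CommunityHyperparams()
    d1_sampler = d1_sampler or truncated_exponential()
    rng = _rng.substream(seed, _rng.CENSUS)

    frames = []
    tree_counter = 0
    for sp, row in params.iterrows():
        n = n_per_species
        d1 = np.asarray(d1_sampler(rng, n), dtype=float)
        if (d1 < 1.0).any():
            raise ValueError("d1_sampler produced diameters < 1 cm (census protocol floor)")
        ln_d1 = np.log(d1)
        growth = row.r1 + row.r2 * ln_d1
        hazard = np.exp(row.m1 + row.m2 * ln_d1 + row.m3 * d1)
        p_surv = np.exp(-hazard * interval)
        status = (rng.random(n) < p_surv).astype(int)
        ln_d2 = ln_d1 + growth * interval + rng.normal(0.0, hyper.sigma_obs, n)
        d2 = np.where(status == 1, np.exp(ln_d2), np.nan)
        if position_bias and sp in position_bias:
            cx, cy, sd = position_bias[sp]
            x = np.clip(rng.normal(cx, sd, n), 0.0, plot_x)
            y = np.clip(rng.normal(cy, sd, n), 0.0, plot_y)
        else:
            x = rng.uniform(0.0, plot_x, n)
            y = rng.uniform(0.0, plot_y, n)
        frames.append(
            pd.DataFrame(
                {
                    "tree_id": np.arange(tree_counter, tree_counter + n),
                    "species": sp,
                    "d1_cm": d1,
                    "d2_cm": d2,
                    "t1_yr": t1,
                    "t2_yr": t1 + interval,
                    "status": status,
                    "x_m": x,
                    "y_m": y,
                }
            )
        )
        tree_counter += n
    if not frames:
        return pd.DataFrame(
            columns=["tree_id", "species", "d1_cm", "d2_cm", "t1_yr", "t2_yr", "status", "x_m", "y_m"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class TraitLink:
    """How one synthetic trait relates to the demographic ground truth.

    ``trait = link(params[target]) + Normal(0, noise_sd)``, with a fraction
    ``missing_frac`` of species blanked at random. ``target=None`` gives a
    trait unrelated to demography (pure noise around ``baseline``).
    """

    target: str | None = None
    link: Callable[[np.ndarray], np.ndarray] = staticmethod(lambda v: np.asarray(v, dtype=float))
    noise_sd: float = 0.0
    missing_frac: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.missing_frac < 1.0):
            raise ValueError("missing_frac must be in [0, 1)")


def default_trait_links(noise_sd: float = 0.3) -> dict[str, TraitLink]:
    """A plausible 12-trait configuration: acquisitive venation (high VLA,
    small DV) and thin leaves track fast growth; light wood tracks mortality;
    the rest are demography-neutral noise traits."""
    z = lambda f: (lambda v: f(np.asarray(v, dtype=float)))
    return {
        "VLA": TraitLink("r1", z(lambda v: 5.0 + 40.0 * v), noise_sd),
        "DA": TraitLink("r1", z(lambda v: 2.0 + 5.0 * v), noise_sd),
        "DV": TraitLink("r1", z(lambda v: 8.0 - 40.0 * v), noise_sd),
        "VADR": TraitLink("r1", z(lambda v: 4.0 - 20.0 * v), noise_sd),
        "LA": TraitLink(None, noise_sd=1.0, baseline=30.0),
        "SLA": TraitLink(None, noise_sd=20.0, baseline=150.0),
        "succulence": TraitLink("r1", z(lambda v: 0.05 - 0.2 * v), noise_sd * 0.05),
        "thickness": TraitLink("r1", z(lambda v: 0.4 - 1.5 * v), noise_sd * 0.1),
        "Nmass": TraitLink(None, noise_sd=0.4, baseline=2.0, missing_frac=0.11),
        "Pmass": TraitLink(None, noise_sd=0.05, baseline=0.15, missing_frac=0.11),
        "WD": TraitLink("m1", z(lambda v: 0.55 - 0.1 * (v - math.log(0.02))), 0.05, missing_frac=0.2),
        "Hmax": TraitLink("r1", z(lambda v: 10.0 + 100.0 * v), 3.0),
    }


def gen_trait_table(
    params: pd.DataFrame,
    links: Mapping[str, TraitLink] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a species × trait table with controlled demography association.

    Noise-free strictly monotone links give Kendall tau = ±1 with the target
    parameter by construction (rank correlation is invariant to monotone
    transforms); noise dilutes the association smoothly toward the null.
    """
    links = links if links is not None else default_trait_links()
    rng = _rng.substream(seed, _rng.TRAITS)
    n = len(params)
    out = {}
    for trait, spec in links.items():
        if spec.target is None:
            base = np.full(n, float(spec.baseline))
        else:
            if spec.target not in params.columns:
                raise ValueError(
                    f"trait {trait!r} targets unknown parameter {spec.target!r}; "
                    f"available: {list(params.columns)}"
                )
            base = np.asarray(spec.link(params[spec.target].to_numpy()), dtype=float)
        vals = base + rng.normal(0.0, spec.noise_sd, n)
        if spec.missing_frac > 0:
            vals = np.where(rng.random(n) < spec.missing_frac, np.nan, vals)
        out[trait] = vals
    tbl = pd.DataFrame(out, index=params.index.copy())
    tbl.index.name = "species_id"
    return tbl


def gen_lattice_vein_image(
    spacing_px: int,
    width_px: int,
    size_px: tuple[int, int] = (100, 100),
    pixel_size_mm: float = 0.01,
) -> BinaryVeinImage:
    """A rectangular-lattice vein image: horizontal and vertical stripes of
    the given width repeated with the given period, starting at row/col 0.

    Metadata records the stripe counts and the analytic centerline length
    (inclusion–exclusion over the stripe crossings), the ground truth that
    skeleton-based VLA approaches as spacing ≫ width.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    if spacing_px < 1:
        raise ValueError("spacing_px must be >= 1")
    nr, nc = size_px
    if nr < 1 or nc < 1:
        raise ValueError("image size must be positive")
    rows = (np.arange(nr) % spacing_px) < width_px
    cols = (np.arange(nc) % spacing_px) < width_px
    mask = rows[:, None] | cols[None, :]
    all_vein = width_px >= spacing_px
    if all_vein:
        warnings.warn("width_px >= spacing_px: every pixel is vein", stacklevel=2)
    n_h = int(rows.sum() // width_px) if not all_vein else 0
    n_v = int(cols.sum() // width_px) if not all_vein else 0
    centerline_px = n_h * nc + n_v * nr - n_h * n_v
    return BinaryVeinImage(
        mask=mask,
        pixel_size_mm=pixel_size_mm,
        meta={
            "generator": "lattice",
            "spacing_px": spacing_px,
            "width_px": width_px,
            "n_horizontal": n_h,
            "n_vertical": n_v,
            "all_vein": all_vein,
            "centerline_length_mm": centerline_px * pixel_size_mm,
        },
    )


@dataclass(frozen=True)
class SoilGrid:
    """A gridded soil variable over the plot.

    ``values[iy, ix]`` is the value of the half-open cell
    ``[ix·s, (ix+1)·s) × [iy·s, (iy+1)·s)`` with ``s = cell_size_m`` and the
    origin at the plot corner (0, 0).
    """

    variable: str
    values: np.ndarray
    cell_size_m: float = 20.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if not np.isfinite(v).all():
            raise ValueError("soil grid values must be finite")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be > 0")
        object.__setattr__(self, "values", v)

    @property
    def extent_m(self) -> tuple[float, float]:
        ny, nx = self.values.shape
        return nx * self.cell_size_m, ny * self.cell_size_m

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(ix, iy) of the half-open cell containing plot position (x, y)."""
        ex, ey = self.extent_m
        if not (0 <= x < ex and 0 <= y < ey):
            raise ValueError(f"position ({x}, {y}) outside grid extent ({ex} x {ey} m)")
        return int(x // self.cell_size_m), int(y // self.cell_size_m)


def _sq_exp_chol(n: int, cell: float, corr_length: float) -> np.ndarray:
    """Cholesky factor of the 1-D squared-exponential correlation matrix."""
    coords = (np.arange(n) + 0.5) * cell
    if corr_length <= 0:
        return np.eye(n)
    d2 = (coords[:, None] - coords[None, :]) ** 2
    corr = np.exp(-0.5 * d2 / corr_length**2)
    corr[np.diag_indices(n)] += 1e-10  # numerical jitter
    return np.linalg.cholesky(corr)


def gen_soil_grid(
    nx: int,
    ny: int,
    mean: float,
    sd: float,
    corr_length: float = 40.0,
    cell_size: float = 20.0,
    seed: int = 0,
    variable: str = "soil",
) -> SoilGrid:
    """Gaussian random field with squared-exponential spatial correlation.

    The correlation between cell centers at distance d is
    exp(-d²/(2·corr_length²)); the marginal distribution of each cell is
    Normal(mean, sd²). The separability of the squared-exponential kernel
    over x and y lets the field be sampled exactly as Lx · Z · Lyᵀ with 1-D
    Cholesky factors, avoiding the full (nx·ny)² covariance.
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be positive")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if corr_length < 0:
        raise ValueError("corr_length must be >= 0")
    rng = _rng.substream(seed, _rng.SOIL)
    z = rng.standard_normal((ny, nx))
    ly = _sq_exp_chol(ny, cell_size, corr_length)
    lx = _sq_exp_chol(nx, cell_size, corr_length)
    field = ly @ z @ lx.T
    return SoilGrid(variable=variable, values=mean + sd * field, cell_size_m=cell_size)


def _yule_tree(n_tips: int, birth_rate: float, rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth tree: exponential waiting times at rate k·λ for k extant
    lineages, a uniformly chosen lineage splits; after the n-th tip appears,
    one further Exp(n·λ) waiting time extends all pendant branches so tips
    are contemporaneous but not flush with the last split."""
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    tree = dendropy.Tree()
    tree.seed_node.edge.length = 0.0
    left, right = tree.seed_node.new_child(), tree.seed_node.new_child()
    active = [left, right]
    for node in active:
        node.edge.length = 0.0
    while True:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.edge.length += wait
        if len(active) >= n_tips:
            break
        parent = active.pop(rng.integers(len(active)))
        kids = [parent.new_child(), parent.new_child()]
        for kid in kids:
            kid.edge.length = 0.0
        active.extend(kids)
    ns = dendropy.TaxonNamespace()
    for i, node in enumerate(active):
        node.taxon = ns.new_taxon(f"sp{i + 1:03d}")
    tree.taxon_namespace = ns
    return tree


def gen_phylo_with_bm(
    n_tips: int,
    bm_sigma: float = 1.0,
    seed: int = 0,
    birth_rate: float = 1.0,
    root_value: float = 0.0,
) -> tuple[dendropy.Tree, pd.Series]:
    """A Yule (pure-birth) phylogeny with a Brownian-motion tip trait.

    The trait evolves along branches with increments Normal(0, bm_sigma²·b)
    for branch length b. Tips are labelled sp001..spNNN. Returns the tree and
    a species-indexed trait series.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if bm_sigma < 0:
        raise ValueError("bm_sigma must be >= 0")
    tree = _yule_tree(n_tips, birth_rate, _rng.substream(seed, _rng.PHYLO))

    rng = _rng.substream(seed, _rng.BM_TRAIT)
    values: dict[str, float] = {}
    tree.seed_node._bm = root_value
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        b = node.edge.length or 0.0
        node._bm = node.parent_node._bm + bm_sigma * math.sqrt(b) * rng.standard_normal()
        if node.is_leaf():
            values[node.taxon.label] = node._bm
    trait = pd.Series(values, name="bm_trait")
    trait.index.name = "species_id"
    return tree, trait


def gen_bm_traits(
    tree: dendropy.Tree,
    bm_sigma: float = 1.0,
    n_traits: int = 1,
    seed: int = 0,
    root_value: float = 0.0,
) -> pd.DataFrame:
    """Many independent Brownian-motion traits on one fixed tree.

    Returns tips × traits (columns ``bm000``, ``bm001``, ...); each column is
    an independent BM realization with increment SD ``bm_sigma`` per unit
    √branch-length. Used for replicate calibration of signal statistics.
    """
    if bm_sigma < 0:
        raise ValueError("bm_sigma must be >= 0")
    rng = _rng.substream(seed, _rng.BM_TRAIT)
    vals: dict[str, np.ndarray] = {}
    tree.seed_node._bmv = np.full(n_traits, float(root_value))
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        b = node.edge.length or 0.0
        node._bmv = node.parent_node._bmv + bm_sigma * math.sqrt(b) * rng.standard_normal(n_traits)
        if node.is_leaf():
            vals[node.taxon.label] = node._bmv
    df = pd.DataFrame(vals).T
    df.columns = [f"bm{i:03d}" for i in range(n_traits)]
    df.index.name = "species_id"
    return df
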