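"""Plain-text interchange formats for every pipeline input and output.

Census tables, trait tables and profiles are CSV; soil grids are a small
self-describing CSV (header row with the variable name, cell size and grid
shape, then row-major values); phylogenies are Newick via dendropy;
posterior draws round-trip through a tidy long CSV
(chain, iteration, species, parameter, value).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from .demogfit import PosteriorDraws
from .synthgen import SoilGrid

__all__ = [
    "read_census",
    "read_draws",
    "read_soil_grid",
    "read_traits",
    "read_tree",
    "write_census",
    "write_draws",
    "write_soil_grid",
    "write_traits",
    "write_tree",
]

CENSUS_COLUMNS = ["tree_id", "species", "d1_cm", "d2_cm", "t1_yr", "t2_yr", "status", "x_m", "y_m"]


def write_census(census: pd.DataFrame, path) -> None:
    """Census CSV; dead trees have an empty d2_cm field."""
    census.to_csv(path, index=False, columns=[c for c in CENSUS_COLUMNS if c in census.columns])


def read_census(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("species", "d1_cm", "status") if c not in df.columns]
    if missing:
        raise ValueError(f"census file missing columns: {missing}")
    return df


def write_traits(traits: pd.DataFrame, path) -> None:
    """Species × trait CSV; empty cells are missing values."""
    traits.to_csv(path, index=True)


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_soil_grid(grid: SoilGrid, path) -> None:
    ny, nx = grid.values.shape
    with open(path, "w") as fh:
        fh.write(f"variable,{grid.variable}\n")
        fh.write(f"cell_size_m,{grid.cell_size_m}\n")
        fh.write(f"nx,{nx}\nny,{ny}\norigin,0,0\n")
        for row in grid.values:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


def read_soil_grid(path) -> SoilGrid:
    with open(path) as fh:
        header = {}
        while len(header) < 5:
            key, *rest = fh.readline().strip().split(",")
            header[key] = rest
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    nx, ny = int(header["nx"][0]), int(header["ny"][0])
    if values.shape != (ny, nx):
        raise ValueError(f"grid body {values.shape} does not match header ({ny}, {nx})")
    return SoilGrid(
        variable=header["variable"][0],
        values=values,
        cell_size_m=float(header["cell_size_m"][0]),
    )


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_draws(draws: PosteriorDraws, path) -> None:
    """Posterior draws as tidy long CSV (chain, iteration, species, parameter, value)."""
    tidy = draws.to_tidy()
    tidy.insert(0, "model", draws.model)
    tidy.to_csv(path, index=False)


def read_draws(path) -> PosteriorDraws:
    tidy = pd.read_csv(path)
    model = tidy["model"].iloc[0]
    param_names = ["r1", "r2"] if model == "growth" else ["m1", "m2", "m3"]
    sp_rows = tidy[tidy["species"] != "_community"]
    species = sorted(sp_rows["species"].unique())
    chains = np.sort(tidy["chain"].unique())
    iters = np.sort(tidy["iteration"].unique())
    c, d, j, k = len(chains), len(iters), len(species), len(param_names)

    def pivot(sub: pd.DataFrame) -> np.ndarray:
        return (
            sub.set_index(["chain", "iteration"])["value"]
            .sort_index()
            .to_numpy()
            .reshape(c, d)
        )

    species_draws = np.empty((c, d, j, k))
    for kk, p in enumerate(param_names):
        for jj, sp in enumerate(species):
            species_draws[:, :, jj, kk] = pivot(sp_rows[(sp_rows.parameter == p) & (sp_rows.species == sp)])
    hyper_mean = np.stack(
        [pivot(tidy[tidy.parameter == p + "_mean"]) for p in param_names], axis=-1
    )
    hyper_sd = np.stack(
        [pivot(tidy[tidy.parameter == p + "_sd"]) for p in param_names], axis=-1
    )
    sigma = None
    if (tidy.parameter == "sigma_obs").any():
        sigma = pivot(tidy[tidy.parameter == "sigma_obs"])
    return PosteriorDraws(
        model=model,
        species=species,
        param_names=param_names,
        species_draws=species_draws,
        hyper_mean_draws=hyper_mean,
        hyper_sd_draws=hyper_sd,
        sigma_obs_draws=sigma,
    )
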