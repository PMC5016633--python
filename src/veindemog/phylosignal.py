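"""Blomberg's K and its tip-randomization test.

K measures how strongly a continuous species trait covaries with phylogeny,
scaled so that K = 1 matches the expectation under Brownian-motion (BM)
evolution along the tree: K ≪ 1 means the trait is more labile than BM
(close relatives no more similar than distant ones), K > 1 means stronger
clustering than BM. The observed ratio of the mean squared deviation from
the phylogenetically corrected mean (MSE0) to the GLS mean squared error
(MSE, through the inverse phylogenetic covariance matrix) is divided by its
BM expectation, a pure function of the tree.

The Monte Carlo P-value shuffles trait values across tips; extremeness is
measured, following picante's convention, by the variance of the
phylogenetically independent contrasts (lower contrast variance = stronger
signal), with the add-one estimator so P is never exactly zero.

Because contrast values are linear in the tip values (the Felsenstein
pruning weights depend only on topology and branch lengths), the whole
permutation null is a single matrix product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloSignalResult",
    "blomberg_k",
    "contrast_matrix",
    "k_pvalue",
    "phylo_vcv",
]


@dataclass(frozen=True)
class PhyloSignalResult:
    """Signal statistic and permutation P for one trait."""

    trait: str
    K: float
    P: float
    n_tips: int
    n_permutations: int
    seed: int


def _match(tree: dendropy.Tree, trait: pd.Series) -> tuple[list[str], np.ndarray]:
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise ValueError("tree tip labels are not unique")
    have = [t for t in tips if t in trait.index and np.isfinite(trait[t])]
    dropped = sorted(set(tips) - set(have))
    if dropped:
        warnings.warn(f"{len(dropped)} tips without trait values dropped: {dropped[:5]}...", stacklevel=3)
    if len(have) < 3:
        raise ValueError("need >= 3 matched tip/trait pairs")
    y = trait[have].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("trait is constant: phylogenetic signal undefined")
    return have, y


def _pruned(tree: dendropy.Tree, keep: list[str]) -> dendropy.Tree:
    t = tree.clone(depth=1)
    if set(keep) != {l.taxon.label for l in t.leaf_node_iter()}:
        t.retain_taxa_with_labels(keep)
    t.resolve_polytomies()  # zero-length bifurcations
    return t


def phylo_vcv(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Phylogenetic variance–covariance matrix: C[i, j] = shared root-to-MRCA
    path length of tips i and j (branch-length units)."""
    node_of = {l.taxon.label: l for l in tree.leaf_node_iter()}
    depth = {}
    for lab in labels:
        depth[lab] = node_of[lab].distance_from_root()
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    C = np.empty((n, n))
    for i, a in enumerate(labels):
        C[i, i] = depth[a]
        for j in range(i + 1, n):
            b = labels[j]
            d = pdm.patristic_distance(node_of[a].taxon, node_of[b].taxon)
            C[i, j] = C[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return C


def blomberg_k(tree: dendropy.Tree, trait: pd.Series) -> float:
    """Blomberg's K for a tip trait.

    observed = MSE0/MSE with MSE0 the variance of tip values around the
    phylogenetically corrected (GLS) mean and MSE the GLS residual mean
    square through C⁻¹; expected = (tr C − n/(1ᵀC⁻¹1)) / (n − 1).
    K is invariant to affine transforms of the trait and to uniform
    rescaling of the branch lengths.
    """
    labels, y = _match(tree, trait)
    t = _pruned(tree, labels)
    C = phylo_vcv(t, labels)
    n = len(y)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Cinv @ one
    ahat = (one @ Cinv @ y) / denom
    d = y - ahat
    mse0 = (d @ d) / (n - 1)
    mse = (d @ Cinv @ d) / (n - 1)
    expected = (np.trace(C) - n / denom) / (n - 1)
    return float((mse0 / mse) / expected)


def contrast_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Linear operator L ((n−1) × n) mapping tip values to standardized
    phylogenetically independent contrasts (Felsenstein pruning).

    The pruning weights and branch-length corrections depend only on the
    tree, so contrasts for any trait (or permutation) are ``L @ y``.
    """
    t = _pruned(tree, labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    rows = []

    # postorder: each node carries (weight vector over tips, adjusted length)
    state: dict[int, tuple[np.ndarray, float]] = {}
    for node in t.postorder_node_iter():
        elen = node.edge.length or 0.0
        if node.is_leaf():
            w = np.zeros(n)
            w[idx[node.taxon.label]] = 1.0
            state[id(node)] = (w, float(elen))
            continue
        children = node.child_nodes()
        # polytomies were resolved, so exactly two children (root may carry
        # a trailing unifurcation after pruning: collapse it)
        if len(children) == 1:
            w, v = state[id(children[0])]
            state[id(node)] = (w, v + float(elen))
            continue
        (wa, va), (wb, vb) = state[id(children[0])], state[id(children[1])]
        vsum = va + vb
        if vsum <= 0:  # zero-length cherry: unstandardizable, guard
            vsum = 1e-12
            va = vb = vsum / 2.0
        rows.append((wa - wb) / np.sqrt(vsum))
        w = (wa / va + wb / vb) / (1.0 / va + 1.0 / vb) if va > 0 and vb > 0 else (
            wa if va == 0 else wb
        )
        state[id(node)] = (w, float(elen) + va * vb / vsum)
    L = np.array(rows)
    if L.shape != (n - 1, n):
        raise RuntimeError(f"expected {n - 1} contrasts, got {L.shape[0]}")
    return L


def k_pvalue(
    tree: dendropy.Tree,
    trait: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    statistic: str = "contrast_variance",
) -> PhyloSignalResult:
    """Tip-randomization test of phylogenetic signal.

    ``statistic='contrast_variance'`` (default, picante's convention) calls a
    permutation at least as extreme as the data when its variance of
    independent contrasts is <= the observed one; ``statistic='K'`` uses
    K itself (>= observed). P = (1 + #extreme) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    labels, y = _match(tree, trait)
    K = blomberg_k(tree, trait)
    rng = np.random.default_rng(seed)
    n = len(y)
    if statistic == "contrast_variance":
        L = contrast_matrix(tree, labels)
        obs = float(np.var(L @ y, ddof=1))
        perms = np.array([y[rng.permutation(n)] for _ in range(n_perm)])  # (n_perm, n)
        null = np.var(perms @ L.T, axis=1, ddof=1)
        n_extreme = int(np.count_nonzero(null <= obs))
    elif statistic == "K":
        t = _pruned(tree, labels)
        C = phylo_vcv(t, labels)
        Cinv = np.linalg.inv(C)
        one = np.ones(n)
        denom = one @ Cinv @ one
        expected = (np.trace(C) - n / denom) / (n - 1)

        def _k(v):
            ahat = (one @ Cinv @ v) / denom
            d = v - ahat
            return ((d @ d) / (d @ Cinv @ d)) / expected

        obs = _k(y)
        n_extreme = int(sum(_k(y[rng.permutation(n)]) >= obs for _ in range(n_perm)))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    P = (1 + n_extreme) / (1 + n_perm)
    return PhyloSignalResult(
        trait=str(trait.name or "trait"), K=K, P=float(P),
        n_tips=n, n_permutations=n_perm, seed=seed,
    )
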