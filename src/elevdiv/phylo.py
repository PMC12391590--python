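"""Phylogenetic structure: patristic distances, MPD, MNTD, Blomberg's K.

The tree is a single rooted Newick tree with branch lengths whose tips map
1:1 onto the analysis species.  Assemblage structure is summarised by the
mean pairwise patristic distance (MPD; basal structure) and the mean
nearest-taxon distance (MNTD; terminal structure).  Phylogenetic signal in
continuous traits is measured by Blomberg's K, whose expectation under
Brownian motion is 1; significance comes from permuting trait values across
tips.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from ._seeding import substream

__all__ = [
    "read_tree",
    "prune_to_species",
    "resolve_polytomies",
    "patristic_matrix",
    "mpd",
    "mntd",
    "pd_table",
    "brownian_covariance",
    "blomberg_k",
    "PhyloSignalResult",
    "PdValues",
]


def read_tree(path) -> dendropy.Tree:
    """Read one rooted Newick tree, preserving branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def prune_to_species(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Prune the tree to the analysis species.

    Tips absent from ``species`` are pruned; species absent from the tree
    abort with an error listing them, because silently dropping analysis
    species would corrupt the null models downstream.
    """
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(species) - labels)
    if missing:
        raise KeyError(f"species absent from the tree: {missing}")
    tree = tree.clone(depth=1)
    keep = set(species)
    tree.retain_taxa_with_labels(sorted(keep))
    return tree


def resolve_polytomies(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Randomly resolve polytomies into bifurcations with zero-length branches.

    Patristic distances are unchanged because every inserted branch has
    length 0.  The resolution is seeded and therefore reproducible.
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted before resolving polytomies")
    import random

    out = tree.clone(depth=1)
    rng = random.Random(int(substream(seed, "polytomy").integers(2**31)))
    out.resolve_polytomies(rng=rng)
    for edge in out.preorder_edge_iter():
        if edge.length is None and edge.head_node.parent_node is not None:
            edge.length = 0.0
    return out


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Sum of branch lengths along the path between every pair of tips."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("tree has missing branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(_leaf_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def mpd(patristic: pd.DataFrame, species: list[str]) -> float:
    """Mean pairwise patristic distance within an assemblage (NaN if S < 2)."""
    if len(species) < 2:
        return float("nan")
    sub = patristic.loc[list(species), list(species)].to_numpy()
    iu = np.triu_indices(len(species), 1)
    return float(sub[iu].mean())


def mntd(patristic: pd.DataFrame, species: list[str]) -> float:
    """Mean distance to the nearest co-occurring taxon (NaN if S < 2)."""
    if len(species) < 2:
        return float("nan")
    sub = patristic.loc[list(species), list(species)].to_numpy().copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


@dataclass(frozen=True)
class PdValues:
    band: str
    richness: int
    mpd: float
    mntd: float


def pd_table(patristic: pd.DataFrame, occ) -> pd.DataFrame:
    """MPD and MNTD for every band of an occurrence matrix."""
    rows = []
    for band in occ.band_labels:
        members = occ.species_in(band)
        rows.append(
            PdValues(band=band, richness=len(members),
                     mpd=mpd(patristic, members), mntd=mntd(patristic, members))
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def brownian_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Expected trait covariance under Brownian motion: shared root-to-MRCA path.

    V[i, j] is the depth of the most recent common ancestor of tips i and j;
    V[i, i] is the tip's own depth.  Computed in one postorder sweep.
    """
    labels = sorted(_leaf_labels(tree))
    pos = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    v = np.zeros((n, n))
    depth: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            if node.edge.length is None:
                raise ValueError("tree has missing branch lengths")
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = pos[node.taxon.label]
            below[id(node)] = [k]
            v[k, k] = depth[id(node)]
        else:
            kids = [below[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        v[i, kids[b]] = d
                        v[kids[b], i] = d
            below[id(node)] = [i for kid in kids for i in kid]
    return pd.DataFrame(v, index=labels, columns=labels)


@dataclass(frozen=True)
class PhyloSignalResult:
    trait: str
    k: float
    p_value: float
    n_permutations: int


def _k_statistic(x: np.ndarray, vinv: np.ndarray, expected_ratio: float, n: int) -> float:
    ones = np.ones(n)
    denom_a = ones @ vinv @ ones
    a_hat = (ones @ vinv @ x) / denom_a
    resid = x - a_hat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ vinv @ resid / (n - 1)
    return float((mse0 / mse) / expected_ratio)


def blomberg_k(
    tree: dendropy.Tree,
    trait: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
    trait_name: str | None = None,
) -> PhyloSignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K is the observed MSE0/MSE ratio over its Brownian expectation, where
    MSE0 uses the raw residuals about the phylogenetic mean and MSE the
    V-weighted residuals (V = Brownian covariance).  K = 1 is the Brownian
    expectation; K > 1 indicates stronger-than-Brownian conservatism.  The
    p-value is the one-sided add-one permutation tail
    ``(1 + #{K_perm >= K_obs}) / (n_permutations + 1)``.
    """
    v = brownian_covariance(tree)
    x = trait.loc[v.index].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; phylogenetic signal undefined")
    n = len(x)
    vm = v.to_numpy().copy()
    # zero-length terminal branches make V singular: nudge those tips
    tip_depths = np.diag(vm).copy()
    eps = 1e-8 * tip_depths.max()
    for i in range(n):
        off = np.delete(vm[i], i).max() if n > 1 else 0.0
        if tip_depths[i] - off <= 0:
            vm[i, i] += eps
    try:
        vinv = np.linalg.inv(vm)
    except np.linalg.LinAlgError as err:
        raise ValueError("Brownian covariance matrix is singular") from err
    ones = np.ones(n)
    expected_ratio = (np.trace(vm) - n / (ones @ vinv @ ones)) / (n - 1)
    k_obs = _k_statistic(x, vinv, expected_ratio, n)
    rng = substream(seed, "blomberg", trait_name or trait.name or "trait")
    count = 0
    for _ in range(n_permutations):
        k_perm = _k_statistic(rng.permutation(x), vinv, expected_ratio, n)
        if k_perm >= k_obs:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PhyloSignalResult(
        trait=str(trait_name or trait.name or "trait"),
        k=k_obs,
        p_value=p,
        n_permutations=n_permutations,
    )
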