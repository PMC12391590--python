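"""Trait-based distances, ordination spaces and space quality.

Four trait blocks feed the analysis: one continuous morphological block
(log-transformed, z-scored, Euclidean distance) and three fuzzy-coded blocks
(diet, foraging strata, feeding strategies; Gower distance).  Each block, or
a group-balanced combination of all of them, yields a species × species
dissimilarity matrix; ordination (PCA for morphology, principal-coordinates
analysis otherwise) turns the matrix into a low-dimensional trait space in
which the functional-diversity metrics are computed.  Space quality is
scored by the mean absolute deviation (MAD) and root-mean-square deviation
(RMSD) between input dissimilarities and distances in the ordination space —
lower is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpaceQuality",
    "TraitSpace",
    "groups_from_manifest",
    "morphological_distance",
    "gower_distance",
    "combined_distance",
    "ordinate",
    "space_quality",
    "select_n_axes",
]


def groups_from_manifest(manifest: Mapping[str, Mapping[str, str]]) -> dict[str, list[str]]:
    """Invert a column manifest into ``{group: [columns in declared order]}``."""
    groups: dict[str, list[str]] = {}
    for col, meta in manifest.items():
        groups.setdefault(meta["group"], []).append(col)
    return groups


def _check_square(d: pd.DataFrame) -> None:
    a = d.to_numpy()
    if a.shape[0] != a.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(a < 0):
        raise ValueError("distances must be non-negative")


def log_z_scores(morph: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform then z-score each trait (sample SD, ddof=1).

    Zero-variance traits are dropped with a warning; non-positive values are
    an error because the log transform requires strictly positive traits.
    """
    if (morph.to_numpy() <= 0).any():
        bad = morph.index[(morph <= 0).any(axis=1)]
        raise ValueError(f"non-positive morphological values for: {list(bad)}")
    logged = np.log(morph.astype(float))
    sd = logged.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"zero-variance traits dropped: {list(sd.index[~keep])}", stacklevel=2
        )
    logged = logged.loc[:, keep]
    return (logged - logged.mean(axis=0)) / logged.std(axis=0, ddof=1)


def morphological_distance(morph: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance on log-transformed, z-scored morphological traits."""
    if len(morph) < 2:
        raise ValueError("need at least two species")
    z = log_z_scores(morph)
    d = squareform(pdist(z.to_numpy()))
    return pd.DataFrame(d, index=morph.index, columns=morph.index)


def gower_distance(
    blocks: Mapping[str, pd.DataFrame],
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Gower dissimilarity for fuzzy-coded trait blocks.

    Within one fuzzy group the dissimilarity between two species is half the
    Manhattan distance between their proportion profiles, which spans [0, 1]
    because each profile sums to 1.  Multiple groups combine as a weighted
    mean of per-group dissimilarities (equal weights by default).
    """
    if not blocks:
        raise ValueError("no fuzzy blocks given")
    index = next(iter(blocks.values())).index
    total = None
    wsum = 0.0
    for name, block in blocks.items():
        rows = block.to_numpy(dtype=float)
        if np.any(rows < 0) or np.any(rows > 1):
            raise ValueError(f"fuzzy block {name!r} has entries outside [0, 1]")
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-6):
            bad = block.index[~np.isclose(rows.sum(axis=1), 1.0, atol=1e-6)]
            raise ValueError(f"fuzzy block {name!r} rows not normalised: {list(bad)}")
        d = 0.5 * squareform(pdist(rows, metric="cityblock"))
        w = 1.0 if weights is None else float(weights[name])
        total = w * d if total is None else total + w * d
        wsum += w
    return pd.DataFrame(total / wsum, index=index, columns=index)


def combined_distance(
    traits: pd.DataFrame,
    manifest: Mapping[str, Mapping[str, str]],
    weights: Mapping[str, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Group-balanced dissimilarity across all four trait blocks.

    The morphology block contributes its Euclidean distances rescaled to
    [0, 1] by the pool maximum; each fuzzy block contributes its Gower
    dissimilarities.  Unless explicit ``weights`` are given, block weights
    are rescaled iteratively until every block's mean contribution to the
    combined dissimilarity is equal (tolerance ``tol``); on non-convergence
    the function falls back to equal weights with a warning.

    Returns the combined matrix and the weights used (summing to 1).
    """
    groups = groups_from_manifest(manifest)
    block_d: dict[str, np.ndarray] = {}
    index = traits.index
    for group, cols in groups.items():
        kind = manifest[cols[0]]["type"]
        sub = traits[cols]
        if kind == "continuous":
            d = squareform(pdist(log_z_scores(sub).to_numpy()))
            dmax = d.max()
            if dmax > 0:
                d = d / dmax
        else:
            d = gower_distance({group: sub}).to_numpy()
        block_d[group] = d

    names = list(block_d)
    if weights is not None:
        w = np.array([float(weights[g]) for g in names])
        w = w / w.sum()
    else:
        w = np.full(len(names), 1.0 / len(names))
        means = np.array([block_d[g][np.triu_indices(len(index), 1)].mean() for g in names])
        if np.any(means == 0):
            warnings.warn("a trait block has zero mean dissimilarity; equal weights used",
                          stacklevel=2)
        else:
            converged = False
            for _ in range(max_iter):
                contrib = w * means
                target = contrib.mean()
                if np.max(np.abs(contrib - target)) < tol:
                    converged = True
                    break
                w = w * target / contrib
                w = w / w.sum()
            if not converged:
                warnings.warn("block balancing did not converge; equal weights used",
                              stacklevel=2)
                w = np.full(len(names), 1.0 / len(names))
    combined = sum(wi * block_d[g] for wi, g in zip(w, names))
    out = pd.DataFrame(combined, index=index, columns=index)
    _check_square(out)
    return out, dict(zip(names, (float(x) for x in w)))


@dataclass(frozen=True)
class SpaceQuality:
    """Deviation between input dissimilarities and ordination distances."""

    mad: float
    rmsd: float
    m_axes: int


@dataclass
class TraitSpace:
    """Species coordinates on the retained ordination axes of one trait set."""

    name: str
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    method: str
    quality: SpaceQuality | None = None

    @property
    def m_axes(self) -> int:
        return self.coordinates.shape[1]

    def points(self, species: Sequence[str] | np.ndarray | None = None) -> np.ndarray:
        if species is None:
            return self.coordinates.to_numpy()
        return self.coordinates.loc[list(species)].to_numpy()


def _pcoa(dist: pd.DataFrame, m_axes: int) -> TraitSpace:
    from skbio import DistanceMatrix as SkbioDM
    from skbio.stats.ordination import pcoa as skbio_pcoa

    with warnings.catch_warnings():
        # negative eigenvalues (non-Euclidean Gower input) are clipped to 0
        # and the corresponding axes dropped; the residual shows up in
        # MAD/RMSD instead of being absorbed by a Cailliez/Lingoes shift
        warnings.simplefilter("ignore")
        res = skbio_pcoa(SkbioDM(dist.to_numpy(), ids=[str(s) for s in dist.index]))
    eig = res.eigvals.to_numpy()
    positive = int((eig > 1e-10).sum())
    m = min(m_axes, positive)
    if m < m_axes:
        warnings.warn(
            f"only {positive} positive eigenvalues; retaining {m} axes", stacklevel=3
        )
    coords = pd.DataFrame(
        res.samples.to_numpy()[:, :m],
        index=dist.index,
        columns=[f"axis_{j + 1}" for j in range(m)],
    )
    return TraitSpace(name="", coordinates=coords, eigenvalues=eig[:m], method="pcoa")


def _pca(raw: pd.DataFrame, m_axes: int) -> TraitSpace:
    from sklearn.decomposition import PCA

    m = min(m_axes, min(raw.shape[0] - 1, raw.shape[1]))
    if m < m_axes:
        warnings.warn(f"PCA rank limits axes to {m}", stacklevel=3)
    model = PCA(n_components=m, svd_solver="full")
    scores = model.fit_transform(raw.to_numpy())
    coords = pd.DataFrame(
        scores, index=raw.index, columns=[f"axis_{j + 1}" for j in range(m)]
    )
    eig = model.explained_variance_ * 1.0
    return TraitSpace(name="", coordinates=coords, eigenvalues=eig, method="pca")


def ordinate(
    data: pd.DataFrame,
    method: str = "pcoa",
    m_axes: int = 2,
    name: str = "",
) -> TraitSpace:
    """Build a trait space by classical metric scaling or PCA.

    ``method='pcoa'`` expects a square dissimilarity matrix; axes with
    non-positive eigenvalues are dropped (with a warning if that reduces
    ``m_axes``).  ``method='pca'`` expects the raw (already log/z-scored)
    trait matrix; because PCA of a Euclidean cloud and PCoA of its distance
    matrix coincide, this is the exact-space route for morphology.
    """
    if m_axes < 1:
        raise ValueError("m_axes must be >= 1")
    if method == "pcoa":
        _check_square(data)
        space = _pcoa(data, m_axes)
        space.quality = space_quality(data, space)
    elif method == "pca":
        space = _pca(data, m_axes)
        d_in = pd.DataFrame(
            squareform(pdist(data.to_numpy())), index=data.index, columns=data.index
        )
        space.quality = space_quality(d_in, space)
    else:
        raise ValueError(f"unknown ordination method {method!r}")
    space.name = name
    return space


def space_quality(dist: pd.DataFrame, space: TraitSpace) -> SpaceQuality:
    """MAD and RMSD between input and in-space pairwise distances."""
    if list(dist.index) != list(space.coordinates.index):
        raise ValueError("distance matrix and space must index the same species")
    d_in = squareform(dist.to_numpy(), checks=False)
    d_sp = pdist(space.coordinates.to_numpy())
    dev = d_in - d_sp
    return SpaceQuality(
        mad=float(np.mean(np.abs(dev))),
        rmsd=float(np.sqrt(np.mean(dev**2))),
        m_axes=space.m_axes,
    )


def select_n_axes(
    dist: pd.DataFrame,
    method: str = "pcoa",
    max_axes: int | None = None,
    criterion: str = "mad",
    raw: pd.DataFrame | None = None,
) -> int:
    """Smallest-deviation axis count, capped at ``max_axes``.

    Scans m = 1..cap and returns the m minimising the chosen quality metric
    (first minimum on ties, favouring fewer axes).  ``max_axes`` should be
    at most (minimum assemblage richness − 1) when hull volumes will be
    computed in the space.
    """
    n = len(dist)
    cap = n - 1 if max_axes is None else min(max_axes, n - 1)
    cap = max(cap, 1)
    best_m, best_q = 1, np.inf
    for m in range(1, cap + 1):
        data = dist if method == "pcoa" else raw
        space = ordinate(data, method=method, m_axes=m)
        q = getattr(space.quality, criterion)
        if q < best_q - 1e-12:
            best_m, best_q = m, q
    return best_m
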