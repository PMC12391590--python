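"""Functional-diversity metrics per assemblage: FRic, FNND, FEve.

All three are computed on assemblage point clouds in a shared ordination
space (one global space per trait set, so values are comparable across
bands):

* FRic — convex-hull volume of the assemblage's points, optionally divided
  by the all-species pool hull volume;
* FNND — mean distance from each species to its nearest co-occurring
  species (low = densely packed trait space);
* FEve — regularity of the minimum-spanning-tree edge lengths linking the
  assemblage's points, scaled to [0, 1] (presence-absence weights).

Undefined cases (too few species for a hull, fewer than 3 for FEve, fewer
than 2 for FNND) are reported as NaN rather than raising, because bands near
the top of a gradient are legitimately species-poor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from ._seeding import substream

__all__ = ["hull_volume", "fric", "fnnd", "feve", "mst_edge_lengths", "fd_table", "FdValues"]


@dataclass(frozen=True)
class FdValues:
    """FD metrics of one assemblage in one trait space."""

    band: str
    trait_set: str
    richness: int
    fric_raw: float
    fric_rel: float
    fnnd: float
    feve: float
    degenerate: bool = False


def hull_volume(points: np.ndarray, jitter_seed: int = 0) -> tuple[float, bool]:
    """Convex-hull volume of an S × m point cloud.

    In one dimension the hull volume is the point range.  Affinely dependent
    (flat) point sets break Qhull; they are retried after a deterministic
    jitter of 1e-9 × coordinate range and flagged.  Returns
    ``(volume, was_degenerate)``; volume is NaN when S <= m.
    """
    points = np.asarray(points, dtype=float)
    s, m = points.shape
    if s <= m:
        return float("nan"), False
    if m == 1:
        return float(points.max() - points.min()), False
    try:
        return float(ConvexHull(points).volume), False
    except QhullError:
        rng = substream(jitter_seed, "hull-jitter")
        scale = np.ptp(points, axis=0)
        scale[scale == 0] = 1.0
        jittered = points + rng.normal(0.0, 1e-9, size=points.shape) * scale
        try:
            return float(ConvexHull(jittered).volume), True
        except QhullError:
            return float("nan"), True


def fric(
    points: np.ndarray,
    pool_points: np.ndarray | None = None,
    relative: bool = False,
    jitter_seed: int = 0,
) -> tuple[float, bool]:
    """Functional richness: hull volume, optionally relative to the pool hull.

    Returns ``(value, degenerate_flag)``.  NaN (with a warning) when the
    assemblage has too few species to span the space.
    """
    vol, degen = hull_volume(points, jitter_seed=jitter_seed)
    if np.isnan(vol):
        warnings.warn(
            f"FRic undefined: {points.shape[0]} species in {points.shape[1]}-D space",
            stacklevel=2,
        )
        return vol, degen
    if relative:
        if pool_points is None:
            raise ValueError("relative FRic needs the pool point cloud")
        pool_vol, pool_degen = hull_volume(pool_points, jitter_seed=jitter_seed)
        degen = degen or pool_degen
        vol = vol / pool_vol if pool_vol > 0 else float("nan")
    return vol, degen


def fnnd(points: np.ndarray | None = None, dist: np.ndarray | None = None) -> float:
    """Mean nearest-neighbour distance among co-occurring species.

    Accepts either coordinates or a precomputed square distance matrix
    (the raw-distance variant).  NaN for fewer than two species.
    """
    if dist is None:
        if points is None:
            raise ValueError("give points or dist")
        if len(points) < 2:
            return float("nan")
        dist = squareform(pdist(np.asarray(points, dtype=float)))
    else:
        dist = np.asarray(dist, dtype=float)
        if len(dist) < 2:
            return float("nan")
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def mst_edge_lengths(points: np.ndarray) -> np.ndarray:
    """Edge lengths of the minimum spanning tree over a point cloud.

    Ties between equal-length candidate edges cannot change the multiset of
    MST edge lengths (all minimum spanning trees share it), so any
    deterministic MST algorithm yields the same FEve.
    """
    d = squareform(pdist(np.asarray(points, dtype=float)))
    mst = minimum_spanning_tree(d).toarray()
    return mst[mst > 0]


def feve(points: np.ndarray) -> float:
    """Functional evenness (presence-absence weighting).

    With S species and the S−1 MST edge lengths EW_l, let
    PEW_l = EW_l / ΣEW_l.  Then
    FEve = (Σ_l min(PEW_l, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1)),
    which is 1 for perfectly regular spacing and tends to 0 as edge lengths
    concentrate.  NaN for S < 3 or a fully coincident point set.
    """
    points = np.asarray(points, dtype=float)
    s = len(points)
    if s < 3:
        return float("nan")
    ew = mst_edge_lengths(points)
    total = ew.sum()
    if len(ew) < s - 1:
        # zero-length edges (duplicated points) are dropped by the sparse
        # graph representation; restore them explicitly
        ew = np.concatenate([ew, np.zeros(s - 1 - len(ew))])
    if total == 0:
        return float("nan")
    pew = ew / total
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def fd_table(space, occ, trait_set: str | None = None, jitter_seed: int = 0) -> pd.DataFrame:
    """FD metrics for every band of an occurrence matrix in one space.

    Returns a tidy frame: band, trait_set, richness, FRic raw and relative
    (to the pool hull), FNND, FEve and a degeneracy flag.
    """
    name = trait_set if trait_set is not None else space.name
    pool = space.points(occ.species)
    rows = []
    for band in occ.band_labels:
        members = occ.species_in(band)
        pts = space.points(members)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw, degen = fric(pts, jitter_seed=jitter_seed)
            rel, _ = fric(pts, pool_points=pool, relative=True, jitter_seed=jitter_seed)
        rows.append(
            FdValues(
                band=band,
                trait_set=name,
                richness=len(members),
                fric_raw=raw,
                fric_rel=rel,
                fnnd=fnnd(points=pts),
                feve=feve(pts),
                degenerate=degen,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
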