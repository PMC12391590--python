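"""Niche packing vs. niche expansion between adjacent assemblages.

Comparing a species-richer assemblage A1 with a species-poorer assemblage
A2, species unique to A1 are removed greedily — always the one contributing
most to A1's convex-hull volume (largest leave-one-out volume drop, ties
broken lexicographically by species id) — until A1's hull volume is equal to
or lower than A2's.  Unique species still present at that point were
accommodated *inside* the poorer assemblage's functional volume: their
percentage is the contribution of niche packing to the richness difference,
and the removed percentage is the contribution of niche expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fd import hull_volume

__all__ = ["unique_species", "packing_decomposition", "packing_table", "PackingResult"]


@dataclass(frozen=True)
class PackingResult:
    """Greedy decomposition of one richer/poorer assemblage pair."""

    band_rich: str
    band_poor: str
    n_unique: int
    n_removed: int
    packing_pct: float
    expansion_pct: float
    volume_rich: float
    volume_poor: float
    exhausted: bool = False


def unique_species(occ, band1: str, band2: str) -> list[str]:
    """Species present in ``band1`` but absent from ``band2``."""
    for b in (band1, band2):
        if b not in occ.band_labels:
            raise KeyError(f"unknown band {b!r}")
    return sorted(set(occ.species_in(band1)) - set(occ.species_in(band2)))


def packing_decomposition(space, occ, band_rich: str, band_poor: str,
                          jitter_seed: int = 0) -> PackingResult:
    """Greedy hull-volume removal of the richer band's unique species.

    Requires hull volumes to be defined for both assemblages (S > m axes).
    Terminates when the current A1 volume is <= A2's volume, or when unique
    species run out (flagged ``exhausted``: the shared species alone span a
    larger hull than A2's).
    """
    rich = occ.species_in(band_rich)
    poor = occ.species_in(band_poor)
    if len(rich) <= len(poor):
        raise ValueError(f"band {band_rich!r} is not richer than {band_poor!r}")
    uniq = unique_species(occ, band_rich, band_poor)
    vol_poor, _ = hull_volume(space.points(poor), jitter_seed=jitter_seed)
    current = sorted(rich)
    vol_rich, _ = hull_volume(space.points(current), jitter_seed=jitter_seed)
    if np.isnan(vol_poor) or np.isnan(vol_rich):
        raise ValueError(
            f"hull volume undefined for {band_rich!r} or {band_poor!r} "
            f"(too few species for a {space.m_axes}-D hull)"
        )
    removed: list[str] = []
    remaining = list(uniq)
    vol_current = vol_rich
    exhausted = False
    while vol_current > vol_poor:
        if not remaining:
            exhausted = True
            break
        best_sp, best_vol = None, np.inf
        for sp in remaining:  # lexicographic order; ties keep the first
            subset = [s for s in current if s != sp]
            vol, _ = hull_volume(space.points(subset), jitter_seed=jitter_seed)
            if np.isnan(vol):
                vol = 0.0
            if vol < best_vol - 1e-15:
                best_sp, best_vol = sp, vol
        current.remove(best_sp)
        remaining.remove(best_sp)
        removed.append(best_sp)
        vol_current = best_vol

    n_unique = len(uniq)
    n_removed = n_unique if exhausted else len(removed)
    packing = 100.0 * (n_unique - n_removed) / n_unique if n_unique else float("nan")
    expansion = 100.0 * n_removed / n_unique if n_unique else float("nan")
    return PackingResult(
        band_rich=band_rich,
        band_poor=band_poor,
        n_unique=n_unique,
        n_removed=n_removed,
        packing_pct=packing,
        expansion_pct=expansion,
        volume_rich=vol_rich,
        volume_poor=vol_poor,
        exhausted=exhausted,
    )


def packing_table(space, occ, trait_set: str | None = None,
                  jitter_seed: int = 0) -> pd.DataFrame:
    """Decompose every adjacent band pair (richer vs. poorer) in one space.

    Pairs with equal richness, or where either hull is undefined, are
    reported with NaN percentages and a note rather than dropped, so the
    output always covers the full gradient.
    """
    name = trait_set if trait_set is not None else space.name
    rich = occ.richness()
    rows = []
    labels = occ.band_labels
    for low, high in zip(labels[:-1], labels[1:]):
        s_low, s_high = int(rich[low]), int(rich[high])
        if s_low == s_high:
            rows.append({"trait_set": name, "band_rich": low, "band_poor": high,
                         "n_unique": np.nan, "packing_pct": np.nan,
                         "expansion_pct": np.nan, "note": "equal richness"})
            continue
        band_rich, band_poor = (low, high) if s_low > s_high else (high, low)
        try:
            res = packing_decomposition(space, occ, band_rich, band_poor,
                                        jitter_seed=jitter_seed)
        except ValueError as err:
            rows.append({"trait_set": name, "band_rich": band_rich,
                         "band_poor": band_poor, "n_unique": np.nan,
                         "packing_pct": np.nan, "expansion_pct": np.nan,
                         "note": str(err)})
            continue
        rows.append({"trait_set": name, "band_rich": res.band_rich,
                     "band_poor": res.band_poor, "n_unique": res.n_unique,
                     "packing_pct": res.packing_pct,
                     "expansion_pct": res.expansion_pct,
                     "note": "exhausted" if res.exhausted else ""})
    return pd.DataFrame(rows)
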