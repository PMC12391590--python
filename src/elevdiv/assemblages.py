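"""Elevational-band assemblages from interpolated species ranges.

A species' elevational range is interpolated as the closed interval between
its lowest and highest records (all survey methods pooled).  The gradient is
tiled by contiguous half-open bands ``[lower, lower + width)``; a species is
a member of every band its range intersects, so each band's species set is a
distinct assemblage.  Presence is therefore contiguous across bands by
construction, and this invariant is asserted on every build.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ElevationalBand",
    "OccurrenceMatrix",
    "build_bands",
    "interpolate_ranges",
    "apply_exclusions",
    "assemble",
    "richness",
    "assign_guilds",
]


@dataclass(frozen=True)
class ElevationalBand:
    """Half-open elevation interval ``[lower, upper)`` in metres a.s.l."""

    lower: float
    upper: float

    @property
    def label(self) -> str:
        return f"{self.lower:g}"

    def intersects(self, lo: float, hi: float) -> bool:
        """Does the closed range [lo, hi] overlap this half-open band?"""
        return hi >= self.lower and lo < self.upper


def build_bands(lower: float = 350.0, upper: float = 2350.0, width: float = 200.0) -> list[ElevationalBand]:
    """Tile ``[lower, upper)`` with contiguous bands of equal ``width``."""
    if width <= 0:
        raise ValueError("band width must be positive")
    n = (upper - lower) / width
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"gradient span {upper - lower} is not divisible by width {width}")
    n = int(round(n))
    if n < 1:
        raise ValueError("gradient must contain at least one band")
    return [ElevationalBand(lower + i * width, lower + (i + 1) * width) for i in range(n)]


def interpolate_ranges(records: pd.DataFrame) -> pd.DataFrame:
    """Pool occurrence records into per-species (min_elev, max_elev) ranges.

    ``records`` needs columns ``species`` and ``elevation``; any other
    columns (survey method, date) are ignored — all methods are pooled.
    """
    if records.empty:
        raise ValueError("no occurrence records supplied")
    grouped = records.groupby("species")["elevation"].agg(min_elev="min", max_elev="max")
    grouped.index.name = "species"
    return grouped


def apply_exclusions(
    ranges: pd.DataFrame,
    deny_list: Iterable[str] = (),
    reason: str = "excluded taxon",
) -> pd.DataFrame:
    """Flag denied species; excluded rows are dropped by :func:`assemble`.

    The deny-list names species ids (the caller expands family-level rules
    such as raptors / swifts / swallows / Palearctic migrants to ids).
    Unknown names are ignored with a warning.
    """
    out = ranges.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
        out["exclusion_reason"] = ""
    deny = set(deny_list)
    missing = deny - set(out.index)
    if missing:
        warnings.warn(f"deny-list names absent from ranges: {sorted(missing)}", stacklevel=2)
    hit = out.index.isin(deny)
    out.loc[hit, "excluded"] = True
    out.loc[hit, "exclusion_reason"] = reason
    logger.info("exclusions: %d of %d species flagged", int(hit.sum()), len(out))
    return out


class OccurrenceMatrix:
    """Species × band presence/absence table (the unit of 'assemblage').

    Wraps a binary DataFrame whose columns are band labels in elevational
    order.  Construction validates that every species occupies at least one
    band and that its occupied bands form a contiguous run.
    """

    def __init__(self, matrix: pd.DataFrame, bands: Sequence[ElevationalBand]):
        if list(matrix.columns) != [b.label for b in bands]:
            raise ValueError("matrix columns must match band labels in order")
        values = matrix.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("occurrence matrix must be binary")
        occupancy = values.sum(axis=1)
        if (occupancy == 0).any():
            empty = list(matrix.index[occupancy == 0])
            raise ValueError(f"species occupy no band: {empty}")
        for sp, row in zip(matrix.index, values):
            occ = np.flatnonzero(row)
            if occ[-1] - occ[0] + 1 != len(occ):
                raise ValueError(f"presence of {sp!r} is not contiguous across bands")
        self.matrix = matrix.astype(np.int8)
        self.bands = list(bands)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def band_labels(self) -> list[str]:
        return list(self.matrix.columns)

    def species_in(self, band_label: str) -> list[str]:
        col = self.matrix[band_label]
        return list(col.index[col == 1])

    def species_indices(self, band_label: str, index: pd.Index | None = None) -> np.ndarray:
        """Integer row positions (into ``index`` or own index) of a band's members."""
        members = self.species_in(band_label)
        idx = self.matrix.index if index is None else index
        return idx.get_indexer(members)

    def richness(self) -> pd.Series:
        return self.matrix.sum(axis=0).astype(int)

    def __repr__(self) -> str:  # pragma: no cover
        return f"OccurrenceMatrix({len(self.species)} species x {len(self.bands)} bands)"


def assemble(ranges: pd.DataFrame, bands: Sequence[ElevationalBand]) -> OccurrenceMatrix:
    """Build the occurrence matrix by intersecting ranges with bands.

    Excluded species (see :func:`apply_exclusions`) are dropped.  Ranges are
    clipped to the gradient; a range entirely outside it is dropped with a
    warning.
    """
    work = ranges
    if "excluded" in work.columns:
        work = work.loc[~work["excluded"].astype(bool)]
    lo, hi = bands[0].lower, bands[-1].upper
    below = work["max_elev"] < lo
    above = work["min_elev"] >= hi
    outside = below | above
    if outside.any():
        warnings.warn(
            f"ranges entirely outside the gradient dropped: {list(work.index[outside])}",
            stacklevel=2,
        )
        work = work.loc[~outside]
    if (work["min_elev"] > work["max_elev"]).any():
        bad = work.index[work["min_elev"] > work["max_elev"]]
        raise ValueError(f"min_elev exceeds max_elev for: {list(bad)}")
    clipped_lo = work["min_elev"].clip(lower=lo)
    clipped_hi = work["max_elev"].clip(upper=hi - 1e-9)
    if (work["min_elev"] < lo).any() or (work["max_elev"] > hi).any():
        logger.info("ranges clipped to the %s-%s m gradient", lo, hi)
    data = {
        b.label: [
            int(b.intersects(l, h)) for l, h in zip(clipped_lo.to_numpy(), clipped_hi.to_numpy())
        ]
        for b in bands
    }
    matrix = pd.DataFrame(data, index=work.index)
    return OccurrenceMatrix(matrix, bands)


def richness(occ: OccurrenceMatrix) -> pd.Series:
    """Species count per band (taxonomic diversity along the gradient)."""
    return occ.richness()


def assign_guilds(
    traits: pd.DataFrame,
    manifest: Mapping[str, Mapping[str, str]],
    groups: Sequence[str] = ("diet", "strata"),
) -> pd.DataFrame:
    """Label each species by its dominant axis within each fuzzy group.

    The guild is the arg-max axis of the group's fuzzy profile; ties go to
    the first axis in declared column order (a uniform row triggers a
    warning).  Returns one column per requested group, e.g. ``diet_guild``.
    """
    out = {}
    for group in groups:
        cols = [c for c, meta in manifest.items() if meta["group"] == group]
        if not cols:
            raise KeyError(f"no columns declared for fuzzy group {group!r}")
        block = traits[cols].to_numpy(dtype=float)
        if (block.sum(axis=1) == 0).any():
            bad = traits.index[block.sum(axis=1) == 0]
            raise ValueError(f"all-zero {group} profile for: {list(bad)}")
        uniform = (block.max(axis=1) - block.min(axis=1)) < 1e-12
        if uniform.any():
            warnings.warn(
                f"uniform {group} profiles assigned to first axis: "
                f"{list(traits.index[uniform])}",
                stacklevel=2,
            )
        # np.argmax takes the first maximum: the declared tie-break
        winners = np.argmax(block, axis=1)
        axis_names = [c[len(group) + 1 :] for c in cols]
        out[f"{group}_guild"] = [axis_names[w] for w in winners]
    return pd.DataFrame(out, index=traits.index)
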