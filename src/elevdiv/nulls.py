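"""Randomisation null models and standardized effect sizes (SES).

The nulls randomise *labels*, never the occurrence matrix: trait rows are
permuted against species labels (whole rows travel together across all trait
blocks) and phylogeny tip labels are permuted on a fixed topology.  Band
membership is untouched, so species richness and range contiguity are
conserved by construction.  Because every metric here depends on species
only through a labelled structure (ordination coordinates or a distance
matrix), one label permutation per replicate — shared across bands and
metrics — defines the whole replicate.

For each metric × band, SES = (Observed − null mean) / null SD, and the
observed value is called significant when it falls outside the empirical
2.5%–97.5% quantiles of the null distribution (linear, type-7
interpolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import dendropy
import numpy as np
import pandas as pd

from ._seeding import substream

__all__ = [
    "shuffle_trait_rows",
    "shuffle_tip_labels",
    "NullDistribution",
    "SesResult",
    "ses",
    "null_ses_table",
]

DEFAULT_N_REPS = 500
DEFAULT_QUANTILES = (0.025, 0.975)


def shuffle_trait_rows(traits: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Permute species labels against intact trait rows.

    Rows travel together across all trait blocks, preserving within-species
    trait covariance; the multiset of rows is unchanged.
    """
    rng = substream(seed, "trait-shuffle")
    perm = rng.permutation(len(traits))
    out = traits.copy()
    out.index = traits.index[perm]
    return out.loc[traits.index]


def shuffle_tip_labels(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Permute tip labels on a fixed topology with fixed branch lengths."""
    rng = substream(seed, "tip-shuffle")
    out = tree.clone(depth=1)
    leaves = list(out.leaf_node_iter())
    taxa = [leaf.taxon for leaf in leaves]
    for leaf, k in zip(leaves, rng.permutation(len(leaves))):
        leaf.taxon = taxa[int(k)]
    return out


@dataclass
class NullDistribution:
    """Null replicate values of one metric in one band."""

    metric: str
    band: str
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1))

    @property
    def n_reps(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SesResult:
    """Observed value, null summary, SES and the two-tailed significance call."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float
    q_low: float
    q_high: float
    significant: bool
    n_reps: int


def ses(
    observed: float,
    null_values: np.ndarray,
    quantiles: tuple[float, float] = DEFAULT_QUANTILES,
) -> SesResult:
    """Standardize an observed metric against its null distribution.

    SES = (Observed − mean) / SD; significance is decided by the empirical
    null quantiles, not by the SES value.  A degenerate (constant) null
    yields SES = NaN and significance iff the observed value differs from
    the constant.  NaN replicates are dropped; if more than half are NaN the
    null is considered unusable and an error is raised.
    """
    values = np.asarray(null_values, dtype=float)
    ok = values[~np.isnan(values)]
    if len(ok) < max(2, len(values) // 2):
        raise ValueError(
            f"metric undefined in {len(values) - len(ok)} of {len(values)} null replicates"
        )
    mean = float(ok.mean())
    sd = float(ok.std(ddof=1))
    q_low, q_high = (float(q) for q in np.quantile(ok, quantiles))
    if np.isnan(observed):
        return SesResult(observed, mean, sd, float("nan"), q_low, q_high, False, len(values))
    if sd == 0:
        warnings.warn("degenerate null distribution (SD = 0)", stacklevel=2)
        return SesResult(
            observed, mean, sd, float("nan"), q_low, q_high, observed != mean, len(values)
        )
    return SesResult(
        observed,
        mean,
        sd,
        (observed - mean) / sd,
        q_low,
        q_high,
        bool(observed < q_low or observed > q_high),
        len(values),
    )


def null_ses_table(
    occ,
    evaluators: Mapping[tuple[str, str], Callable[[np.ndarray], float]],
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    quantiles: tuple[float, float] = DEFAULT_QUANTILES,
    stream: str = "nulls",
) -> pd.DataFrame:
    """Observed values, null distributions and SES for every metric × band.

    ``evaluators`` maps ``(trait_set_or_tree, metric)`` to a function of the
    integer row positions of an assemblage's species in the pool ordering
    ``occ.species``.  Each replicate draws one permutation of the pool
    labels (a trait-row / tip-label shuffle) shared by all evaluators and
    bands; the occurrence matrix itself is never touched.
    """
    species = occ.species
    n = len(species)
    band_idx = {b: occ.species_indices(b) for b in occ.band_labels}

    observed = {
        (key, b): fn(band_idx[b]) for key, fn in evaluators.items() for b in occ.band_labels
    }
    nulls = {k: np.empty(n_reps) for k in observed}
    for rep in range(n_reps):
        rng = substream(seed, stream, rep)
        perm = rng.permutation(n)
        for key, fn in evaluators.items():
            for b in occ.band_labels:
                nulls[(key, b)][rep] = fn(perm[band_idx[b]])

    rows = []
    for (key, b), obs in observed.items():
        trait_set, metric = key
        try:
            res = ses(obs, nulls[(key, b)], quantiles=quantiles)
        except ValueError:
            # metric undefined in most replicates (assemblage too small):
            # keep the cell, explicitly missing
            nan = float("nan")
            res = SesResult(obs, nan, nan, nan, nan, nan, False, n_reps)
        rows.append(
            {
                "trait_set": trait_set,
                "metric": metric,
                "band": b,
                "observed": res.observed,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "ses": res.ses,
                "q_low": res.q_low,
                "q_high": res.q_high,
                "significant": res.significant,
                "n_reps": res.n_reps,
            }
        )
    return pd.DataFrame(rows)
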