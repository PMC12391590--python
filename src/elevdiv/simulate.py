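"""Synthetic elevational-gradient datasets.

Generates the three inputs the analysis pipeline consumes — contiguous
species elevational ranges, a trait table (five continuous morphological
traits plus fuzzy-coded diet / foraging-stratum / feeding-strategy profiles),
and a rooted ultrametric phylogeny — with controlled statistical structure:

* ranges are drawn as (midpoint, extent) with midpoint density decaying with
  elevation, so expected band richness declines toward the top of the
  gradient;
* morphological traits are log-normal, optionally evolved by Brownian motion
  along the simulated tree so they carry phylogenetic signal;
* fuzzy trait groups are Dirichlet draws, row-normalised to sum to one;
* trait *scenarios* impose community-assembly structure on the continuous
  traits: ``filtering`` pulls co-occurring species toward band-specific
  optima (trait clustering), ``limiting_similarity`` thins out within-band
  pairs that are too close in trait space (trait overdispersion), and
  ``neutral`` leaves traits untouched.

All randomness flows from one master seed through named substreams
(:func:`elevdiv._seeding.substream`), so identical configurations yield
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._seeding import substream

__all__ = [
    "DEFAULT_FUZZY_AXES",
    "MORPHOLOGY_TRAITS",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_fuzzy_traits",
    "simulate_ranges",
    "apply_trait_scenario",
    "simulate_dataset",
    "write_dataset",
]

#: Continuous morphological traits (measured in the field as mass/lengths;
#: simulated here on a log scale, hence log-normal marginals).
MORPHOLOGY_TRAITS = (
    "body_mass",
    "wing_length",
    "tail_length",
    "tarsus_length",
    "culmen_length",
)

#: Fuzzy trait groups and their niche axes: proportional use of six dietary
#: items, four vegetation strata and seven feeding strategies; each group's
#: row sums to 1.
DEFAULT_FUZZY_AXES: Mapping[str, tuple[str, ...]] = {
    "diet": (
        "invertebrates",
        "vertebrates",
        "fruits",
        "nectar",
        "seeds",
        "other_plant",
    ),
    "strata": ("ground", "low", "mid", "canopy"),
    "strategies": (
        "foliage_glean",
        "bark_probe",
        "flycatch",
        "sit_and_wait",
        "ground_search",
        "fruit_take",
        "nectar_take",
    ),
}

_SCENARIOS = ("neutral", "filtering", "limiting_similarity")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic gradient.

    Defaults mirror the structure of a tropical-mountain bird survey: a
    2000-m forest gradient split into 200-m bands, ~100 breeding species
    with contiguous ranges and richness declining with elevation.
    """

    n_species: int = 100
    elevation_min: float = 350.0
    elevation_max: float = 2350.0
    band_width: float = 200.0
    #: dimensionless decay of range-midpoint density with relative elevation;
    #: 0 = flat richness, larger = steeper low-elevation richness peak.
    richness_gradient: float = 1.5
    trait_scenario: str = "neutral"
    scenario_strength: float = 0.0
    #: Brownian-motion rate of log-trait evolution per unit tree depth.
    bm_sigma: float = 1.0
    #: Dirichlet concentration per fuzzy group (scalar broadcast per axis).
    dirichlet_alpha: Mapping[str, float] = field(
        default_factory=lambda: {"diet": 0.8, "strata": 0.8, "strategies": 0.8}
    )
    birth_rate: float = 1.0
    #: median and log-SD of the log-normal range extent (metres).
    extent_median: float = 800.0
    extent_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if not self.elevation_max > self.elevation_min:
            raise ValueError("elevation_max must exceed elevation_min")
        if self.band_width <= 0:
            raise ValueError("band_width must be positive")
        if self.trait_scenario not in _SCENARIOS:
            raise ValueError(f"unknown trait_scenario {self.trait_scenario!r}")
        if any(a <= 0 for a in self.dirichlet_alpha.values()):
            raise ValueError("dirichlet_alpha entries must be positive")

    def species_ids(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{str(i + 1).zfill(width)}" for i in range(self.n_species)]


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Simulate a rooted bifurcating pure-birth (Yule) tree.

    Lineages split after exponential waiting times with total rate
    ``k * birth_rate``; after the n-th lineage appears the process runs for
    one more exponential waiting time so every terminal branch has strictly
    positive length.  Tips are labelled ``sp001``.. in leaf-traversal order.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = substream(seed, "tree")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # active lineages as (node, birth_time of its subtending edge)
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = [(tree.seed_node, 0.0)]
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.edge.length = t - born if node.parent_node is not None else None
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, t))
        active.append((right, t))
    t_end = t + rng.exponential(1.0 / (n_species * birth_rate))
    for node, born in active:
        node.edge.length = t_end - born

    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        taxon = taxa.new_taxon(label=f"sp{str(i + 1).zfill(width)}")
        leaf.taxon = taxon
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree,
    n_traits: int = 5,
    bm_sigma: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Evolve ``n_traits`` independent traits by Brownian motion on ``tree``.

    Each edge contributes a Gaussian increment with variance
    ``bm_sigma**2 * edge_length``; the root value is 0.  Returns a tip ×
    trait table (columns ``trait_1``..), rows ordered by tip label.
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    edge_total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    if edge_total <= 0:
        raise ValueError("tree has zero total depth; cannot evolve traits")
    rng = substream(seed, "bm")
    values: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.zeros(n_traits)
        else:
            length = node.edge.length or 0.0
            step = (
                rng.normal(0.0, bm_sigma * np.sqrt(length), size=n_traits)
                if length > 0 and bm_sigma > 0
                else np.zeros(n_traits)
            )
            values[id(node)] = values[id(node.parent_node)] + step
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    data = np.vstack([values[id(leaf)] for leaf in tree.leaf_node_iter()])
    out = pd.DataFrame(data, index=labels, columns=[f"trait_{j + 1}" for j in range(n_traits)])
    out.index.name = "species"
    return out.sort_index()


def simulate_fuzzy_traits(
    species: Sequence[str] | int,
    dirichlet_alpha: Mapping[str, float | Sequence[float]] | None = None,
    axes: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw fuzzy-coded trait groups from per-group Dirichlet distributions.

    Each group's row is renormalised to sum to exactly 1.  Column names are
    ``<group>_<axis>``.
    """
    if isinstance(species, int):
        width = len(str(species))
        species = [f"sp{str(i + 1).zfill(width)}" for i in range(species)]
    axes = dict(axes or DEFAULT_FUZZY_AXES)
    alpha_by_group = dict(dirichlet_alpha or {})
    rng = substream(seed, "fuzzy")
    blocks = []
    for group, names in axes.items():
        alpha = alpha_by_group.get(group, 1.0)
        alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float), (len(names),)).copy()
        if np.any(alpha_vec <= 0):
            raise ValueError(f"dirichlet alpha for group {group!r} must be positive")
        draw = rng.dirichlet(alpha_vec, size=len(species))
        draw = draw / draw.sum(axis=1, keepdims=True)
        blocks.append(
            pd.DataFrame(draw, index=list(species), columns=[f"{group}_{a}" for a in names])
        )
    out = pd.concat(blocks, axis=1)
    out.index.name = "species"
    return out


def simulate_ranges(config: SimulationConfig) -> pd.DataFrame:
    """Draw contiguous elevational ranges as (midpoint, extent) pairs.

    Midpoints follow a truncated-exponential density decaying with relative
    elevation at rate ``richness_gradient`` (0 = uniform); extents are
    log-normal; ranges are clipped to the gradient, so every species spans a
    non-empty interval and occupies at least one band.
    """
    rng = substream(config.seed, "ranges")
    lo, hi = config.elevation_min, config.elevation_max
    span = hi - lo
    extent = rng.lognormal(mean=np.log(config.extent_median), sigma=config.extent_sigma,
                           size=config.n_species)
    # midpoints live on the extent-extended domain (lo - e/2, hi + e/2) so a
    # band's coverage probability does not suffer edge deficits: at gradient 0
    # every band is covered with the same probability (e + width)/(span + e)
    u = rng.uniform(low=1e-12, high=1.0 - 1e-12, size=config.n_species)
    g = config.richness_gradient
    ext_span = span + extent
    if g > 0:
        # truncated-exponential inverse CDF, decay rate g per gradient span
        total = 1.0 - np.exp(-g * ext_span / span)
        mid = (lo - extent / 2.0) - (span / g) * np.log1p(-u * total)
    else:
        mid = (lo - extent / 2.0) + u * ext_span
    min_elev = np.clip(mid - extent / 2.0, lo, hi)
    max_elev = np.clip(mid + extent / 2.0, lo, hi)
    out = pd.DataFrame(
        {"species": config.species_ids(), "min_elev": min_elev, "max_elev": max_elev}
    ).set_index("species")
    return out


def _standardize_log(morph: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    logged = np.log(morph.to_numpy(dtype=float))
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (logged - mu) / sd, mu, sd


def apply_trait_scenario(
    traits: pd.DataFrame,
    occurrence,
    scenario: str,
    strength: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Impose assembly structure on continuous (morphological) traits.

    ``filtering``: each species is pulled toward the trait optimum of its
    *home band* (the band holding its range midpoint); optima drift linearly
    along the gradient, so co-occurring species converge and within-band
    nearest-neighbour distances shrink (expected SES.FNND < 0).

    ``limiting_similarity``: within every band, pairs of co-occurring
    species closer than a minimum standardized trait distance are thinned —
    one member of the offending pair is re-drawn from the pool trait
    distribution until no within-band pair violates the threshold (or an
    iteration cap is hit).  Expected SES.FNND > 0.

    ``neutral``: traits are returned unchanged.

    Transformations act on the log/z-standardized scale and are mapped back,
    preserving positivity and the pool-level trait location/scale.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "neutral" or strength == 0:
        return traits.copy()
    if strength < 0:
        raise ValueError("scenario strength must be non-negative")

    rng = substream(seed, "scenario", scenario)
    z, mu, sd = _standardize_log(traits)
    n, p = z.shape
    occ01 = occurrence.matrix.reindex(traits.index).to_numpy()
    # home band = centre of the occupied band run (presence is contiguous)
    band_idx = np.arange(occ01.shape[1])
    home = np.rint((occ01 * band_idx).sum(axis=1) / occ01.sum(axis=1)).astype(int)

    if scenario == "filtering":
        n_bands = occ01.shape[1]
        direction = rng.normal(size=p)
        direction /= np.linalg.norm(direction)
        centers = np.linspace(-1.5, 1.5, n_bands)[:, None] * direction[None, :]
        w = min(float(strength), 1.0)
        z_new = (1.0 - w) * z + w * centers[home]
    else:  # limiting_similarity
        from scipy.spatial.distance import pdist, squareform

        z_new = z.copy()
        d = squareform(pdist(z_new))
        np.fill_diagonal(d, np.inf)
        pool_nn = np.median(d.min(axis=1))
        r_min = min(float(strength), 3.0) * pool_nn
        co = (occ01 @ occ01.T) > 0  # i, j co-occur in >= 1 band
        np.fill_diagonal(co, False)
        for _ in range(50 * n):
            viol = np.where(co & (d < r_min))
            if viol[0].size == 0:
                break
            # closest violating pair first
            k = np.argmin(d[viol])
            i, j = int(viol[0][k]), int(viol[1][k])
            victim = j if traits.index[j] > traits.index[i] else i
            z_new[victim] = rng.normal(size=p)
            di = np.linalg.norm(z_new - z_new[victim], axis=1)
            d[victim, :] = di
            d[:, victim] = di
            d[victim, victim] = np.inf

    out = pd.DataFrame(np.exp(mu + sd * z_new), index=traits.index, columns=traits.columns)
    out.index.name = traits.index.name
    return out


@dataclass
class SyntheticDataset:
    """One simulated study: ranges, traits (+ manifest), phylogeny, config."""

    config: SimulationConfig
    ranges: pd.DataFrame
    traits: pd.DataFrame
    manifest: dict[str, dict[str, str]]
    tree: dendropy.Tree

    @property
    def morphology(self) -> pd.DataFrame:
        cols = [c for c, m in self.manifest.items() if m["group"] == "morphology"]
        return self.traits[cols]


def _build_manifest(fuzzy_axes: Mapping[str, Sequence[str]]) -> dict[str, dict[str, str]]:
    manifest = {c: {"group": "morphology", "type": "continuous"} for c in MORPHOLOGY_TRAITS}
    for group, names in fuzzy_axes.items():
        for a in names:
            manifest[f"{group}_{a}"] = {"group": group, "type": "fuzzy"}
    return manifest


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete, mutually consistent synthetic study.

    Morphological traits are ``exp(mu_t + bm_sigma-scaled Brownian values)``
    on the simulated tree (log-normal marginals with phylogenetic signal);
    fuzzy groups are Dirichlet; the trait scenario from the config is applied
    to the morphological block using the assembled occurrence matrix.
    """
    from .assemblages import assemble, build_bands

    tree = simulate_tree(config.n_species, config.birth_rate, seed=config.seed)
    bm = simulate_bm_traits(tree, n_traits=len(MORPHOLOGY_TRAITS),
                            bm_sigma=config.bm_sigma, seed=config.seed)
    # plausible avian log-scale locations: mass ~ 30 g, lengths ~ 15-80 mm;
    # Brownian values rescaled so log-trait SD across the pool is ~0.4
    base = np.log([30.0, 80.0, 70.0, 25.0, 15.0])
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    log_scale = 0.4 / max(np.sqrt(depth), 1e-12)
    morph = pd.DataFrame(
        np.exp(base + log_scale * bm.to_numpy()),
        index=bm.index,
        columns=list(MORPHOLOGY_TRAITS),
    )
    fuzzy = simulate_fuzzy_traits(list(bm.index), config.dirichlet_alpha, seed=config.seed)
    ranges = simulate_ranges(config)

    bands = build_bands(config.elevation_min, config.elevation_max, config.band_width)
    occ = assemble(ranges, bands)
    morph = apply_trait_scenario(
        morph, occ, config.trait_scenario, config.scenario_strength, seed=config.seed
    )
    traits = morph.join(fuzzy.loc[morph.index])
    traits.index.name = "species"
    return SyntheticDataset(
        config=config,
        ranges=ranges,
        traits=traits,
        manifest=_build_manifest(DEFAULT_FUZZY_AXES),
        tree=tree,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write ranges CSV, trait CSV + JSON manifest, and Newick tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ranges": outdir / "ranges.csv",
        "traits": outdir / "traits.csv",
        "manifest": outdir / "trait_manifest.json",
        "tree": outdir / "tree.nwk",
    }
    dataset.ranges.rename(
        columns={"min_elev": "min_elev_m", "max_elev": "max_elev_m"}
    ).to_csv(paths["ranges"])
    dataset.traits.to_csv(paths["traits"])
    paths["manifest"].write_text(json.dumps(dataset.manifest, indent=1))
    dataset.tree.write(path=str(paths["tree"]), schema="newick", suppress_rooting=True)
    return paths
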