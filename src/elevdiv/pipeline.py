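"""End-to-end orchestration: inputs -> assemblages -> spaces -> metrics ->
nulls/SES -> trends -> packing -> summary.

One :class:`PipelineConfig` drives the whole analysis, either from files
(ranges or raw occurrence records, trait table + manifest, Newick tree) or
from the synthetic generator.  Every stage writes a diff-able TSV whose
first line records the package version and master seed, and the resolved
configuration is snapshotted next to the outputs, so a run can be
reproduced or resumed stage by stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import assemblages as asm
from . import fd as fdmod
from . import nulls as nullmod
from . import packing as packmod
from . import phylo as phylomod
from . import trends as trendmod
from . import traitspace as tsmod
from ._seeding import spawn_seed
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "ValidationReport", "load_inputs",
           "validate_inputs", "run_pipeline"]

TRAIT_SETS = ("morphology", "diet", "strata", "strategies", "all")
FD_METRICS = ("fric", "fnnd", "feve")
PD_METRICS = ("mpd", "mntd")
#: axis-count ceiling: hull volumes in more than ~6 dimensions are both
#: numerically fragile and slow, and ordination quality gains level off
MAX_AXES = 6


@dataclass
class PipelineConfig:
    """Everything one run needs; file inputs and synthetic input are exclusive."""

    occurrence_path: str | None = None
    traits_path: str | None = None
    manifest_path: str | None = None
    tree_path: str | None = None
    synthetic: SimulationConfig | None = None
    band_lower: float = 350.0
    band_upper: float = 2350.0
    band_width: float = 200.0
    trait_sets: tuple[str, ...] = TRAIT_SETS
    exclusions: tuple[str, ...] = ()
    n_null_reps: int = 500
    n_signal_perms: int = 1000
    quantiles: tuple[float, float] = (0.025, 0.975)
    m_axes: int | None = None
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.trait_sets) - set(TRAIT_SETS)
        if unknown:
            raise ValueError(f"unknown trait sets: {sorted(unknown)}")
        if self.synthetic is None and self.occurrence_path is None:
            raise ValueError("either synthetic config or input paths are required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ValidationReport:
    issues: list[dict] = field(default_factory=list)

    def add(self, severity: str, message: str) -> None:
        self.issues.append({"severity": severity, "message": message})

    @property
    def fatal(self) -> list[dict]:
        return [i for i in self.issues if i["severity"] == "fatal"]

    @property
    def ok(self) -> bool:
        return not self.fatal


@dataclass
class PipelineResult:
    """All stage outputs of one run, as in-memory tables."""

    config: PipelineConfig
    occurrence: asm.OccurrenceMatrix
    richness: pd.Series
    spaces: dict[str, tsmod.TraitSpace]
    space_quality: pd.DataFrame
    fd: pd.DataFrame
    pd_: pd.DataFrame
    signal: pd.DataFrame
    ses: pd.DataFrame
    trends: pd.DataFrame
    packing: pd.DataFrame
    guild_richness: pd.DataFrame
    summary: "pd.DataFrame | None" = None


def load_inputs(config: PipelineConfig):
    """Load (ranges, traits, manifest, tree) from files or the generator."""
    if config.synthetic is not None:
        ds = simulate_dataset(config.synthetic)
        return ds.ranges, ds.traits, ds.manifest, ds.tree
    occ_df = pd.read_csv(config.occurrence_path, comment="#")
    cols = {c.lower(): c for c in occ_df.columns}
    if "elevation" in cols or "elevation_m" in cols:
        col = cols.get("elevation", cols.get("elevation_m"))
        ranges = asm.interpolate_ranges(occ_df.rename(columns={col: "elevation"}))
    else:
        ren = {}
        for want in ("min_elev", "max_elev"):
            for cand in (want, want + "_m"):
                if cand in cols:
                    ren[cols[cand]] = want
        ranges = occ_df.rename(columns=ren).set_index("species")[["min_elev", "max_elev"]]
    traits = pd.read_csv(config.traits_path, index_col=0, comment="#")
    traits.index.name = "species"
    mpath = Path(config.manifest_path)
    if mpath.suffix in (".yaml", ".yml"):
        manifest = yaml.safe_load(mpath.read_text())
    else:
        manifest = json.loads(mpath.read_text())
    tree = phylomod.read_tree(config.tree_path)
    return ranges, traits, manifest, tree


def validate_inputs(
    ranges: pd.DataFrame,
    traits: pd.DataFrame,
    manifest: Mapping[str, Mapping[str, str]],
    tree: dendropy.Tree,
) -> ValidationReport:
    """Cross-check label concordance, trait validity and tree coverage."""
    report = ValidationReport()
    range_sp = set(ranges.index)
    trait_sp = set(traits.index)
    tree_sp = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for name, missing in (
        ("trait table", range_sp - trait_sp),
        ("tree", range_sp - tree_sp),
    ):
        if missing:
            report.add("fatal", f"species missing from {name}: {sorted(missing)}")
    unknown_cols = set(traits.columns) - set(manifest)
    if unknown_cols:
        report.add("fatal", f"trait columns absent from manifest: {sorted(unknown_cols)}")
        return report
    groups = tsmod.groups_from_manifest(manifest)
    for group, cols in groups.items():
        kind = manifest[cols[0]]["type"]
        block = traits[[c for c in cols if c in traits.columns]]
        if kind == "continuous":
            bad = block.index[(block <= 0).any(axis=1)]
            if len(bad):
                report.add("fatal", f"non-positive {group} values for: {list(bad)}")
        else:
            sums = block.sum(axis=1)
            bad = block.index[~np.isclose(sums, 1.0, atol=1e-6)]
            if len(bad):
                report.add("fatal", f"{group} rows not summing to 1: {list(bad)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            report.add("fatal", "tree has missing branch lengths")
            break
    if (ranges["min_elev"] > ranges["max_elev"]).any():
        bad = ranges.index[ranges["min_elev"] > ranges["max_elev"]]
        report.add("fatal", f"inverted ranges for: {list(bad)}")
    return report


def _build_spaces(
    traits: pd.DataFrame,
    manifest: Mapping[str, Mapping[str, str]],
    trait_sets: tuple[str, ...],
    m_cap: int,
) -> dict[str, tsmod.TraitSpace]:
    groups = tsmod.groups_from_manifest(manifest)
    spaces: dict[str, tsmod.TraitSpace] = {}
    for name in trait_sets:
        if name == "morphology":
            raw = tsmod.log_z_scores(traits[groups["morphology"]])
            m = min(m_cap, raw.shape[1], raw.shape[0] - 1)
            spaces[name] = tsmod.ordinate(raw, method="pca", m_axes=m, name=name)
        elif name == "all":
            dist, weights = tsmod.combined_distance(traits, manifest)
            logger.info("combined-distance block weights: %s", weights)
            spaces[name] = tsmod.ordinate(dist, method="pcoa", m_axes=m_cap, name=name)
        else:
            dist = tsmod.gower_distance({name: traits[groups[name]]})
            spaces[name] = tsmod.ordinate(dist, method="pcoa", m_axes=m_cap, name=name)
    return spaces


def _fd_evaluators(space: tsmod.TraitSpace, pool: list[str], jitter_seed: int):
    coords = space.points(pool)

    def _fric(idx: np.ndarray) -> float:
        return fdmod.hull_volume(coords[idx], jitter_seed=jitter_seed)[0]

    def _fnnd(idx: np.ndarray) -> float:
        return fdmod.fnnd(points=coords[idx])

    def _feve(idx: np.ndarray) -> float:
        return fdmod.feve(coords[idx])

    return {"fric": _fric, "fnnd": _fnnd, "feve": _feve}


def _pd_evaluators(patristic: pd.DataFrame, pool: list[str]):
    d = patristic.loc[pool, pool].to_numpy()

    def _mpd(idx: np.ndarray) -> float:
        if len(idx) < 2:
            return float("nan")
        sub = d[np.ix_(idx, idx)]
        return float(sub[np.triu_indices(len(idx), 1)].mean())

    def _mntd(idx: np.ndarray) -> float:
        if len(idx) < 2:
            return float("nan")
        sub = d[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        return float(sub.min(axis=1).mean())

    return {"mpd": _mpd, "mntd": _mntd}


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# elevdiv v{_version} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage under one master seed and return the result bundle.

    Raises ``ValueError`` listing the offending species when the occurrence,
    trait and tree species sets disagree after exclusions.
    """
    ranges, traits, manifest, tree = load_inputs(config)
    report = validate_inputs(ranges, traits, manifest, tree)
    if not report.ok:
        raise ValueError(f"input validation failed: {report.fatal}")

    bands = asm.build_bands(config.band_lower, config.band_upper, config.band_width)
    if config.exclusions:
        ranges = asm.apply_exclusions(ranges, config.exclusions)
    occ = asm.assemble(ranges, bands)
    pool = occ.species
    traits = traits.loc[pool]
    richness = occ.richness()
    logger.info("assembled %d species into %d bands", len(pool), len(bands))

    tree = phylomod.prune_to_species(tree, pool)
    tree = phylomod.resolve_polytomies(tree, seed=spawn_seed(config.seed, "resolve"))
    patristic = phylomod.patristic_matrix(tree)

    m_cap = config.m_axes or min(MAX_AXES, max(int(richness.min()) - 1, 1))
    spaces = _build_spaces(traits, manifest, config.trait_sets, m_cap)
    quality = pd.DataFrame(
        [
            {"trait_set": n, "method": s.method, "m_axes": s.m_axes,
             "mad": s.quality.mad, "rmsd": s.quality.rmsd}
            for n, s in spaces.items()
        ]
    )

    fd_frames = []
    for name, space in spaces.items():
        fd_frames.append(
            fdmod.fd_table(space, occ, trait_set=name,
                           jitter_seed=spawn_seed(config.seed, "jitter", name))
        )
    fd_all = pd.concat(fd_frames, ignore_index=True)
    pd_table = phylomod.pd_table(patristic, occ)

    groups = tsmod.groups_from_manifest(manifest)
    signal_rows = []
    if "morphology" in groups:
        for col in groups["morphology"]:
            res = phylomod.blomberg_k(
                tree, traits[col], n_permutations=config.n_signal_perms,
                seed=spawn_seed(config.seed, "signal"), trait_name=col,
            )
            signal_rows.append(dataclasses.asdict(res))
    signal = pd.DataFrame(signal_rows)

    evaluators = {}
    for name, space in spaces.items():
        for metric, fn in _fd_evaluators(
            space, pool, spawn_seed(config.seed, "jitter", name)
        ).items():
            evaluators[(name, metric)] = fn
    ses_fd = nullmod.null_ses_table(
        occ, evaluators, n_reps=config.n_null_reps,
        seed=spawn_seed(config.seed, "nulls"), quantiles=config.quantiles,
        stream="trait-shuffle",
    )
    ses_pd = nullmod.null_ses_table(
        occ, {("tree", m): f for m, f in _pd_evaluators(patristic, pool).items()},
        n_reps=config.n_null_reps, seed=spawn_seed(config.seed, "nulls"),
        quantiles=config.quantiles, stream="tip-shuffle",
    )
    ses_all = pd.concat([ses_fd, ses_pd], ignore_index=True)

    elevations = {b.label: b.lower for b in bands}
    obs_frame = pd.concat(
        [
            fd_all.rename(columns={"fric_raw": "fric"})[
                ["band", "trait_set", "fric", "fnnd", "feve"]
            ],
            pd_table.assign(trait_set="tree")[["band", "trait_set", "mpd", "mntd"]],
        ],
        ignore_index=True,
    )
    ses_wide = ses_all.pivot_table(
        index=["band", "trait_set"], columns="metric", values="ses", aggfunc="first"
    ).reset_index()
    ses_wide.columns = [
        c if c in ("band", "trait_set") else f"ses_{c}" for c in ses_wide.columns
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trends_obs = trendmod.trends_table(
            obs_frame, elevations, ["fric", "fnnd", "feve", "mpd", "mntd"]
        )
        trends_ses = trendmod.trends_table(
            ses_wide, elevations,
            [c for c in ses_wide.columns if c.startswith("ses_")],
        )
    trends = pd.concat([trends_obs, trends_ses], ignore_index=True)

    packing_frames = [
        packmod.packing_table(space, occ, trait_set=name,
                              jitter_seed=spawn_seed(config.seed, "jitter", name))
        for name, space in spaces.items()
    ]
    packing = pd.concat(packing_frames, ignore_index=True)

    fuzzy_groups = [g for g in ("diet", "strata") if g in groups]
    if fuzzy_groups:
        guilds = asm.assign_guilds(traits, manifest, groups=fuzzy_groups)
        counts = []
        for b in occ.band_labels:
            members = occ.species_in(b)
            for gcol in guilds.columns:
                vc = guilds.loc[members, gcol].value_counts()
                for guild, cnt in vc.items():
                    counts.append({"band": b, "guild_type": gcol, "guild": guild,
                                   "richness": int(cnt)})
        guild_richness = pd.DataFrame(counts)
    else:
        guild_richness = pd.DataFrame(columns=["band", "guild_type", "guild", "richness"])

    result = PipelineResult(
        config=config, occurrence=occ, richness=richness, spaces=spaces,
        space_quality=quality, fd=fd_all, pd_=pd_table, signal=signal,
        ses=ses_all, trends=trends, packing=packing, guild_richness=guild_richness,
    )
    from .reporting import summarize

    result.summary = summarize(result)

    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    seed = result.config.seed
    _write_tsv(result.occurrence.matrix.reset_index(names="species"),
               outdir / "occurrence.tsv", seed)
    _write_tsv(result.richness.rename("richness").rename_axis("band").reset_index(),
               outdir / "richness.tsv", seed)
    _write_tsv(result.space_quality, outdir / "space_quality.tsv", seed)
    _write_tsv(result.fd, outdir / "fd.tsv", seed)
    _write_tsv(result.pd_, outdir / "pd.tsv", seed)
    _write_tsv(result.signal, outdir / "phylosignal.tsv", seed)
    _write_tsv(result.ses, outdir / "ses.tsv", seed)
    _write_tsv(result.trends, outdir / "trends.tsv", seed)
    _write_tsv(result.packing, outdir / "packing.tsv", seed)
    _write_tsv(result.guild_richness, outdir / "guild_richness.tsv", seed)
    if result.summary is not None:
        _write_tsv(result.summary, outdir / "summary.tsv", seed)
    cfg = result.config.to_dict()
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
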