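# elevdiv

Functional and phylogenetic structure of species assemblages along
elevational gradients.

`elevdiv` is a Python library for community ecologists asking *how*
assemblages are put together along a mountainside: does species richness
decline with elevation because abiotic filtering clusters ecologically
similar species, because competition spaces them out, or by chance?  It
implements the full analysis chain used in elevational bird-assemblage
studies — range interpolation into band assemblages, multi-block trait
spaces, functional and phylogenetic diversity, label-randomisation null
models, segmented elevational trends, and the decomposition of richness
differences into niche packing vs. niche expansion — together with a
synthetic-data generator so every stage is testable without field data.

## The analysis

**Assemblages.** Each species is assumed present at every elevation between
its lowest and highest records (range interpolation).  The gradient
(default 350–2350 m) is tiled by half-open 200-m bands `[lower, lower+200)`;
the species whose ranges intersect a band form that band's assemblage.

**Trait spaces.** Five morphological traits (body mass; wing, tail, tarsus
and culmen lengths) are log-transformed, z-scored and carried into a PCA
space (Euclidean distances).  Three fuzzy-coded trait groups — proportional
use of 6 diet items, 4 foraging strata, 7 feeding strategies, each profile
summing to 1 — use the Gower distance (half the Manhattan distance within a
group) and PCoA.  A combined space balances all four blocks so each
contributes equally to the mean dissimilarity.  Space quality is the
MAD/RMSD between input and in-space distances.

**Diversity metrics.** For an assemblage of S species with points
x₁…x_S in the m-axis space:

- FRic — convex-hull volume (optionally relative to the species-pool hull);
- FNND — mean over species of the distance to the nearest co-occurring
  species;
- FEve — with MST edge lengths EW_l and PEW_l = EW_l/ΣEW_l,
  `FEve = (Σ min(PEW_l, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1))` in [0, 1];
- MPD / MNTD — mean pairwise / mean nearest-taxon patristic distance on a
  rooted phylogeny;
- Blomberg's K — the observed MSE₀/MSE ratio over its Brownian expectation
  (V = shared root-to-ancestor path lengths); K = 1 under Brownian motion,
  tested by permuting trait values across tips.

**Null models and SES.** Trait rows (or tip labels) are shuffled against
species 500 times while the occurrence matrix stays fixed, conserving
richness and range contiguity.  `SES = (Observed − X̄)/SD(X)`; a value is
significant when it falls outside the null's empirical 2.5%–97.5%
quantiles.  Negative SES of FRic/FNND reads as trait clustering
(environmental filtering), positive as overdispersion (limiting
similarity).

**Trends.** Every observed and SES metric is regressed on the band lower
elevation.  A one-breakpoint segmented model (iterative linearisation) is
adopted only when the Davies test — the best difference-in-slope statistic
over candidate breakpoints with the correction for a parameter that exists
only under the alternative — is significant at p < 0.05; otherwise the
relationship is reported linear.

**Niche packing vs. expansion.** Comparing a richer assemblage A₁ with a
poorer adjacent assemblage A₂, the species unique to A₁ contributing most
hull volume are removed greedily until A₁'s volume is ≤ A₂'s.  The share of
unique species never removed is the richness increase due to packing; the
removed share is due to expansion.

## Worked example

Detecting environmental filtering that the generator built in
(`examples/05_null_models_ses.py`):

```python
import numpy as np
import elevdiv as ed
from elevdiv.fd import fnnd
from elevdiv.nulls import null_ses_table
from elevdiv.traitspace import log_z_scores

config = ed.SimulationConfig(n_species=60, trait_scenario="filtering",
                             scenario_strength=0.8, seed=7)
dataset = ed.simulate_dataset(config)
occ = ed.assemble(dataset.ranges, ed.build_bands())
coords = log_z_scores(dataset.morphology.loc[occ.species]).to_numpy()
table = null_ses_table(
    occ, {("morphology", "fnnd"): lambda idx: fnnd(points=coords[idx])},
    n_reps=500, seed=11)
```

prints

```
band  observed  null_mean  null_sd    ses  significant
 350     0.911      1.077    0.075 -2.207         True
 550     0.977      1.124    0.088 -1.662        False
 750     0.905      1.154    0.091 -2.726         True
 950     0.987      1.125    0.082 -1.673        False
1150     1.014      1.123    0.086 -1.258        False
1350     0.851      1.093    0.078 -3.106         True
1550     0.853      1.144    0.092 -3.180         True
1750     0.861      1.179    0.098 -3.242         True
1950     1.033      1.236    0.110 -1.839        False
2150     1.242      1.357    0.146 -0.787        False

mean SES.FNND = -2.17
```

Co-occurring species are closer in trait space than trait-shuffle nulls
allow (SES.FNND < 0 in every band, significantly so in five): the signature
of environmental filtering.  On neutral data the same analysis returns SES
scattered around 0 with ~5% of cells significant.

The other scripts in `examples/` walk through gradient simulation, trait
spaces, FD/PD metrics, trend fitting and the packing decomposition; the
whole pipeline runs from one config via `ed.run_pipeline(...)` or the CLI:

```bash
elevdiv run-all --synthetic-n-species 60 --seed 5 --out out/
```

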