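# Methods notes

This note records the modelling assumptions, parameter choices and
numerical conventions behind `elevdiv`, in the places where the analysis
admitted more than one defensible design.

## Assemblage construction

Band intervals are half-open, `[lower, lower + width)`, tiling the gradient
without gaps; a record exactly on a boundary (e.g. 550.0 m) belongs to the
upper band.  A species belongs to every band its closed interpolated range
`[min_elev, max_elev]` intersects, which makes band occupancy contiguous by
construction — the `OccurrenceMatrix` constructor asserts this on every
build.  Ranges partly outside the gradient are clipped with a log message;
ranges entirely outside are dropped with a warning.  Elevation enters every
regression as the band's lower limit.

## Trait spaces

* Morphology: natural-log transform, then z-scores with the sample SD
  (ddof = 1) over the full species pool.  The log base only rescales
  z-scores, so the choice is inert; zero-variance traits are dropped with a
  warning.
* Fuzzy groups: Gower dissimilarity as half the Manhattan distance between
  proportion profiles, so each group spans [0, 1] exactly when rows sum
  to 1.
* Combined space: morphology distances rescaled to [0, 1] by their pool
  maximum; block weights rescaled iteratively (tolerance 1e-6, ≤ 100
  iterations) until each block's mean contribution `w_g · mean(D_g)` is
  equal, falling back to equal weights with a warning if balancing cannot
  converge (e.g. a block with zero variance).
* Ordination: classical metric scaling via scikit-bio's PCoA.  Axes with
  non-positive eigenvalues (possible for Gower input, which is not
  Euclidean-embeddable) are dropped without a Cailliez/Lingoes correction;
  the residual misfit is reported as MAD/RMSD instead of being absorbed
  into a shifted geometry.  PCA (scikit-learn, full SVD) is used for
  morphology, where it is the exact dual of PCoA on Euclidean distances.
* Retained axes: PCoA/PCA deviation is non-increasing in the axis count, so
  the quality-minimising m subject to a cap is the cap itself.  The
  pipeline caps m at min(6, minimum assemblage richness − 1): the richness
  bound keeps convex hulls defined in every band, and the ceiling of 6
  keeps hull computation stable and fast while ordination quality gains
  level off.  One *global* space per trait set is used for all assemblages,
  so FRic/FNND/FEve values are comparable across bands.

## Functional diversity

FNND is computed in the same ordination space as FRic and FEve for internal
consistency (a raw-distance variant is available through
`fnnd(dist=...)`).  Degenerate (affinely dependent) point sets break Qhull;
they are retried after a deterministic jitter of 1e-9 × coordinate range
drawn from the run's seed substream and flagged in the output.  In a
one-axis space the hull volume is the point range.  MST ties cannot affect
FEve (all minimum spanning trees share the same edge-length multiset), so
scipy's MST is used as-is; zero-length edges between coincident points are
restored explicitly before the evenness formula.  Metrics undefined for
small assemblages (S ≤ m for FRic, S < 2 for FNND, S < 3 for FEve) are
reported as NaN, never raised, because species-poor summit bands are a
legitimate feature of gradients.

## Phylogenetic structure

Polytomies are resolved randomly (seeded) with zero-length inserted
branches, leaving patristic distances unchanged.  Tips absent from the
species list are pruned; species absent from the tree abort with an
explicit list, because silently dropping them would corrupt the nulls.
For Blomberg's K the Brownian covariance V holds shared root-to-MRCA path
lengths; tips whose terminal branch is zero get a diagonal nudge of
1e-8 × tree depth so V stays invertible.  The permutation test is
one-sided (greater), since K values above 1 are the signal of interest, and
uses the add-one convention `p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1)`
(minimum attainable p is 1/(n_perm + 1); the default is 1000 permutations).

## Null models

Nulls randomise labels, never the occurrence matrix: whole trait rows
travel together across all blocks (preserving within-species trait
covariance), and one permutation per replicate is shared by all bands and
metrics, because a single trait shuffle defines every band's null value
simultaneously.  Tip-label shuffles use a separate seed substream.
Defaults: 500 replicates; significance by the empirical 2.5%/97.5% null
quantiles with linear (type-7) interpolation — the quantile rule, not the
SES value, makes the call.  A degenerate null (SD = 0) yields SES = NaN and
is significant only if the observed value differs from the constant.  If a
metric is undefined in more than half the replicates the cell is reported
as missing.

Calibration (recomputed by `scripts/acceptance.py` and the acceptance
tests): on neutral synthetic gradients, pooled SES of FNND has mean ≈ 0,
SD ≈ 1 and a two-tailed significance rate of ≈ 5%.  Within a *single*
dataset, significance calls are strongly correlated across bands — nested
assemblages share one pool trait configuration and one permutation stream —
so per-dataset significant fractions scatter widely around 5%; calibration
statements are about the average over replicate datasets.

## Segmented trends

The one-breakpoint model is fitted by iterative linearisation: regress y on
`{1, x, (x−ψ)₊, −I(x>ψ)}` and update ψ by the ratio of the indicator and
difference-in-slope coefficients until the step is below 1e-6 × x-range
(≤ 100 iterations).  ψ is clamped to [2nd smallest, 2nd largest] x — with
10 bands, anything beyond the penultimate point leaves a one-point segment
and an unidentified fit.  Per-segment slope t-values come from the
linearised fit's covariance (slope2 = slope1 + difference term).  The
Davies test evaluates the difference-in-slope Wald statistic at the
interior observed x values (8 candidates at the 10-band scale) and applies
the upper bound `p = 2·P(t_df > M) + V·(1 + M²/df)^(−(df−1)/2)/√(8π)`
with V the total variation of the statistic over the grid — the t-kernel
version of the classical Gaussian bound, which keeps the type-I rate at or
below nominal at n = 10 (measured ≈ 5% at nominal 5%).  Model selection is
exactly the Davies p < 0.05 gate; no information criterion is involved.
Undefined metric values are dropped pairwise before fitting.

## Niche packing / expansion

Volumes are raw hull volumes in the shared global ordination space of the
chosen trait set (percentages are scale-invariant).  "Contributes the most"
means the largest leave-one-out volume decrease; ties break
lexicographically by species id.  The loop stops at volume(A₁') ≤
volume(A₂) (equality stops it).  If unique species run out while A₁'s
volume still exceeds A₂'s — possible when the shared species alone span the
larger hull — the pair is reported as 100% expansion with an `exhausted`
flag.  Pairs with equal richness or undefined hulls stay in the output with
NaN percentages and a note.

## Synthetic data generator

The generator emulates the structure of a tropical-mountain bird survey:

* **Ranges** are (midpoint, extent) pairs: extents log-normal (median
  800 m, log-SD 0.6 — realistic elevational amplitudes for forest birds);
  midpoints follow a truncated-exponential density decaying with elevation
  at rate `richness_gradient` (default 1.5) per gradient span, drawn on the
  extent-extended domain `(lo − e/2, hi + e/2)` so that band coverage
  probability is exactly position-free at gradient 0 and declines
  monotonically otherwise.  With 100 species the default yields ~60 species
  in the lowest band falling to ~16 in the highest.
* **Phylogeny**: pure-birth (Yule) simulation run one extra exponential
  waiting time past the n-th speciation, so every terminal branch is
  strictly positive.
* **Morphology**: Brownian motion on the simulated tree (rate `bm_sigma`),
  exponentiated around plausible avian log-locations (≈ 30 g mass,
  15–80 mm lengths) with pool log-SD ≈ 0.4 — log-normal marginals carrying
  phylogenetic signal (mean Blomberg's K ≈ 1 by construction).
* **Fuzzy traits**: per-group Dirichlet draws with concentration 0.8 per
  axis — moderately sparse profiles, i.e. most species dominated by one or
  two diet items/strata/strategies, as fuzzy coding of real bird behaviour
  tends to look.
* **Scenarios** act on the morphological block in log/z space and map back:
  `filtering` pulls each species toward its home band's optimum (optima
  drift linearly along one random trait direction spanning ±1.5 SD);
  strength is the pull weight in [0, 1], with 0.8 the "strong" condition
  used in the recovery experiments.  `limiting_similarity` is Strauss-type
  thinning: while any co-occurring pair is closer than
  strength × median pool nearest-neighbour distance, one member is
  re-drawn from the pool distribution (iteration cap 50n); strength 2.0 is
  the strong condition.  `neutral` returns the input unchanged.

What the generator does **not** emulate: survey-method detection biases,
abundances, non-contiguous ranges, trait–elevation correlations outside the
scenario mechanism, and non-ultrametric trees.  Passing calibration and
recovery tests therefore demonstrates that the *statistical machinery* is
unbiased and directionally sensitive under known conditions — not that any
particular empirical gradient is driven by those mechanisms.

## Problem sizes

Defaults mirror the field scale the package targets (10 bands, 500 null
replicates, 1000 signal permutations).  The acceptance script and tests use
60–100-species pools, 100 replicate datasets for calibration, 200
Brownian traits for the K calibration and 1000 simulations for the Davies
type-I check — sizes at which the Monte-Carlo standard errors are well
inside the tolerances being asserted.

## Known limitations

* The group-balancing of the combined distance equalises *mean*
  contributions; it is not the full analytical weight solution that also
  balances correlation structure between blocks.
* Blomberg's K inverts V directly (O(n³) once per tree), fine for a few
  hundred tips but not for mega-trees.
* The Davies bound is conservative by construction; very weak breakpoints
  near the edge of the grid lose some power relative to an exact test.
* Hull-based metrics (FRic, packing) are limited to modest axis counts;
  the 6-axis ceiling is a pragmatic, documented cap.
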