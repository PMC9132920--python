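# Methods

This note documents the models and procedures implemented in `enmpipe`, the
conventions adopted where the underlying methods literature leaves choices
open, and what the synthetic-fixture tests do and do not establish.

## Taxonomic harmonization

A synonym table maps historical names (binomials or trinomials, normalized
to lowercase with collapsed whitespace) to accepted binomials; every
accepted name also resolves to itself, making resolution idempotent.
`update_name` resolves a (genus, species[, subspecies]) triple in three
steps:

1. an exact trinomial entry wins outright — this is the authoritative record
   of a subspecies elevated to species rank (e.g. a trinomial mapped to the
   elevated binomial);
2. otherwise the species (genus+species) and subspecies (genus+subspecies)
   are resolved separately; agreement, or a single resolution, wins. Two
   different accepted names trigger a per-component Levenshtein contest
   against each candidate, ties broken by fewer changed components then
   lexicographically, with the ambiguity reported so the record can be
   routed to manual checking;
3. names with no exact key fall back to a Levenshtein search over all keys,
   accepted only within a repair budget of a quarter of the name's length
   (at least 2 edits) — beyond that the name is reported as not in the
   table. Pure string distance cannot arbitrate a genuine taxonomic split,
   which is why exact table entries take precedence over edit distance.

## Dated-tree utilities

Patristic distance is the sum of branch lengths (My) along the unique path
between two tips. Tip grafting attaches a new tip on the sister's terminal
edge; the attachment point sits at `stem_fraction` (default 0.5) of the edge
measured from the tip, and the new tip's branch length equals the sister's
depth below the attachment. This preserves every pre-existing pairwise
distance exactly and keeps ultrametric trees ultrametric. The midpoint
default is a convention: the divergence time of a newly added taxon is
unknown, and the midpoint is the least-informative choice on the terminal
edge.

## Record–range reconciliation

Each record is joined to the up-to-20 nearest range polygons within 50 km,
the radius inclusive (a tie at exactly 50 km is in). Distances are geodesic
meters on the WGS84 ellipsoid: point-to-point via Vincenty's inverse
formula, point-to-polygon via a local equirectangular chart scaled by the
ellipsoid's radii of curvature at the record's latitude (error < 0.1% at
sub-100-km scales; verified against `geosphere::distGeo` and a densified-
boundary oracle in the tests). The decision cascade: expected species among
the candidates → unchanged (plus an outside-range flag if its distance is
positive); otherwise minimize patristic distance (ties at 1e-9 My are
"the same ancestor"), then geodesic distance; remaining ties → manual flag
with the name retained. Reassignments across more than 5 My also receive a
dubious flag. Records flagged manual/dubious/outside-range are excluded from
modeling. Records whose name is not a tree tip are flagged rather than
guessed; per-record failures degrade to manual flags so a batch never
aborts.

## Geometry

Chaikin smoothing replaces each ring edge with its `cut_ratio` and
`1 − cut_ratio` points (default 0.25, 3 iterations), doubling vertex counts
per iteration; holes are smoothed like shells. The concave hull maps a
concaveman-style `concavity` parameter (default 2.0, larger = simpler,
infinity = convex hull) to shapely's `concave_hull` ratio as `1 − 1/c`, and
falls back toward the convex hull if the concave result fails to cover every
point; species with < 3 usable points get 25-km geodesic point buffers
instead. M-areas union all ecoregions whose equal-area fraction covered by
the hull is ≥ 20%; fractions are computed in a cylindrical equal-area
projection on the authalic sphere because raw lon/lat areas are
latitude-distorted. The bias surface is a Gaussian product kernel over all
pooled records with a normal-reference bandwidth per axis
(`1.06·min(sd, IQR/1.34)·n^(−1/5)`), evaluated at cell centers of the
modeling grid, scaled by 1000 and rounded to three decimals. Rounding means
far-field cells are exactly zero; background weighting treats those cells as
unavailable.

## Maximum-entropy model

Features on background-scaled variables (min/max from the background sample
only; presences clamp into [0, 1]): linear, quadratic, pairwise products,
threshold steps at 10 interior knots `j/(n+1)`, and forward hinges
`max(0, (x−k)/(1−k))` at 10 knots `j/n` in [0, 1). Constant variables are
dropped with a warning. The objective is the penalized presence log-score

    −mean_p(f·λ) + log Σ_i w_i exp(f_i·λ) + Σ_j β_j|λ_j|,

with background weights `w` normalized to sum to one (bias-raster values,
normalized to mean 1, when a bias surface is supplied) and
`β_j = rm·σ_j/√n` — a deliberate simplification of the reference tool's
per-feature-class interpolation tables, which are not published. The convex
problem is solved in the split form λ = u − v (u, v ≥ 0) with L-BFGS-B,
restarting up to twice if the line search stalls, and declared converged
only when the L1 subgradient-optimality residual falls below 1e-6; a
closed-form two-cell fixture (λ = ln 4, raw = 0.8) pins the solution in the
tests. Entropy H is computed over the fitted training-background
distribution; raw scores over a prediction grid renormalize to sum to one
there; cloglog = `1 − exp(−e^H·raw)` and logistic = `e^H·raw/(1+e^H·raw)`.

Permutation importance permutes one variable jointly across presences and
background, re-expands features with the fitted scalers, and measures the
drop in training gain (mean presence log raw-score relative to the
background distribution), averaged over 5 repeats, clipped at zero, and
normalized to percentages. Training gain rather than AUC is used as the
yardstick; the two orderings agree on the planted fixtures, and gain is the
quantity the fit optimizes. VIF is 1/(1−R²) from OLS of each variable on
the others, `inf` for exact collinearity.

`select_variables` runs three phases: (1) drop zero-importance variables
under a default (lq, rm = 1) fit; (2) while max VIF ≥ 10, refit, take the
two highest-VIF variables and drop the one with lower permutation
importance — the loop acts even when only a pair remains, since otherwise a
collinear pair could never be resolved; (3) refit and drop variables under
1% importance, always keeping at least one. At a shadow correlation of 0.99
the driver/shadow decision approaches the statistical identifiability
limit; the recovery experiments use 800 presences, in line with per-species
occurrence counts typical of well-sampled taxa, and recover the true driver
in ≥ 90% of seeded replicates.

## Calibration and selection

Partitions: 5% of records (rounded) form an independent test set; if that
is fewer than 5 records the testing partition substitutes for final
evaluation (fallback rule). The rest are assigned to four spatial bins by a
two-level checkerboard — bin = 2·parity(coarse) + parity(fine) with
aggregation factors (2, 4) over the raster grid — one bin drawn at random
as the testing partition. 2000 background points are sampled uniformly over
valid cells (without replacement when possible); they serve evaluation and
partition geometry only, not fitting, which uses the full valid grid as its
background.

Candidates are the Cartesian grid of regularization multipliers ×
feature-class combinations × predictor sets in rm-major order. The full
published-scale grid is 17 × 29 × 3 = 1,479 specifications; source
descriptions of comparable pipelines cite roughly twice that number without
an identifiable extra factor, so the enumerator reports the grid size it
actually builds.

Partial ROC plots sensitivity against the proportion of background area
predicted present, restricted to sensitivity ≥ 1 − E (E = 5%), and the AUC
ratio divides the model's partial area by the diagonal's. Sensitivity uses
a plotting-position (rank/(n+1)) interpolated ECDF of the test predictions
anchored at the overall prediction range: with small resampled test sets
the raw step ECDF holds sensitivity at 1 over a finite area fraction, which
inflates the ratio above 1 for uninformative models; the interpolated curve
restores null calibration (noise ⇒ ratio ≈ 1, p ≈ 0.5) while leaving strong
models' ratios (> 1.5) intact. Each of 500 bootstrap replicates resamples
50% of the test points with replacement; p is the fraction of replicate
ratios ≤ 1, and "significant" means p < 0.05. The omission threshold is the
smallest calibration-presence prediction after discarding the lowest E
fraction; OR is the fraction of evaluation presences strictly below it.
AICc uses the log-likelihood of grid-normalized raw scores at the
presences with k = number of nonzero weights, undefined (candidate
excluded) when n ≤ k + 1.

Selection: significant → OR < 5% (falling back to the minimal-OR set when
empty) → within 2 AICc of the best survivor. The chosen specification is
refitted on 10 bootstrap resamples of the non-independent records; failed
replicates are dropped (an error if more than half fail); replicate
surfaces are averaged cell-wise on the cloglog scale — averaging raw scores
would let high-entropy replicates dominate after transformation. The final
model per predictor set is evaluated on the independent records, and the
overall winner minimizes OR, then maximizes AUC ratio, then (a tie-break
this package adds) prefers fewer nonzero parameters. Thresholding uses the
percentile (default 10th, linear interpolation) of training-presence
suitabilities, stepped down to the nearest order statistic whenever
interpolation would leave more than the nominal fraction of training
presences strictly below the cutoff — the bound, not the interpolation
formula, is the contract.

## Synthetic world

The default world is a 100×100 lon/lat grid (0.1°) with six layers: two
informative smooth Gaussian random fields, two shadows correlated at 0.95,
two noise fields; true suitability is `logistic(−0.5 + 2.5·z1 + 2.0·z2)` of
the standardized informative layers, so variable selection and model
recovery have a defined answer. Eight species get an ultrametric
coalescent-style tree (root depth 20 My), wobbly-circle ranges around
well-separated suitability peaks, and 150 records each sampled within their
range proportional to suitability — at the low end of per-species record
counts for well-sampled taxa. Contamination plants outdated names on 10% of
records (drawn from the generated synonym table, hence deterministically
fixable) and 5% cross-range mislabels (a record inside species T's range
relabeled as T's phylogenetically nearest neighbor, so the cascade has a
recoverable truth). A ledger stores every plant.

What the fixtures do not emulate: realistic climate covariance structure,
spatially autocorrelated sampling bias, coordinate errors (country
centroids, swapped signs), range overlap between close relatives, and
taxonomies deeper than one synonym per species. Passing recovery tests
therefore demonstrates that the algorithms implement their decision rules
correctly and recover planted structure under honest noise — not that any
particular real-world cleaning rate is to be expected.

## Problem sizes and runtime

The test suite and the acceptance script run on the default fixtures: the
100×100 world, 200–800 presences, a reduced 3 × 4 candidate grid, 300–500
pROC replicates, and 20-seed recovery loops. These sizes were chosen so a
full run of everything completes in a few minutes on a single core while
every statistic stays comfortably inside its asymptotic regime; all grids
and replicate counts scale up through configuration without code changes.

## Known limitations

- The L1 penalty uses a single analytic rule rather than the reference
  tool's empirical per-feature-class regularization schedule; absolute λ
  values differ from that tool even where rankings agree.
- Background for fitting is the full valid grid; for very large rasters a
  subsample would be needed.
- Geodesic point-to-polygon distance assumes polygons within a few hundred
  km of the record; antipodal geometries fall back to a spherical formula.
- No clamping/extrapolation diagnostics (MESS/MOP) and no categorical
  features.
- `aicc` evaluates the model fitted on the training partition at all
  non-independent presences; pipelines that refit on all records before
  computing AICc will produce slightly different values.
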