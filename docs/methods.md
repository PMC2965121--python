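# Methods

This note documents what `phylosoil` computes, the conventions it fixes
where the field's usage is loose, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducing a run.

## From census to traits

A stem census (species code, x, y in metres, dbh in cm) is overlaid on
gridded environmental layers with a common cell size (default 20 m, the
scale at which kriged soil maps for large census plots are typically
distributed).  Cells are half-open intervals `[i·s, (i+1)·s)` measured
from the plot corner; a stem sitting exactly on the far plot boundary is
clamped into the last cell, so every in-bounds stem lands in exactly one
cell.  How stems exactly on internal cell boundaries were assigned in the
original GIS workflows is generally unrecorded; the half-open rule is this
package's fixed convention.

Stems below the diameter threshold (default 1 cm, inclusive: kept when
dbh ≥ 1) are dropped.  Each remaining stem contributes the value of its
cell; stems in cells missing *any* requested variable are excluded
listwise, so a single per-species individual count describes every trait
column.  The species trait is the **median** across its stems' cell
values; even counts take the mean of the two middle order statistics.
Species absent from the phylogeny are kept in the trait table and dropped
only at tree–table reconciliation, so the overlay report stays
census-complete.

## Composite fertility axes

Skewed variables (default: extractable B, Ca, Cu, Fe, K, Mg, P and Zn,
plus elevation) are natural-log transformed — natural rather than base-10
log is a fixed convention; after standardization the choice only rescales,
not reorders.  Net nitrogen mineralization can be negative and is never
log-transformed.  Every layer is then z-scored (population SD) across its
non-missing cells, and the correlation matrix over complete cells is
eigendecomposed.  Cells missing any variable are deleted listwise.
Variance fractions are eigenvalue/p; each axis is oriented so its
largest-|loading| variable loads positively — PCA orientation is
arbitrary, and fixing it makes runs comparable (published loading tables
may differ axis-by-axis by a sign flip).  The observations are grid
cells, not field sample points, consistent with treating the axis scores
as map layers: the first `k` (default 3) axes are appended to the grid
and flow through stem extraction and species medians exactly like
measured soil variables.

## Contrasts and phylogeny-wide signal

Standardized independent contrasts are computed in one postorder pass:
at a bifurcation with child values x₁, x₂ on adjusted branches b₁, b₂,
the contrast is (x₁−x₂)/√(b₁+b₂), the node estimate is the
precision-weighted mean, and the node's own branch is lengthened by
b₁b₂/(b₁+b₂).  A polytomy yields **one** contrast (keeping
"one contrast per internal node" exact): children are ranked by value and
split at the median rank — the ⌊k/2⌋ lowest-ranked versus the rest, stable
sort breaking ties by input order — and the contrast is taken between the
precision-weighted group means, with group branch lengths combining
harmonically.  The split rule is isolated in one function
(`contrasts._split_polytomy`) so an alternative (e.g. sequential pairwise
contrasts) can be swapped without touching the engine.

Phylogeny-wide signal is the mean of |contrast| over all internal nodes.
Absolute rather than signed contrasts are used: signed means are ~0 by
construction under any sign convention, so the absolute mean is the
informative statistic; this choice is recorded in results metadata.  The
null is built from R (default 999) random reassignments of trait values
to tips; p values follow the (r+1)/(R+1) rule with ties counted as
extreme, so the smallest attainable p at R = 999 is 0.001 per tail and
the test is exactly valid.  A significantly *low* observed mean contrast
indicates conservatism.

## Blomberg's K

K is computed from the Brownian tip covariance V (shared root-path
lengths), exactly as in the README's formula: the observed MSE₀/MSE ratio
over its Brownian expectation.  Properties used as test oracles: K ≡ 1 on
equal-depth star trees for arbitrary data; K is invariant to affine trait
transforms and to global rescaling of branch lengths (branch-length units
of the input tree are therefore irrelevant and are consumed as given); K
averages 1 over Brownian simulations.  Significance is a permutation
test on K itself: the two-tailed p doubles the smaller (r+1)/(R+1) tail
and caps at 1.  Whether published K p values were derived from K itself
or from contrast variances is often unrecoverable; the K-based null is
this package's documented choice.  A zero-length internal branch makes V
singular; a ridge of 1e-8·mean(diag V) is added and flagged in the
result.  Zero-length *terminal* branches are rejected at parse time
(they would divide by zero in contrast standardization); zero internal
branches are legal because collapsing them is how polytomies arise.

## Node-specific tests

For each internal node two observed statistics are computed from the
species trait values: the **tip average** (unweighted mean over subtended
species) and the **ancestral average** (recursive equal-weight mean over
immediate daughters, branch lengths ignored — the classic nodes-as-units
correction for uneven clade sizes; the exact definition is isolated in
one routine since the field's usage varies).  Both statistics are linear
in the tip values, so one shared stream of R tip shuffles — shared across
nodes and both methods, making node results comparable within a run —
reduces the whole test to two matrix products.

Tail p values use (r+1)/(R+1) with ties extreme; equality is judged with
a relative tolerance of 1e-9 so that permutation-invariant statistics
(the root's tip average) report exactly p = 1 despite float
summation-order jitter.  Significance is p ≤ α per tail (inclusive,
α = 0.05 default — borderline-α results count as significant).  No
multiple-testing correction is applied; the number of tests performed is
recorded so users can apply their own.

Reporting filters, each configurable:

1. **Both-methods rule** (default on): a node is reported only when the
   tail is significant under both averagings.  This is never less
   conservative than tip-only reporting (tested property).
2. **Rare-species dependence**: a significant node containing a species
   with fewer than `min_individuals` (default 5) stems is flagged; for
   each such species the test is re-run with that species removed
   (re-pruned tree, same R and seed), and the node is excluded if the
   significance does not survive any removal.  Simple exclusion of every
   node containing a rare species would be too blunt — real analyses
   retain nodes whose signal is robust to 1-individual members — so
   fragility, not mere presence, is the exclusion criterion.  Both the
   flag and the verdict are reported.
3. **PCA high tail only** (default on): low-tail records for PCA-axis
   traits are suppressed from report tables (a low composite-fertility
   score has no tolerance interpretation) but retained in the full
   results object.

The null permutes traits across tips, which ignores spatial
autocorrelation of the underlying stems; a torus-translation or other
spatially aware null is out of scope, and this limitation should be kept
in mind when interpreting borderline nodes.

## Synthetic data

The generator produces the joint structure the analysis assumes, with a
known ground truth:

* **Tree**: pure-birth (Yule) process run to n tips, one extra
  exponential wait so terminal branches are positive, depth normalized
  to 1.  Internal branches shorter than ε can be collapsed into
  polytomies (depths preserved) to exercise the polytomy path.
* **Optima**: Brownian motion on the tree (rate σ², default 1 on the
  depth-1 tree, so optima span the standardized landscape).  A planted
  clade — the node whose tip count is nearest a requested size — can be
  shifted by a stated offset, giving a known-positive node for power
  studies.  A null variant shuffles optima across species, destroying
  conservatism while preserving marginals.
* **Landscape**: a few latent white-noise fields smoothed by a Gaussian
  kernel (bandwidth in cells, default 3), mixed with random weights plus
  smoothed independent noise; each variable is affinely rescaled so its
  min/max match the calibration range of the corresponding published
  variable (15 defaults spanning Mehlich-3 extractable elements,
  nitrogen, pH, elevation, slope).  An affine map cannot match a mean
  and both endpoints simultaneously, so ranges are matched exactly and
  means land near mid-range.  Default extent 50 × 25 cells of 20 m
  (a 1000 m × 500 m, 50-ha plot).
* **Stems**: a Thomas-type clustered process.  Parent points (default 5
  per species) land in cells with probability ∝
  exp(−(z−optimum)²/2τ²) on the standardized driver layer; stems
  scatter around parents (Gaussian SD 30 m, redrawn when outside the
  plot).  Abundances are lognormal, realized multinomially to the exact
  stem total (default 20,000).  dbh is truncated lognormal
  (log-mean 0.9, log-SD 1.0, minimum 1 cm), putting ~90% of stems below
  10 cm as in dense tropical censuses.  Clustering parameters are stated
  defaults, not calibrated to any particular plot.

Habitat filtering acts on a single designated driver variable per
scenario so planted signal stays interpretable; other variables receive
signal only through landscape cross-correlation — deliberately mimicking
the correlated-soil-variable caveat of real plots.  What the generator
does **not** emulate: real spatial covariance structure of soils, dispersal
limitation, species-specific size distributions, demographic turnover, or
plant feedback onto soil.  Passing calibration tests on these data shows
the statistics behave correctly under the stated model, not that any
particular field dataset satisfies that model.

## Problem sizes and calibration checks

The test suite verifies, among others: contrast-engine equivalence with
an independently coded brute-force recursion (1,000 random trees, n ≤ 8,
atol 1e-9); exact-enumeration permutation probabilities on a 4-tip
example (phylogeny-wide p_low = 2/6; one cherry's p_high = 1/6) against
Monte-Carlo at R = 999; K = 1 on star trees to 1e-9; mean K within
[0.85, 1.15] over 200 Brownian simulations on 50-tip Yule trees and
uniformity of its two-tailed p under exchangeable traits (KS, 500
replicates); node-test type-I rate within [0.03, 0.07] over 200 null
scenarios of 32 species and 2,000 stems; and ≥ 80% detection of an
8-species clade shifted +3 SD (τ = 0.25, 64 species, 20,000 stems, 100
replicates).  `scripts/acceptance.py` recomputes the same headline
quantities at slightly smaller replicate counts (100 Brownian trees, 50
null scenarios, 30 power replicates), chosen as comfortable desk-scale
sizes with stable estimates.

## Degenerate inputs and edge rules

* Trees: exactly one root, ≥ 2 tips, unique labels, finite non-negative
  branch lengths; Newick branches without lengths default to 1.
* Constant traits: K and standardization are undefined → explicit errors.
* Pruning suppresses unary nodes, summing branch lengths; reconciliation
  of tree and trait table requires ≥ 2 shared species and is idempotent.
* Tip label matching is exact and case-sensitive (species codes are
  identifiers, not names).
* All randomness flows through seeded `numpy` generators; every result
  object records its seed and R, and a fixed pipeline seed yields a
  byte-identical output directory.
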