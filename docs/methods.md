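# Methods

This note documents the models, the numerical choices, and the design
decisions behind `exprevo`, in the order the pipeline runs.  It also
states what the synthetic generators emulate — and what they do not —
so that it is clear what a passing test suite does and does not say
about real data.

## Synthetic data (`exprevo.synth`)

**Gene families.** A family evolves along a dated, ultrametric species
tree by a branch-wise Gillespie process on gene lineages with per-MY
rates of duplication, loss, and retrotransposition.  A
retrotransposition is modelled as a duplication whose new copy loses
all introns and relocates to a random chromosome; the copy is flagged
so that truth branch categories distinguish the retrocopy branch (R)
from its sister (D).  Speciation nodes copy every surviving lineage
into both descendant species branches.  Families whose copies all die
return an explicit extinct signal rather than raising.  Lineages
compound (a duplicated copy can duplicate again), so event counts are
linear in the rates only while `rate × tree length` is small; the
linearity test uses rates ≤ 1e-3/gene/MY for that reason.

**Expression.** Six-organ log₂ expression evolves by the exact OU
transition `x' ~ N(θ + (x−θ)e^{−αt}, σ²(1−e^{−2αt})/2α)` applied
branch-wise, with the root drawn from the stationary distribution
around the root optimum.  Shifts are planted at branch starts with
per-category probabilities; the targeted organ is drawn from the
propensity row of the current regime's primary-expressed organ, gets a
positive optimum jump of about `shift_size_sd`, and the other organs
get small `N(0, (shift_size_sd/4)²)` perturbations, making the shift
joint across organs as the detector assumes.  Defaults — α = 0.05/MY
(phylogenetic half-life ≈ 14 MY), σ² = 0.3 (stationary SD ≈ 1.2 log₂
units), shift size 4 log₂ units, per-branch shift probabilities
0.30/0.09/0.02 for R/D/S — were chosen once as a regime with strong
stabilising selection and well-separated regimes; no published
duplication/retro or shift-size rates exist to calibrate against, so
these are test-power choices, not empirical estimates.

**Samples.** Each project spans all six organs; a sample's log value is
the organ truth mean plus a per-(project, gene) batch offset plus iid
noise; the FPKM variant is additionally scaled by a per-sample
lognormal library factor.  Anomalous projects keep their measurements
but have organ labels cyclically permuted.  Per-branch ω values are
drawn lognormally around a median that is higher on D/R branches and
higher again on shifted branches.

**What the generators do not emulate:** sequence evolution, read-level
noise, organ-specific α/σ² correlations between organs, expression
measurement error that depends on expression level, gene-tree
estimation error (topologies are true by construction), or the
free-text metadata problems of public archives.  Tests passing on
these inputs show the estimators are correct under their assumed
model, not that the assumptions hold for any particular real dataset.

## Amalgamation (`exprevo.amalgam`)

* **TMM.** Factors are computed on the single-copy-ortholog subset of
  the FPKM table against a reference sample (the column whose 75th
  percentile is nearest the mean 75th percentile).  M values are raw
  log₂ ratios (not library-normalised — the point is to capture the
  sample's overall scaling bias), trimmed 30% per side; A values
  trimmed 5% per side; weights are delta-method inverse variances
  treating values as Poisson intensities.  Factors are normalised to
  geometric mean 1 and divide the sample's values.  Fewer than 20
  usable genes in any sample (configurable) is an error.
* **Log transform** is log₂(x+1); figures of the underlying analyses
  are log₂-scaled, so "log(N+1)" is read as base 2.
* **Curation.** Each sample is correlated with every organ's
  leave-own-project-out mean profile; a sample violates if its
  same-organ correlation is not strictly greater than every other
  organ's (ties count as violations).  One project is removed per
  iteration — the one with the most violating samples, ties broken by
  violating fraction, then by smaller project id — until no violations
  remain.  When a project is the only source for an organ the mean
  falls back to leave-self-out.  Fewer than two projects skips
  curation entirely.
* **Batch correction.** A two-pass residual-PCA surrogate-variable
  scheme: fit per-gene organ means, take residuals, and keep leading
  right singular vectors while their *variance fractions* exceed the
  95th percentile of row-permuted residuals (20 permutations).  Raw
  singular values cannot be compared directly: residualisation
  confines the observed variance to a rank-(n−k) subspace and inflates
  every observed singular value over its permuted counterpart, which
  would select all dimensions.  Surrogates are orthonormal and lie in
  the residual row space, hence exactly orthogonal to the organ
  design: removal provably leaves per-gene organ means untouched (the
  protection property the tests assert).  Because effective correction
  removes within-organ variance, variance-ratio statistics such as an
  organ F necessarily *increase*; preservation is of means, not F.

## Rooting and dating (`exprevo.treetime`)

Nodes are classified duplication (D) iff their child subtrees share
species, else speciation (S); S nodes map to the species-tree MRCA of
their species set.  Every branch is scored as a candidate root by
LCA-reconciliation duplication–loss cost (dup 1.5, loss 1.0), and
midpoint and minimal-ancestor-deviation (MAD) candidates are computed
alongside.  The final root is the MAD root if it is DL-minimal, else
the midpoint root if DL-minimal, else the DL-minimal candidate
topologically nearest the MAD root (ties: lexicographically smallest
bipartition).

Dating fixes S-node ages to species-tree ages and brackets each D node
between the oldest fixed age among its nearest descendant S nodes
(0 if none) and its nearest ancestral S node's age (1105 MY — the
animal–fungi split — when the root is a duplication with no ancestral
speciation).  Free ages minimise
`Σ_b (ℓ_b − r_{c(b)} t_b)² / max(ℓ_b, 1e-6)` over node ages and
per-category clock rates (default one category = strict clock; with
more categories, branches are binned by depth and a smoothing penalty
shrinks rate spread), solved by SLSQP under ordering and bracket
constraints from a feasible postorder start.  With every node fixed
the rates are solved analytically per branch.  Infeasible brackets are
widened by 10% of the species-tree root age per step, at most 5 steps,
then dropped; the ladder is logged in the dating report.  Ages are
measured backwards from tips at 0; output branch lengths are MY.

## Shift detection (`exprevo.oushifts`)

**Skimming.** Maximal clades in which all tip pairs have Pearson
correlation of their six-organ profiles above 0.99 are collapsed to a
single tip carrying the clade's Brownian-motion GLS root estimate;
zero-variance profiles compare equal (r := 1) only when elementwise
identical.  The collapsed tip keeps the clade root's label, so shift
branch ids remain comparable across differently skimmed versions of
the same tree.

**Design.** With the root treated as stationary, the tip covariance is
`V_ij = (1/2α) e^{−α d_ij}(1 − e^{−2α t_ij})` (σ² factored out) and a
shift on branch b contributes `1[b ancestral to i](1 − e^{−α(T −
t_start(b))})` — the shift sits at the branch start, so the branch's
category is that of the branching event that precedes it.  The cap on
shift counts is `⌊max[min(N/2, 100), √N]⌋`, overridable per family.

**Search.** Per organ, the single-regime ML fit profiles θ₀ and σ² in
closed form and maximises over α on a 32-point log grid spanning
phylogenetic half-lives from 0.1% to 1000% of tree depth, refined by
bounded scalar optimisation.  Each organ's data and the full candidate
design are whitened by the Cholesky inverse of its V(α̂); a group
lasso (groups = the six organs' coefficients of one branch) is run
down a 50-value geometric λ path from λ_max to 0.001 λ_max by a
numba-compiled block coordinate descent (pure-python fallback), with
early stop once the active set exceeds the cap (smaller λ only grows
it).  Every distinct support along the path is refit by unpenalised
GLS with α re-optimised per organ on the cached grid, and scored by

AICc = −2ℓ + 2p + 2p(p+1)/(n−p−1) + 2|S| ln B,

with p = 3·6 + 6|S| parameters over n = 6N observations and B the
number of candidate branches.  The last term prices the *position* of
each shift, selected among B branches (an MDL / uniform-model-prior
argument).  Without it, plain AICc admits a spurious shift whenever
the best of ~B correlated χ²₆ improvements beats a fixed 6-df penalty,
which happens in roughly a quarter to a third of no-shift trees at
N = 64 — the familiar anti-conservativeness of AICc in lasso-based
shift selection.  The term is the package's default df convention and
can be disabled (`position_penalty=False`) to recover the plain
count.  Ties in AICc prefer smaller supports, then lexicographic
branch ids.  A backward pass drops any shift whose removal lowers
AICc, to a fixpoint; AICc is monotone non-increasing along accepted
steps by construction.

**Consensus** intersects the shift branch sets detected on the two
expression metrics and reports Venn counts; branches collapsed away by
one metric's skimming simply cannot be consistent.

## Annotation (`exprevo.annotate`)

Intron counts are collapsed to a binary character (intronless /
intron-containing) with loss 1e-3 and gain 1e-4 per gene per MY;
chromosomes {autosome, X, Y} evolve by a symmetric 1e-3 rate.  Both
use matrix exponentials of the rate matrix over branch durations (ε =
1e-9 MY for zero branches), marginal posteriors by the inside–outside
form of the pruning algorithm with a stationary root prior (uniform
available via config), and missing tips marginalised.  Node-level
stochastic mapping draws joint histories for transition localisation.
A duplication-descended branch is R when the MAP intron state flips
containing → intronless across it with both endpoint posteriors above
0.5; if both children qualify, only the stronger intronless posterior
is the retrocopy, the sister stays D.  Note the rates-to-zero limit
with discordant tips yields a 50/50 root posterior — the stationary
prior cancels exactly against the first-order transition
probabilities — whereas the no-information limit that recovers the
prior is long branches; the tests assert both.

## Propensity statistics (`exprevo.propensity`)

τ, TEC and PEO are computed on unlogged optima (2^x − 1, clamped at
0); Δμ_max stays on the log scale.  TEC is defined as `1 − Σ min(p, q)`
on sum-normalised vectors, which reproduces the stated endpoints
(0 overlapping, 1 mutually exclusive); PEO ties exclude the record
from PEO analyses (counted).  Sister pairs where both branches shifted
are excluded from ω comparisons (no clean baseline); the ±5%
"undifferentiated" band applies to the raw ω ratio, regressions use
log₂ ratios with slope t-tests, split by the sign of Δτ and Δμ_max.
The Brunner–Munzel test delegates to scipy; with fewer than 10 values
per side, or under complete separation (where the t approximation
degenerates), it falls back to a flagged permutation test on the
relative effect.

Permutation enrichment of a PEO transition matrix shuffles the
multiset of derived labels against the fixed ancestral labels
(preserving both margins exactly, per draw); identity pairings land on
the ignored diagonal.  Per-cell two-sided p =
`2 min(P(null ≥ obs), P(null ≤ obs))` with the (b+1)/(n+1) correction;
Benjamini–Hochberg across the 30 off-diagonal cells is optional and
off by default.  Global polarity is `Σ_{i<j}|N_ij − N_ji| / Σ N_ij`
(the scaled sum of opposite-shift differences; the scaling is this
package's definition), with bootstrap over individual switching
records and two-sided Kolmogorov–Smirnov comparisons between category
bootstrap distributions.

## Pipeline (`exprevo.pipeline`)

Stages run simulate → amalgamate (per species, per metric; TMM only
for FPKM) → optional re-dating → shift detection per metric →
consensus → annotation → statistics, with per-family error isolation
and per-stage seeds derived as `crc32(global_seed:stage:item)`, so
reruns are byte-identical.  Gene ids are family-qualified
(`fam0001:sp03_g2`) because tip labels repeat across families.  JSON
outputs use sorted keys; TSV columns are fixed-order with 10
significant digits.

## Problem sizes used in the operating-characteristic tests

The simulation-based tests run at sizes chosen to give stable pass/
fail behaviour with commodity compute: detector calibration and power
use 50 no-shift and 50 planted-shift trees of 64 tips (one planted
joint shift of 4 per-organ stationary SDs; consensus of two
measurement replicates with 0.25 log₂-unit noise); parameter recovery
uses 100 replicates at 128 tips; curation calibration uses 100
replicates of 4-project designs; permutation calibration uses 500 null
matrices of ~150 records at 999 permutations; propensity recovery uses
50 runs of 600 switching shift records with three 3-fold-enriched
cells at 9,999 permutations.  The propensity-recovery check generates
shift records directly from the generator's propensity mechanism; the
detection chain that would produce such records at scale is validated
separately by the calibration/power test.

## Known limitations

* α and σ² are global per organ; branch- or clade-wise heterogeneity
  and within-species variance are out of scope by design.
* The stationary-root design nearly confounds the root optimum with a
  shift on a root-child branch; such shifts are reported but their
  placement between the two root children is weakly identified.
* The dating objective is a weighted least-squares surrogate for
  penalized likelihood (alignment lengths are unavailable to form a
  Poisson likelihood); with a strict clock and exact constraints it
  recovers simulated ages to well under 2%, but rate-category
  smoothing is heuristic.
* The curation rule needs an informative gene panel; with only a
  handful of genes per species the leave-project-out correlations are
  dominated by noise and entire species can be discarded.
* Retrotranspositions of originally intronless genes are undetectable
  by construction (no containing → intronless transition exists).
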