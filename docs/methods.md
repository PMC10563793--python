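# Methods

This note documents the models and procedures the package implements, the
choices made where the underlying problem left the design open, and what
the synthetic-data generator does and does not emulate.

## Duplicate classification

Genes are classified from two inputs: a paralog-pair table carrying an
estimated duplication node (last common ancestor) per pair, and a gene
table carrying chromosome, order index, intron count and an optional
macrosynteny-segment assignment.  All positional rules are stated in gene
counts (order indices), not base pairs.

**Ohnolog (WGD) pair calling.**  Pairs linking two distinct macrosynteny
segments are grouped by the unordered segment pair they link, sorted by
anchor position on one segment, and chained greedily while the number of
genes strictly between consecutive anchors is ≤ `max_gap` (default 8) on
*both* segments; chains of ≥ `min_block` (default 3) pairs are called.
Design choices where the rule is under-specified:

* "genes separating" means genes strictly between anchors;
* the gap constraint applies to consecutive anchors on both segments (not
  to all anchor pairs of a block);
* crossed (inverted-order) chains are allowed — strand and orientation are
  ignored.

A brute-force enumerator over all contiguous anchor windows guards the
greedy implementation in the validation suite; the two agree exactly on
random instances because every valid window is contained in a maximal
greedy run.

**Retroduplication.**  A would-be SSD pair is retro when one member has 0
introns and the other ≥ 3, or when one member has 0 introns, the other
< 3 and there is no conserved microsynteny (another pair linking the ± 5
gene neighbourhoods of both members; the tested pair itself never counts,
neighbour pairs may share a member with it).  Intron gain is never
inferred.  The screen is applied only to pairs not already called WGD or
pre-vertebrate.

**Pair-label precedence** (the sources leave this implicit):
PRE_VERTEBRATE (node at or older than the vertebrate ancestor) → WGD →
RETRO → SSD.  Gene labels follow from pair labels: WGD iff all
vertebrate-lineage pairs are WGD, SSD iff all are SSD, SINGLETON iff none
exist (subtyped by whether pre-vertebrate paralogy exists), EXCLUDED for
retro-pair membership (which outranks) or mixed WGD/SSD membership.

**Majority vote.**  The consensus over three ohnolog data sets is any
label held by ≥ 2 of them; three-way disagreement yields
EXCLUDED/NO_MAJORITY (configurable).  In the per-data-set summary table,
"presumed SSD pairs" counts the vertebrate-lineage pairs that are neither
WGD, retro nor pre-vertebrate — i.e. the pairs actually used as SSD
evidence — so the three excluded/SSD rows partition the non-WGD pairs
exactly.

## Derived features

* **τ (tissue specificity)** is computed on raw TPM without any floor,
  ceiling or log transform; development stages are treated as additional
  tissues.  An all-zero profile has undefined τ (missing, logged); a
  single-condition matrix is an error.
* **Duplicate age** is the oldest duplication node in the gene's
  vertebrate family (transitive closure over vertebrate-lineage pairs),
  in units of 50 MY (configurable).  Singletons get a *missing* age, not
  0, so they can never leak into age regressions.  WGD genes take ages by
  the same family rule as SSD genes.
* **GC3** is the percent G+C at third codon positions; a trailing partial
  codon is dropped with a warning and `N` bases are excluded from both
  numerator and denominator.
* Where a feature differs between transcripts, the longest transcript is
  used, ties broken by lexicographically smallest transcript id.

A default node-age table ships with the package (Chordata 550, Vertebrata
530, Euteleostomi 430, Tetrapoda 350, Amniota 310, Mammalia 180, Primates
75, Homininae 9 MY) and is overridable everywhere it is consumed.

## Group statistics

Direct class comparisons are two-tailed Mann–Whitney U tests; the
Bonferroni family is all tests performed in the call (configurable).  A
feature constant across both groups yields p = 1 rather than an error.

The age/type regressions fit OLS `feature ~ age + type` per feature.  The
response transformation is selected among none / log / Box–Cox by the
lowest Jarque–Bera statistic of the model residuals (the normality target
is configurable to raw values).  The Box–Cox exponent is chosen by profile
likelihood over the interpretable grid λ ∈ {−2, −1.5, …, 2}: with a
continuous λ estimate, log-scale data gives λ̂ ≈ 0 and the log and Box–Cox
candidates differ only by sampling noise, making the selected *label* a
coin flip; on the grid, λ̂ = 0 makes the Box–Cox candidate identical to
the log transform and the tie resolves deterministically to the simpler,
earlier candidate.  Candidates requiring positivity are skipped with a
warning when non-positive values are present (no automatic shift).  The
age × type interaction is kept iff it lowers AIC by ≥ 2 units.

Residualization for the age-controlled classifier uses untransformed
features (`feature ~ age` by OLS); residuals are numerically orthogonal to
age (checked to 1e-10).  Age regressions cover duplicates only, since
singletons have no age.

## Importance protocol

The duplicate-type classifier is a random forest (balanced class weights,
default 39 trees — the tuned value; 100 before tuning) fitted on complete
cases over repeated simple-random 80/20 splits (not stratified).  Held-out
accuracy is recorded per iteration and permutation importance is the
held-out accuracy drop on permuting one feature, one permutation round per
iteration by default (iteration count supplies the averaging; rounds are
configurable).  All feature × round permutations are stacked into a single
model prediction per iteration, which computes the identical quantity much
faster than per-permutation predictions.  Aggregates: mean/s.d. of
importance, mean rank, mean accuracy with a normal-approximation 95% CI
over iterations, and confusion matrices normalized per column (precision)
and per row (recall).  The whole protocol is deterministic given the
master seed (per-iteration seeds are drawn from it).

Hyperparameter tuning is a randomized search (n_estimators, max_features,
max_depth, min_samples_split, min_samples_leaf, bootstrap) with 10-fold
CV maximising binary F1 with the minority class as positive label
(configurable); candidate grids are the usual forest grids.

The dependence matrix fits, per feature, a random-forest regressor from
all other features on an 80/20 split and reports held-out R² plus
per-predictor permutation importances, clipped to [0, 1].

The isolation analysis reruns the full protocol for each member of a
correlated feature group with the other members dropped; the new rank is
the insertion position of the isolated mean importance into the original
ranked list.  Because both runs share the master seed, the accuracy
comparison is paired over identical splits.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* ohnolog families (2 genes each) laid out as anchor chains of ≥ 3
  linking pairs between paired segments on two chromosomes, anchor gaps
  drawn from 0–3 (within the ≤ 8 rule), so the block caller recovers them
  exactly; fewer than three requested families is a sizing error because
  no valid block can be formed;
* retro pairs made by copying a parent with ≥ 3 introns to a random free
  location with 0 introns, with no surrounding microsynteny;
* SSD families placed outside segments with duplication nodes strictly
  inside the vertebrate lineage; remaining genes are singletons, a few of
  which optionally carry pre-vertebrate-only pairs;
* three ohnolog replicate sets that share the non-WGD pair universe and
  independently drop/add pairs at the configured noise rate (only WGD
  membership is perturbed — the axis on which published ohnolog sets
  actually differ);
* per-class Gaussian or log-Gaussian feature distributions with
  configurable location shifts, an optional shared latent factor for
  correlated feature groups (loading 1 gives exact copies), and an
  optional age confound mixing standardized duplicate age into designated
  features at a configured correlation;
* a TPM expression matrix with broad, high expression for WGD genes,
  broad moderate expression for singletons and narrow expression for SSD
  genes, from which τ and maximum expression are computed downstream.

What it does **not** emulate: nucleotide evolution (CDS sequences are
random, so dN/dS-like columns are surrogate draws, and GC3 on simulated
CDS is ≈ 50%), physical coordinates, bounded score supports (pLI-like
columns are unbounded Gaussians), GO structure (annotations for
enrichment tests are random flat sets), and any between-dataset structure
beyond independent noise.  Passing tests therefore demonstrate the
correctness and calibration of the *procedures*, not biological effect
sizes.

## Validation studies

`duplicability/validation.py` fixes the designs used by the test suite and
the reproduction script.  Effect sizes and sample sizes were chosen once
for statistical power (the underlying comparisons publish no effect
sizes): e.g. the age-confound study plants five correlated length-like
features (3 σ shift, pairwise r ≈ 0.64), two independent informative
features (1.6 σ), one age-only feature (r = 0.99 with age, no class
shift) and two noise features over ~150 genes per class, and runs the
protocol at 20 iterations × 3 permutation rounds over 100 seeds; the
null-calibration study uses label shuffles of a signal-free data set, with
chance compared at the binomial scale of the data-set size (iterations
reuse the same genes and are not independent draws); the enrichment
calibration uses a 4 000-gene universe with 40 terms of 200–1 000 genes so
the discrete hypergeometric p-values are dense enough for their sub-0.05
mass to sit near 0.05.  Problem sizes keep each study to minutes on one
CPU.

## Known limitations

* Block assembly is greedy after sorting on one segment; pathological
  instances where skipping an anchor would rescue a longer chain are
  resolved in favour of the contiguous reading (guarded by the oracle
  test, which shares that reading).
* The enrichment stand-in (two-sided hypergeometric, doubled smaller
  tail, BH-FDR) is not the external g:SCS procedure; published enrichment
  percentages are not expected to reproduce exactly.
* `majority_vote` resolves tied exclusion reasons in favour of the retro
  reason; consensus subtypes take the majority subtype.
* The Mann–Whitney implementation delegates to SciPy; exact small-sample
  p-values follow SciPy's method selection.
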