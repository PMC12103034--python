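# Methods

This note records the models, parameter choices, numerical conventions
and limitations behind `coexsig`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic cohorts

The generator (`simulate.py`) draws from a latent single-factor model per
module: module *m* has one eigengene value per sample, e_{m,s} ~ N(0, 1),
shifted by `effect_delta` (default 2 latent SD) for affected samples when
*m* is a disease module.  A member gene with loading a_g (drawn uniform
from `loading_range`, default 0.6–0.9) carries the log2-scale signal
a_g·e_{m,s} + √(1 − a_g²)·ε, so the latent gene–eigengene correlation is
exactly a_g; grey genes are pure noise.  One eigengene per module is
deliberate: the downstream classifier operates on first principal
components, so this makes ground truth for eigengene recovery exact.

On top of the signal the expected count receives:

- gene length (FPKM's target) and a baseline abundance spread
  (`base_log2_sd` = 1.5 log2 units);
- a per-sample quadratic GC bias with sample-specific random coefficients
  (`gc_bias_sd` = 0.5 log2) — exactly the artifact the CQN-style
  correction is meant to remove;
- gene-specific sex and batch offsets (log2 SDs 0.2 and 0.3), plus an
  XIST-like female-high marker gene and four Y-like male-high markers for
  the sex QC check;
- a log-normal library size (σ = 0.2) around 2×10⁶ reads.

Counts are negative binomial with variance μ + μ²·`nb_dispersion`.  The
dispersion default is 0.01 and represents *technical* overdispersion
only: biological variability is already modelled explicitly by the
log-scale latent layer, so a typical "biological" dispersion here would
double-count it.

**Library share.**  Real transcriptomes have ~15,000 expressed genes of
which any module is a small fraction of sequencing depth; a 500-gene
miniature in which 300 module genes carried most of the reads would make
total-count normalization feed each module's own signal back into every
gene (self-normalization) far beyond anything seen at real scale.  The
grey genes therefore stand in for the background transcriptome:
`module_library_share` (default 0.10) fixes the expected fraction of the
library carried jointly by module genes, with scaling constants computed
from cohort-average abundances so genuine per-sample composition
fluctuations survive, damped to realistic size.

Affected samples are partitioned into `n_families` families (default 7
families for 11 cases, matching the cohort design the package targets);
controls are attached to case families cyclically, as unaffected
relatives.  Companion datasets reuse the gene→module map and loadings for
a chosen subset of modules and scramble all others into independent
noise, which is the ground truth the preservation statistics are tested
against.

What the generator does *not* emulate: isoform structure, read-level
error, gene–gene correlation beyond the single factor per module,
abundance-dependent dispersion trends, and population structure beyond
the family labels.  Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical model, not performance on any
real cohort.

## Normalization

Stages are strictly ordered and tagged: raw → log2fpkm → normalized →
residualized.  Genes with zero counts in **all** samples are removed (a
per-any-sample rule would discard most genes in sparse data).  log2 FPKM
uses a 0.5 pseudocount and the per-sample total count as library size.
The GC/length correction fits, per sample, an OLS regression of
expression on a centered quadratic in GC fraction plus log10 length and
subtracts the fitted effect while preserving the sample mean; this keeps
the contract of conditional-quantile normalization (remove
sample-specific GC/length trends, then quantile normalize) in a
transparent, testable form rather than re-implementing the full
conditional-quantile machinery.

Full quantile normalization (the default second step) assumes most genes
do not vary in a coordinated way between samples.  At miniature scale —
modules making up half of a 500-gene universe — that assumption fails
badly: forcing identical per-sample distributions makes coordinated
module shifts nearly zero-sum across the remaining genes and induces
artificial negative correlation between modules.  `cqn_like_normalize`
therefore takes `quantile=False` for recovery experiments on small
simulated universes; real-scale data should keep the default.

Covariate cleanup is per-gene OLS on indicator-coded sex/batch, returning
residuals plus the gene's grand mean.  Note an estimator property that
matters for truth-recovery experiments: regressing q design columns out
of n samples removes, in expectation, q/n of *any* latent factor's
variance (its chance projection onto the design), with substantial
seed-to-seed spread at n ≈ 46.  On real data this trade is worthwhile
because the covariate artifacts are real; in a simulation where recovery
is measured against known latent factors it biases the measurement, so
the canonical recovery scenario evaluates the network on the detrended
stage.  Surrogate-variable correction is intentionally out of scope.

Outlier detection standardizes sample connectivity k_i = Σ_j ((1 +
cor_ij)/2)² and flags Z.k < −2.5 — a conventional, testable rule chosen
because published exclusions rarely state one.

## Network construction

Unsigned adjacency |cor|^β with Pearson correlation throughout (the
common default; signed networks and biweight midcorrelation are not
implemented).  The soft power is chosen as the smallest β whose binned
log10(freq) vs log10(k) fit reaches signed R² ≥ 0.8 **and** whose mean
connectivity stays ≥ 1.  The connectivity floor is load-bearing: at high
powers the connectivity of any dataset, including pure noise, is
dominated by each gene's single largest correlation, whose heavy tail
mimics a scale-free fit, but the resulting network is degenerate (mean
k ≈ 0).  An explicit override power is always accepted (the blood-network
convention is β = 4).

TOM uses the standard shared-neighbor formula; correctness is pinned to a
brute-force triple-loop oracle at 10⁻¹² and to the closed form that a
uniform adjacency *a* yields TOM = *a*.

**Dynamic tree cut.**  The implementation makes the usual "hybrid"
contract explicit and fully deterministic:

1. *Static cut* of the average-linkage dendrogram just below the top
   (99% of the maximum merge height) yields candidate clusters.
2. *Gap-gated recursive splitting*: a cluster splits into its two
   children when both hold ≥ `min_module_size` genes and the merge gap
   (node height minus the taller child, as a fraction of the dendrogram
   height range) reaches a deep-split-dependent floor (0.27, 0.2025,
   0.135, 0.0675, 0.0375 for deep_split 0–4, derived from the published
   core-scatter ladder).  Because a higher deep_split only lowers the
   floor, the module count is non-decreasing in deep_split by
   construction.
3. *kME refinement* (hybrid method, when expression is supplied): every
   gene is iteratively reassigned to the module whose eigengene it
   correlates with most, or to grey when that correlation is below 0.4.
   The floor sits ≈ 2.5 null standard deviations above chance correlation
   at the cohort sizes the package targets (1/√45 ≈ 0.15), so genes
   attached to a branch only by sampling luck are shed while true members
   with loadings ≥ 0.6 are retained.  Without expression, unassigned
   genes are pulled in by mean-TOM proximity only.  `method="tree"` skips
   stage 3 for oracle testing.

Labels are renumbered by decreasing module size with ties broken by the
smallest member index, so runs are bit-reproducible; module merging by
eigengene dissimilarity (1 − cor < cut height) recomputes eigengenes
after each merge and relabels by size.

## Eigengenes and statistics

Eigengenes are the first right singular vector of the standardized module
submatrix, scaled to unit variance (ddof = 1) and sign-flipped to
correlate non-negatively with mean standardized module expression, which
makes results invariant to gene order and SVD sign.  Variance explained
is s₁²/Σs².  Per-module gene means/SDs, the left singular vector and
scale factors are retained so out-of-cohort samples can be projected onto
training eigengenes (≤ 5% missing genes allowed, dot products
renormalized by the retained squared loading mass).  By default,
validation samples are analyzed jointly with the cohort; projection is
the alternative for true out-of-cohort use.

Hypergeometric overlap and enrichment use the upper tail including the
observed count.  The enrichment universe is a parameter (all expressed
genes vs all network genes give different answers, and published analyses
rarely state which was used).  The differential-expression step is a
deliberately simple per-gene Welch t with Benjamini–Hochberg correction —
a stand-in whose only pipeline role is to produce a DE flag for
enrichment statistics on synthetic data; it is not a count-model DE
method.

## Classifier

The one-sample t-test is taken as two-sided with a direction gate: the
worked per-patient probabilities in the source analyses read a small p as
disease-consistent, which only fits "sample differs from controls", and
the gate prevents calling samples that deviate *away* from the patient
mean.  The combination rule is OR — the signature behavior (sensitivity
non-decreasing, specificity non-increasing as modules are added) is
asserted per replicate in the acceptance suite.  The combination search
ranks subsets by specificity first, then sensitivity, then size,
mirroring a biomarker-development preference for few false positives.

The decision tree is a transparent CART-style fit: Gini impurity,
deterministic midpoint thresholds, at most one split per module, depth
≤ 2, leaf ties toward control.  It replaces an external decision-tree
package whose Bayesian-network machinery is out of scope.

Confidence intervals are exact Clopper–Pearson (Beta quantiles); this
convention was verified against all printed interval brackets it is meant
to reproduce.  Percentages are rounded half away from zero to integer
percent.  Family-level sensitivity counts a family positive iff any
affected member is positive; family-level specificity, when requested, is
computed over families with no affected members and errors on a zero
denominator rather than report an undefined rate.

A note on operating characteristics: because the t statistic scales the
deviation by the standard error (sd/√n) of the control mean, the
rejection region at α = 0.05 and n = 35 controls begins ≈ 0.34 control-SD
from the control mean.  The analytic specificity of a single module on
controls drawn from the training distribution is therefore Φ(0.34) ≈ 63%,
not 1 − α; the acceptance suite checks the simulated specificity against
this analytic value, and the calibrated sensitivity against the analytic
rejection power.

## Preservation

The published preservation suite is reduced to a defined 3-statistic
composite: density (mean intra-module adjacency in the test data, β = 4
by default) and two connectivity statistics (correlation of intra-module
connectivity profiles between datasets; correlation of the upper-triangle
gene–gene correlations).  The permutation null redraws gene sets of the
module's size from the shared universe without replacement (seeded;
default 50 permutations, seed 1).  Zsummary = (Z_density +
Z_connectivity)/2 with Z_connectivity the mean of the two connectivity
Zs; Zsummary ≥ 2 is preserved.  A statistic whose permutation
distribution is numerically constant carries no information — e.g. both
connectivity correlations are identically 1 when the test data are the
reference data — and is excluded from the composite; it is an error only
when every statistic degenerates.  Cross-species ortholog mapping is out
of scope: the caller supplies a pre-mapped shared universe.

## Acceptance problem sizes

The canonical recovery scenario is the generator default at seed 1
(modules of 120/100/80 genes + 200 grey + 5 sex markers, 11 cases / 35
controls), evaluated on the detrended stage with β = 4; recovery metrics
(adjusted Rand index, eigengene correlations) vary by a few points across
generator seeds, and the canonical seed makes the check deterministic.
Classifier calibration uses 500 latent-level cohorts of 11 vs 35 with the
disease shift solved analytically for 75% rejection power — the test
concerns the rejection region of the t rule, so simulating the count
layer would only add noise around the same comparison.  Preservation
discrimination uses 50 replicate companion datasets at 50 permutations
each.  These sizes keep the default suite in the low minutes on one CPU.

## Known limitations

- Blockwise construction is not implemented; networks above a few
  thousand genes are quadratic-to-cubic in memory and time.
- The tree-cut variant, while contract-equivalent and monotone by
  construction, is not a line-for-line port of the published dynamic
  hybrid cut; branch-by-branch agreement with it is not guaranteed.
- Quantile normalization's zero-sum artifact at small gene universes is
  inherent to full QN, not removed — only documented and avoidable via
  `quantile=False`.
- The Welch-t DE screen is not a substitute for count-based differential
  expression on real data.
- Reported results that depend on external cohorts (cross-disease
  preservation z values, specific module gene lists, per-patient match
  probabilities) are outside what synthetic data can reproduce; the
  package validates the rules and statistics that produce such numbers,
  not the numbers themselves.
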