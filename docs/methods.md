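# Methods

## Study design the package models

Two tissues (pancreatic islets and liver) are profiled from the same
animals in a two-diet longitudinal design: high-fat diet (HFD) vs chow
(CD), six time points on a 4-week grid (weeks 4–24), four replicate
animals per diet × week cell, one sample per tissue per animal.  That
gives 48 paired subjects.  Traits are endpoint measurements per animal
(insulin-secretion parameters from glucose-tolerance testing, liver
enzymes, lipids), each annotated with a category so selection rules can
address "the insulin-secretion parameters" as a group.

## Normalization and filtering

Counts are normalized by median-of-ratios size factors: the reference
profile is the per-gene geometric mean over samples, computed over genes
with no zero count; a sample's size factor is the median ratio of its
counts to the reference.  Values become `log2(count / size_factor + 1)`.
Log base 2 with pseudocount 1 keeps fold changes on the reporting scale
used downstream.  Gene filtering keeps genes with at least `min_count`
(default 5) in at least `min_samples` (default 2) samples, optionally
followed by a top-k-by-variance cut on the log scale.  Gene ids are
opaque case-sensitive strings throughout — no annotation lookup, so the
package is independent of any genome release.  Missing trait values are
kept as missing and handled pairwise in the regressions; imputation
would invent data.

## Differential expression

Per (tissue, week) stratum: Welch's unequal-variance *t*-test per gene
on log2-normalized values, two-sided, with Welch–Satterthwaite degrees
of freedom, then Benjamini–Hochberg adjustment across genes within the
stratum.  A gene is a DEG when adjusted *p* < α (default 0.05) and
|log2FC| ≥ 1 (configurable).  A Welch test rather than a count GLM keeps
the stage transparent and dependency-light; the validation targets are
calibration (null rejection ≈ 5%) and recovery of planted effects, both
of which the Welch test meets at the simulated depths.  Degenerate
inputs: two constant groups with equal means give *t* = 0, *p* = 1;
constant groups with unequal means give *p* = 0 with a warning.
Cross-week overlap is computed by exact inclusion–exclusion over all
week subsets; region counts always sum to the union size.

## Co-expression networks

Per tissue, on all samples jointly (both diets, all weeks — a consensus
network over conditions):

* Pearson correlation between genes; zero-variance genes are an error
  (the filter should have removed them).
* Soft power β: for each candidate (1–20), compute unsigned adjacency
  |r|^β, connectivity k_i = Σ_j a_ij, bin log10(k) into 10 bins, and
  regress log10 p(k) on log10 of the bin-mean k.  The fit r² counts only
  when the slope is negative; the smallest β reaching r² ≥ 0.80 wins.
  When no candidate reaches the target — common on strongly modular
  synthetic data, whose degree distribution is bimodal rather than
  scale-free — the fallback is the historical default β = 6, with a
  warning.
* TOM: `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
  computed on a zero-diagonal adjacency, unit diagonal by convention.
* Modules: average-linkage hierarchical clustering of 1 − TOM with a
  static cut at 0.90 × the tallest merge height.  Clusters smaller than
  `min_module_size` (default 30) become unassigned.  A static cut is
  fully specifiable and deterministic, unlike the dynamic hybrid cut;
  the cost is that module counts are not comparable to dynamic-cut
  analyses, and that large noise clusters can survive the cut (the
  min-size rule is the guard; residual background genes attaching to
  real modules are tolerated and measured by the recovery benchmarks).
* Labels are M1, M2, … by decreasing size, ties broken by the
  lexicographically smallest member gene; genes are re-ordered
  canonically before clustering, so the partition is invariant to input
  order.
* Eigengenes: genes are z-scored across samples (ddof = 1), the module
  eigengene is the first right singular vector of the module block,
  scaled to unit variance and oriented so the mean member kME is ≥ 0.
  Variance explained is s₁²/Σs².
* Merging: modules whose eigengene dissimilarity 1 − cor falls below
  0.25 (average linkage) are unioned, labels recomputed, eigengenes and
  kME refitted.

The `CoexpressionNetwork(...).fit()` model object chains these steps and
returns the partition, eigengenes, membership matrix, and the power fit
table.

## Module–trait regression

One ordinary-least-squares fit per (module, trait): eigengene as the
dependent variable, z-scored trait as the independent variable, on the
subjects with a non-missing trait value (subjects, not samples, are the
unit — each subject has one eigengene value per tissue).  The *p*-value
is the standard *t*-test on the slope; *r* is the sample correlation.
Traits with fewer than 3 non-missing values yield missing cells, not
errors.  No multiple-testing correction is applied across the
module × trait grid by default (the common practice for module–trait
screens); a BH option exists.  Selection rules: a module is "of
interest" for a category when its count of traits with *p* < α in that
category reaches `min_hits` — islet preset 1 ("any one insulin-secretion
parameter"), liver preset 6 ("more than five").

## Cross-tissue integration

The combined coefficient of an (islet module, liver module) pair is the
membership-weighted mean of absolute cross-tissue correlations (formula
in the README).  Design choices:

* |r| by default, so anti-correlated modules also pair; a signed mode
  keeps raw r (where positive and negative correlations cancel).
* Weights are own-module kME clipped below at zero — a gene
  anti-correlated with its own module should not carry weight in its
  module's pairing — and the score is invariant to positive rescaling
  of the weights and to gene relabeling.
* Tiers: strong C > 0.4, moderate 0.35 < C ≤ 0.4, strict at both
  boundaries.  With all-zero weights on either side the score is
  undefined and reported missing with a warning.

"Correlation to a partner module" for key genes is read as correlation
with the partner module's eigengene (default); the alternative reading
— mean correlation to the partner module's genes — is implemented as
`partner_mode="mean_gene"` and agrees closely on coupled modules (the
eigengene is, up to noise, the weighted mean profile).  Key-gene
thresholds are membership > 0.9 and |partner correlation| > 0.5.

The secretome filter is an ordered intersection of liver DEGs with the
user's secreted-protein list.  Candidate ranking scores each secreted
liver DEG by |cor| with the first principal component of the islet DEG
block across paired subjects; it stands in for commercial
knowledge-base network scoring, which is out of scope.

## Enrichment

One-sided hypergeometric tail P(X ≥ k) per gene set, with the
expression-filtered gene universe of the relevant tissue as background
(an expression-aware background, not the whole annotation).  Sets are
intersected with the universe first; empty sets are skipped; BH across
tested sets.  The temporal heatmap takes each week's top-N sets by raw
*p* (the heatmap intensity convention), unions rows across weeks, fills
cells with −log10 raw *p* (untested or *p* = 1 → 0), and orders week
columns by average-linkage clustering on Euclidean distance, leaves in
dendrogram order.

## Synthetic data generator

The generator is first-class, tested code; its defaults encode the
design above (2 diets × 6 weeks × 4 replicates = 48 paired subjects).

Counts: negative binomial via gamma–Poisson with a log2 link,

```
log2 mean = baseline + factor_scale · loading · f_m(subject)
            + DE shift + N(0, noise_sd)
mean      = 2^(log2 mean) · depth(sample)
```

* baselines per gene ~ U(3, 9) on the log2 scale (≈ 8–512 expected
  counts), `factor_scale` = 3 log2 units per unit latent factor,
  per-sample depth ~ log-normal (sd 0.15 in ln units) so the
  normalization stage has real work to do;
* module factors f_m ~ N(0, 1) per subject; a coupled (islet m, liver
  m′, ρ) pair shares a latent z with islet factor z and liver factor
  ρz + √(1−ρ²)ε, making ρ the factor-level cross-correlation;
* per-gene loadings ~ U over the configured range; the key-gene preset
  additionally plants "hub" genes (20% of coupled-module members with
  loadings in [0.95, 1.0] against a [0.35, 0.55] body) because a kME
  threshold of 0.9 at n = 48 can only separate loading groups that are
  far apart — the sampling sd of a correlation near 0.9 (~0.03) maps to
  a loading blur of ~0.15;
* DE effects are diet-specific log2 shifts (random sign) on chosen
  genes from a start week onward, drawn from background genes when
  available so planted modules stay clean;
* traits are loading × driving-factor + Gaussian noise per subject, or
  pure noise for null traits;
* one global seed feeds a fixed set of named `SeedSequence` spawn
  streams (baselines, loadings, factors, noise, counts, depth, traits,
  DE selection), so changing the gene count does not perturb trait
  noise, and identical configs are bit-identical.

The matched null generator keeps the marginal count model and removes
every planted effect (no modules, no coupling, no DE; module-driven
traits become noise).

What the generator does *not* emulate: realistic library sizes or gene
counts (tens of thousands), mean–variance trends fitted to real data,
compositional effects, batch structure, gene–gene correlation beyond
the single-factor module model, or annotation-linked gene identity.
Passing benchmarks therefore demonstrate that the statistics recover
the planted generative structure under calibrated noise — not
performance on any particular real dataset.

## Benchmarks and problem sizes

The recovery/calibration benchmarks (`modlink.benchmarks`, rerun by
`scripts/acceptance.py`) use: 2,000 genes per tissue with 8 modules of
80–300 genes for module and coupling recovery (one network fit per
tissue, ~3 s each); planted-partition scoring for the 10-seed coupling
check so the pairing statistic is isolated from module detection;
2,000-gene null datasets for DE calibration (10 seeds); and the small
demo configuration (600 genes) for the double-run determinism check.
These sizes were chosen to give stable Monte-Carlo estimates on a
single CPU in about two minutes.

## Known limitations

* The static tree cut makes module counts incomparable to dynamic-cut
  WGCNA runs and admits occasional background clusters of size ≥
  `min_module_size`.
* The scale-free fit rarely succeeds on strongly modular synthetic
  data; the β = 6 fallback is then the operative default.
* Module–trait regressions are univariate and cross-sectional; no
  longitudinal or mixed-effects modeling of the week structure.
* The combined coefficient compresses a module pair's full cross-
  correlation block to one number; anti-correlated sub-blocks are
  indistinguishable from correlated ones in the default absolute mode.
* Enrichment assumes exchangeable genes within the universe; no
  gene-length or expression-level bias correction.
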