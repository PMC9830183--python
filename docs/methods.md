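# Methods

`socortex` implements a cross-species transcriptomic meta-analysis for
detecting a conserved "genetic toolkit" — a set of orthologous genes whose
expression consistently separates reproductive from non-reproductive
phenotypes across several species of social insects. This note documents the
models, the synthetic data the package validates itself against, and the
numerical choices a maintainer would want to know about.

## Input model and preprocessing

The common currency of all stages is an orthogroup × sample count matrix.
Orthogroups are consumed in the OrthoFinder `Orthogroups.tsv` dialect and
filtered with a relaxed near-single-copy policy: at most 3 gene copies per
species and absence in at most 1 species (both configurable). Multi-copy
genes within a species are collapsed by summation by default — summing
preserves library-size accounting, whereas taking a maximum or mean would
distort size-factor estimation. Orthogroups absent in a species carry NaN and
are excluded row-wise from cross-species statistics rather than zero-imputed
(zeros would fabricate expression evidence).

Normalization follows the negative-binomial variance-stabilization approach:

1. **Size factors** are median-of-ratios: `f_j = median_g(c_gj / geomean_g)`
   over genes expressed in every sample, with a ratio-of-totals fallback
   (plus a warning) when no such gene exists.
2. **Dispersion trend.** Per-gene method-of-moments dispersions
   `α̂ = (s² − μ)/μ²` are computed on normalized counts — in species-aware
   mode as a sample-size-weighted average of per-species estimates, so that
   cross-species mean shifts do not masquerade as biological dispersion.
   Estimates are floored at 1e-6 (negative values are sampling noise under
   weak overdispersion) and a robust trimmed least-squares fit of `α̂` against
   `1/μ` yields the parametric trend `α(μ) = a0 + a1/μ`, with `a0` the
   asymptotic dispersion and `a1` the extra-Poisson term.
3. **Closed-form VST.**
   `g(q) = log2((1 + a1 + 2 a0 q + 2 √(a0 q (1 + a1 + a0 q))) / (4 a0))`,
   the antiderivative of `1/√(q(1 + a1 + a0 q))` up to scale: square-root-like
   where shot noise dominates (`a0·q ≪ 1`) and `log2`-like with unit slope at
   large counts. If the fitted `a0` is non-positive the transform falls back
   to `log2(q + 1)` and says so.
4. **Center-scaling** (for the classifier): per-gene mean 0 / sd 1, globally
   or within species; constant rows are set to 0 and flagged.

"Species awareness" is deliberately exposed at two points — trend fitting on
within-species moments and per-species centering — because controlling for
species can reasonably mean either; both default to on for the pipeline.

## PCA trait screen

A sample-space PCA (full SVD, deterministic sign convention: the
largest-|loading| gene of each component is positive) is screened for Pearson
correlation between the top components (default 10) and clade, species, and
phenotype. Multi-level traits are coded one-vs-rest, reporting each PC's best
coding; integer coercion of factor levels is available behind a flag but
rejected as the default because it imposes an arbitrary level order.
Benjamini–Hochberg correction is applied jointly across all (PC, coding)
pairs. The randomized-phenotype control shuffles labels *within species* —
preserving the phylogenetic signal under the null so the test isolates
phenotype — and reports where the observed max |r| falls in the null
distribution. The "variance accounted for by a trait" summary is defined as
Σ explained-variance-fraction × r² over significantly correlated PCs.

## SVM recursive feature elimination

For each focal species the remaining species form the training set
(leave-one-species-out). The classifier is a C-SVM with radial kernel; a full
grid search over gamma ∈ {1e-7, 1e-6, 1e-5} and cost ∈ {8, 16, 32} is scored
by stratified 3-fold cross-validated misclassification (seeded folds; ties
broken toward smaller cost, then smaller gamma). Misclassification fraction
is used as "error rate" throughout: for hard 0/1 predictions it coincides
with a squared-error rate. Feature weights are
`w_g = Σ_i (α_i y_i) x_{i,g}` — the dual-coefficient / support-vector matrix
product, exact for linear kernels and applied as the standard ranking
heuristic for the radial kernel. Elimination removes exactly one gene per
step (the smallest |w|; ties broken by lexicographically smallest id),
re-tunes, and records CV and held-out-species test error from `n_genes` down
to the floor + 1 (the floor-size set terminates elimination unfit). A
configuration option removes the bottom q% per step for large gene sets;
q = 0 is the default.

The best model minimizes the cross-validated training error, with ties
broken toward the smallest gene set (the parsimony convention for recursive
elimination). Selection deliberately never consults the focal-species test
error: that error is recorded per step for diagnostics and serves as the
*unbiased* observed statistic of the label-shuffle randomization test
(default 100 shuffles),
`p = (1 + #{null error ≤ observed}) / (n + 1)`. Selecting on the test error
instead would make the randomization test anti-conservative, since the
observed error would be a minimum over the whole elimination trace evaluated
on the same few test samples. The best model's gene set is the focal
species' predictor set. Predictor sets are
intersected across focal species; the all-species intersection feeds the
toolkit. Lineage-restricted runs (bees-only, wasps-only) use the same
machinery on a species subset.

## Consensus co-expression networks

Per species: adjacency `|cor|^β` (or signed `((1+cor)/2)^β`), with β chosen
as the smallest value in 1..20 whose scale-free fit reaches median R² ≥ 0.8
across species, else 6. Topological overlap is

`TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`.

Per-species TOMs are quantile-calibrated (95th percentiles matched to the
first species — without calibration one dataset's scale dominates a minimum)
and combined by a component-wise quantile, default 0 = minimum: only
co-expression present in *every* species survives. Modules come from
average-linkage clustering of `1 − TOM` with a static cut at 0.995 × the
maximum merge height and a minimum-size filter swept over 30 → 20 → 10
(relaxation); the static cut replaces the dynamic hybrid tree cut, which is
out of scope — consequently module boundaries are blunter than the reference
implementation's and the cut height is exposed as a parameter. Labels are
deterministic: size-ranked, ties broken by smallest member id; 0 =
unassigned.

Module eigengenes are first principal components of standardized module
expression per species (unit variance, oriented so mean gene–eigengene
correlation ≥ 0); kME is gene–eigengene correlation. Trait association uses
a sample-size-weighted Stouffer meta-analysis over species:
`z_s = atanh(r_s)√(n_s − 3)`, `Z = Σ w_s z_s / √(Σ w_s²)`, `w_s = √n_s`.
A gene is *trait-associated* when (i) its own phenotype meta-p, (ii) its
module eigengene's meta-p, and (iii) its kME meta-p all pass BH at α = 0.05
— the strict conjunctive reading; the reported set is the union over the
size-relaxation sweep. Module preservation is a permutation Z on mean
intramodular consensus kME against same-size random gene sets.

The resampling null shuffles phenotype labels within species, rebuilds the
entire network and trait screen, and records the proportion of the
point-estimate gene set recovered, k times (default 1000; the worked examples
and tests use 50–100). Two p-values are reported: the literal two-tailed rule
(share of resamples whose proportion deviates from the 50% null expectation),
which degenerates to 1.0 when all null proportions sit at zero, and the
conventional exceedance `p = (1 + #{proportion ≥ observed}) / (k + 1)`.

## Differential expression

Per species, a from-scratch NB regression: log-link mean with size-factor
offset, gene-wise dispersion by Cox–Reid-adjusted profile maximum likelihood
on a 60-point log-grid with parabolic refinement (method-of-moments
fallback at the boundary), and a Wald test on the phenotype coefficient with
expected-information standard errors. No fold-change shrinkage, independent
filtering, or outlier replacement — divergences from the reference DE
framework that are deliberate; correctness is asserted by calibration (type-I
error within [0.03, 0.08] at n = 6+6) and power simulations rather than
output equality. A joint clade-adjusted model (intercept + clade + phenotype)
guards against clade-confounded phenotype imbalance. Unequal group sizes are
handled by permutation balancing: subsample the larger phenotype to the
smaller one's size, re-test, and retain genes significant in ≥ 50% of
subsamples (threshold configurable). Cross-species overlap is exact set
algebra keyed by orthogroup.

## Integration

The putative toolkit is `SVM ∩ WGCNA` (all-species predictor intersection ∩
union of trait-associated genes over the size sweep); differential-expression
overlaps are reported alongside, with every percentage recomputed from the
stored sets and an explicitly named denominator. Term enrichment is plain
per-term one-sided Fisher/hypergeometric testing over a user-supplied
gene → term map, restricted to terms with ≥ 5 annotated background genes,
BH-corrected; the background defaults to all analyzed orthogroups (the
tested universe), not a genome.

## Synthetic data: what it emulates and what it does not

The generator draws NB counts
`NB(mean = lib_j · exp(base_g + clade_gc + species_gs + loading_g · factor_j
+ effect_gj), Var = μ + α_g μ²)` with:

- 6 species in 2 clades, 3–12 samples per phenotype per species (default 8+8);
- log-uniform library sizes in [0.5, 2];
- per-gene species shifts (sd 1.0, natural log) and clade shifts (sd 0.5) —
  the dominant phylogenetic signal the PCA screen should find;
- gene-wise dispersions log-normal(ln 0.2, 0.5) around the range typical of
  individual-level insect brain RNA-seq;
- a **continuous reproductive state** per sample: the 0/1 phenotype plus
  Gaussian noise (sd 0.35). Toolkit, clade-restricted, and trait-module
  effects respond to the state, not the label. Castes in rudimentary
  societies are plastic and physiologically overlapping; this term produces
  the irreducible classification error without which every classifier is
  perfect and model selection over the elimination trace is vacuous;
- a planted toolkit (default 40 genes, log2 effect 1.0–1.5) with
  sign-consistent effects in all species; clade-restricted effect genes; and
  latent-factor modules (loadings ±[0.5, 1], factor sd 1) of which a subset
  tracks phenotype via a shifted factor mean.

Gene roles are disjoint by default so recovery scoring is unambiguous
(a flag allows overlap). What the generator does **not** emulate: read-level
artifacts (mapping, GC, length biases), phylogenetic covariance of expression
evolution along branch lengths, orthology errors, and batch structure within
species. Passing tests therefore demonstrate that the pipeline recovers the
structure this model plants at desk scale — not that it would recover
toolkits from arbitrary real data.

## Problem sizes and determinism

The validation suite runs the full study at 300 genes, 40 toolkit genes,
8+8 samples per species, an SVM floor of 20, and the 30/20/10 module sweep —
sizes chosen so a complete 5-seed study finishes in minutes on one CPU while
every stage still has realistic granularity (the elimination trace has 280
steps; focal test sets have 16 samples). The full-scale defaults (floor
100, resampling k = 1000) remain the package defaults for real data.

All randomness flows from explicit seeds; per-stage seeds are derived from
the global seed by hashing the stage name, so adding a stage never shifts
another stage's stream, and the full pipeline is byte-identical under a fixed
seed (checksummed manifest). Correlations are clipped to ±0.999999 before
Fisher's z; SVM fold assignment is seeded; module labels, eigengene signs,
and elimination tie-breaks are all deterministic by construction.

## Known limitations

- The static tree cut under-segments weakly separated modules compared with
  the dynamic hybrid algorithm.
- Wald tests are anticonservative below ~5 samples per group (type-I ≈ 0.11
  at 3+3); the permutation-balancing wrapper inherits this at its subsample
  size.
- The radial-kernel feature weights are the linear-kernel formula applied as
  a heuristic; rankings are meaningful, magnitudes are not.
- With strong planted signal the elimination trace can tie at zero error over
  wide ranges; selection then falls to the documented tie-break rather than
  the data.
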