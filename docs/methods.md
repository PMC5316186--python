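# Methods

`stagedyn` analyzes a four-stage tumor-progression RNA-seq design: tumor and
age-matched control mammary tissue sampled at weeks 6, 8, 10 and 12, three
replicates per cell, corresponding to hyperplasia, adenoma/MIN, early
carcinoma and late carcinoma in the MMTV-PyMT mouse model of breast cancer.
This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Filtering and normalization

A gene is called transcriptionally inactive and removed when its counts per
million (CPM, count × 10⁶ / column sum of the raw matrix) fall below 1 in
strictly more than half of the samples. "More than half" is read literally
(strictly greater than n/2; 3 of 6 samples retains the gene), and library
sizes are taken before any gene removal, so the filter is idempotent. The
filter is applied globally across all 24 samples; a per-stage variant is a
configuration away but not the default, because the inactive-gene notion is a
property of the experiment, not of one contrast.

Size factors are the classic median-of-ratios estimator: with geometric mean
g_i of gene i across samples over genes with no zero count,
s_j = median_i (x_ij / g_i). When no gene is all-positive the estimator fails
loudly with a pointer to a pseudo-count fallback rather than silently
applying one. Normalized expression is x_ij / s_j; the log view is
log2(x/s + 1). The pseudo-count of 1 is the conventional choice for
count-scale data and is configurable; nothing downstream depends on its
exact value beyond low-count genes.

The qPCR utility implements relative quantification,
fold change = 2^−[(Ct_target − Ct_reference)_case − (Ct_target − Ct_reference)_control],
with *Actb*-style reference genes supplied by the caller.

## Per-stage differential expression

Each week is a two-group (3 tumor vs 3 control) negative-binomial comparison
in the classical conditional exact-test formulation:

- Counts are equalized to a common effective library, x_ij × geomean(s)/s_j
  ("pseudo-counts"). Group totals are rounded half-up to integers because
  the conditional distribution lives on integer splits.
- A common dispersion φ̂ is estimated by maximizing the summed NB
  log-likelihood across genes with each group's mean profiled out, with a
  Cox–Reid adjustment (−½ log of the Fisher information of each profiled
  mean, n_k μ/(1+φμ)). The adjustment matters: with 2 + 2 residual degrees
  of freedom the unadjusted profile likelihood underestimates φ by roughly
  a third, which propagates into an inflated type-I error (~0.08 at nominal
  0.05 in our calibration runs). With the adjustment, recovery is accurate
  (φ̂ ≈ 0.100 at true 0.1, 2000 genes) and the null p-value distribution is
  calibrated.
- Per-gene dispersions are method-of-moments estimates,
  φ_g = Σ(n_k−1)(s²_k − m_k) / Σ(n_k−1)m_k², shrunk toward φ̂ with a prior
  weight of 10 pseudo-genes (a convex combination weighted by residual df),
  clipped to [0, 10].
- Conditional on the total s of both groups' rounded pseudo-counts, the
  probability of a split (a, s−a) is proportional to
  C(a+r₁−1, a) · C(s−a+r₂−1, s−a) with r_k = n_k/φ — the common mean cancels.
  The two-sided p sums the probabilities of all splits no more likely than
  the observed one. At φ = 0 this reduces exactly to the two-sided binomial
  test with success probability n₁/(n₁+n₂), which is the oracle used in
  tests. For s above a cap (default 5000) a normal approximation with
  conditional mean sπ and variance v₁v₂/(v₁+v₂), v_k = n_k(μ̂+φμ̂²), plus a
  continuity correction is used; it agrees with enumeration to ~10% near
  the cap, where p-values are already far from any decision boundary.
- log2 fold change = log2((mean₁+c)/(mean₂+c)) with prior count c = 0.5 so
  zero counts give finite estimates.
- Benjamini–Hochberg adjustment is applied within each stage (the analysis
  reports per-stage DEG lists); a gene is a DEG when |log2FC| > log2(2) and
  FDR < 0.05. Both thresholds are configurable.

Cross-stage accounting reports the 15-cell Venn partition of the four DEG
sets, the union, the all-four intersection and its fraction of the union,
and per-stage up/down counts.

## PCA and covariate association

Sample PCA runs on the log2(normalized+1) values of the top-variance genes
(library default 500; the pipeline raises this to 2000 so that the 1000
trend genes below all carry loadings), with per-gene centering and SVD. A
deterministic sign convention (each loading vector sums to ≥ 0, ties broken
by the first nonzero loading) makes outputs platform-reproducible. Covariate
association regresses each of the top PCs' scores on each known covariate:
simple linear regression with a slope t-test for continuous covariates, and
one-way ANOVA for categorical ones (the categorical treatment was an open
choice; ANOVA is the natural F-test generalization of "linear regression"
to factors). Entries are −log10 p; single-level covariates are reported as
0 with a degeneracy flag.

## Transition-pattern classification

For genes with all four stage contrasts (default: the union of all per-stage
DEGs), the log-ratio change over transition i is LRC_i = R^(i+1) − R^(i),
i = 1..3, where R^(i) is the stage-i log2 fold change. The triple telescopes
to R^(4) − R^(1) exactly. Each LRC column is z-scored across genes and
trinarized: +1 if z ≥ τ, −1 if z ≤ −τ, else 0. τ defaults to 1.0 SD — the
"deviance from the mean" cutoff is not prescribed anywhere, and 1 SD
reproduces the qualitative behavior that the large majority of genes are
all-constant. z-scoring is per transition column (the three transitions have
different spreads); a pooled mode exists. The 27 patterns are encoded as
id = 9d₁ + 3d₂ + d₃ + 1 with digit d = status + 1, so all-constant (0,0,0)
is id 14; this encoding is this package's own fixed convention, and patterns
are always also reported by their code (e.g. "0,+,0"). Patterns with a
non-constant second transition (adenoma/MIN → early carcinoma, where
malignant transition occurs) carry a flag; 18 of 27 patterns have one.

## Trend clustering

The n genes (default 1000) with the largest |loading| on a configured PC
(default PC1, computed on all samples) are summarized by relative ratios of
mean tumor normalized expression: r_w = mean_w / mean_6 for w ∈ {8, 10, 12},
on the linear normalized scale. Genes with a zero week-6 tumor mean are
dropped with a logged reason. k-means (10 restarts, fixed seed) is run for
k in 1..10 recording total within-cluster SS; the chosen k maximizes the
discrete second difference WSS(k−1) − 2·WSS(k) + WSS(k+1) over interior k.
"First inflection point" has no unique formula; the maximal-second-difference
rule picks the sharpest bend of a convex-then-flat curve, and a manual
override (`k_override` / `--k`) is provided for analyses that fix k by
inspection. Note that the rule genuinely prefers k = 2 for three collinear
blobs (the geometry where merging two of them is cheap); recovery guarantees
in the tests use pairwise-equidistant planted blobs.

## Co-expression network and modules

Pearson correlations of log-normalized expression on the top-variance genes
(default 2000, tumor samples) feed a signed adjacency
a_ij = ((1+cor_ij)/2)^β with β = 12, the common signed-network default;
soft-threshold selection by scale-free fit is out of scope and β is a
configuration knob. The topological overlap measure is
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), verified
against a triple-loop oracle. Modules come from average-linkage hierarchical
clustering on 1 − TOM with a static cut (height 0.8, minimum size 30;
clusters below the minimum go to module 0/grey) — a deliberate simplification
of dynamic tree cutting, which is a separate algorithm with its own
parameters; the planted-module tests define correctness for this choice.

The module eigengene is PC1 over samples of the z-scored member submatrix,
scaled to unit variance and sign-aligned to correlate non-negatively with
the module's mean standardized profile. Hubs are ranked by intramodular
connectivity kWithin (ties broken by gene id). Eigengene–stage association
uses Spearman correlation against the ordinal stage coding (control → 0
regardless of age, tumor weeks → 1..4) with a two-sided label-permutation
p-value, p = (1 + #{|ρ*| ≥ |ρ|})/(B+1), B = 10,000 by default; an exhaustive
mode enumerates all permutations for small n and anchors the Monte-Carlo
implementation in tests.

Module preservation is a simplified two-statistic Z-summary: the reference
network is built from tumor samples and preservation is evaluated in control
samples (the direction is fixed here; the comparison "co-expression similar
in tumors and controls" does not specify one). For each module we compute
the test-set module density and the correlation between reference and test
intramodular connectivity, standardize each against random same-size gene
sets from the test network (default 200 draws), and take the median of the
two Z scores. The conventional thresholds 2 (moderate) and 10 (high) are
retained. The full composite preservation statistic involves many more
ingredients and is intentionally out of scope.

## Enrichment

Over-representation of a query gene list in GMT-supplied sets uses the
hypergeometric upper tail with the universe equal to all genes surviving the
expression filter, and BH adjustment across sets. Length-bias-corrected
enrichment and running-sum set statistics are intentionally not implemented;
they are external methods, not part of this pipeline's own computation.

## Synthetic data generator

The generator emulates exactly the structure the analysis assumes: NB counts
with per-gene log-normal baselines (natural-log location 4.0, scale 1.5 —
median ≈ 55 counts with a realistic dynamic range) and log-normal per-gene
dispersions (median 0.1, typical for inbred-mouse bulk RNA-seq), log-normal
library size factors (σ = 0.15), and four planted gene classes besides null:

- constant DEGs (5%, |log2FC| = 3 at every stage, alternating sign),
- progressive DEGs (2%, |log2FC| rising 0.75 → 3.0 across stages),
- transition genes (2%, a ±3 log2 jump at the second transition, so the
  planted LRC sign matches the planted pattern),
- module members (2 modules × 50 genes) whose log-scale expression adds
  loading × latent factor; the first module's factor is linear in ordinal
  stage (0 for controls, 1–4 for tumor weeks) plus standard-normal noise,
  the second's is pure noise. Loadings are uniform in [0.5, 1] times a scale
  (default 1.0).

Litter and batch are small additive log2 shifts (SD 0.1) assigned per
sample, enough for the covariate-association heat map to show the contrast
between biological and technical drivers without distorting DE. Counts are
drawn independently per gene given the factors — there is no residual
gene–gene correlation outside modules, which keeps the network null clean
but also means passing tests cannot speak to correlated-noise artifacts in
real data. Also not emulated: read-level structure, isoform usage, GC and
length bias, outlier samples. A separate helper plants pairwise-equidistant
expression-trend blobs for clustering tests.

At the default scale (5000 genes, 12 tumor samples, loading scale 1.0), the
latent-factor module sits near the detectability boundary of the β = 12 /
cut 0.8 network: across seeds its genes sometimes remain grey while the
strongly co-expressed transition/progressive blocks form the detected
stage-associated modules. This is a property of the declared conditions,
not an error, and the planted-module recovery guarantees are therefore
stated (and tested) under stronger loading-to-noise ratios.

## Problem sizes and determinism

Every stochastic step takes an explicit seed (simulation config, k-means,
permutation tests, preservation nulls), and identical inputs give identical
outputs; the pipeline derives per-module permutation seeds from its one seed.
Default analysis sizes — 5000 genes, 24 samples, 2000 network genes, 10,000
permutations, 200 preservation draws — run end-to-end in well under a minute
on a single CPU; test fixtures use smaller gene counts chosen to keep each
statistical check's Monte-Carlo error far from its assertion margin.

## Known limitations

- The exact test conditions on rounded pseudo-counts; for very small size
  factors the rounding loses sub-integer information (negligible at
  realistic library sizes).
- The normal approximation above the total cap is accurate in the tails
  that matter but is not an exact-tail computation.
- The static tree cut cannot split nested modules the way dynamic cutting
  can; closely correlated modules may merge.
- The preservation Z-summary uses two statistics, not the full composite;
  its absolute values are comparable across modules within a run, not with
  other software.
- BH within stage assumes per-stage discovery lists are the inferential
  unit; a global-FDR variant would need a different adjustment scope.
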