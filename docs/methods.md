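# Methods

`tregsig` reimplements, as a tested library, the computational path from
bulk RNA-seq count matrices of sorted CD4 T-cell populations to three
derived objects: the thymic Treg expression signature (the up/down DEG
partition of the thymic Treg-vs-Tconv contrast), the "private" gene set
(up-DEGs whose expression in conventional cells falls below the *IL2RA*
level there), and a nine-cell classification of each private gene's
expression trajectory from thymus to naive to memory regulatory T cells.
Analysis starts from a gene × sample integer count matrix; read alignment
and feature counting are out of scope.

## Differential-expression engine

The engine follows the standard weighted-linear-model route for RNA-seq
counts.

**CPM and filtering.** Counts per million are
`(y + c) / (N·f + 2c) × 10⁶` with prior count `c` (0 for plain CPM, 0.5
for log2-CPM), library size `N` and TMM factor `f`. The low-expression
filter removes a gene if its CPM (prior 0, unit factors) is below
`filter_min_cpm` (default 1) in more than `filter_max_low_libraries`
(default 2) of the libraries in the analysis at hand — a gene low in
exactly two libraries is kept. The filter is applied per analysis (6
libraries for the thymic contrast, 18 for the harmonized run), and the
reference gene is exempted so the private-gene threshold is always
computable.

**TMM normalization.** Between-sample scaling factors are trimmed means of
M-values against a reference library (the sample whose 75th count
percentile over library size is closest to the mean of that statistic).
For each sample, genes nonzero in both libraries contribute
`M = log2((y_k/N_k)/(y_r/N_r))` and `A = ½·log2(y_k y_r/(N_k N_r))`;
two-sided trims of 30% on M and 5% on A are applied by rank (ties broken
by gene order for determinism), and the factor is `2^(Σ wM/Σ w)` with
inverse asymptotic-variance weights `w = 1/(1/y_k − 1/N_k + 1/y_r − 1/N_r)`.
Factors are divided by their geometric mean. The implementation agrees
with edgeR's `calcNormFactors(method="TMM")` to ~1e-11 on random matrices
(cross-checked in the test suite).

**Sample QC by classical MDS.** The distance between two samples is the
root mean square of the 500 largest absolute log2-CPM differences for that
pair (pair-specific gene selection), embedded by Torgerson scaling of the
double-centred squared-distance matrix. Axis signs are fixed so each
axis's largest-magnitude loading is positive.

**Precision weights.** log2-CPM uses prior 0.5 against effective library
size `N·f + 1`. An unweighted per-gene least-squares fit of the
group-means design yields residual SDs; a lowess (span 0.5, 2 robustifying
iterations) of quarter-root SD against mean log2 count gives the
mean-variance trend; each observation's fitted log2 count is mapped
through the trend (constant extrapolation beyond the fitted range, trend
clipped to [1e-2, 1e3]) and the weight is the fitted value to the −4
power. This reproduces the voom construction: weights rise with
expression for NB counts and become flat for homoskedastic input.

**Fits and moderation.** Per-gene weighted least squares on a group-means
design gives the contrast estimate `β̂ = c'(X'WX)⁻¹X'Wy` and unscaled SD
`u = sqrt(c'(X'WX)⁻¹c)`; singular systems are excluded with a warning.
Residual variances are shrunk by empirical Bayes: `(d₀, s₀²)` are
moment-matched to a scaled F by digamma/trigamma inversion of the spread
of `log s²` in excess of the chi-square sampling contribution (when there
is no excess spread, `d₀ = ∞` and `s₀²` is the arithmetic mean of the
gene variances — complete pooling). The posterior variance
`(d₀s₀² + d·s²)/(d₀ + d)` always lies between `s²` and `s₀²`; the
moderated t uses `d₀ + d` degrees of freedom; `d₀ = 0` recovers the
ordinary t. The estimator matches limma's `fitFDist` exactly (tested).
Moderation can be disabled (`prior_df=0`) for a literal unmoderated fit.

**Multiple testing and DEG calling.** Both Holm (step-down FWER) and
Benjamini–Hochberg (step-up FDR) adjustments are provided through
statsmodels. The DEG rule thresholds an FDR — "adjusted p < 0.05" jointly
with |log2FC| ≥ 1 — so the default adjustment is BH, which controls
exactly that quantity; Holm is retained as `adjust_method: holm` for a
strictly family-wise reading. With three libraries per group, Holm across
~14,000 genes requires observed effects near 1.8 log2 units to call a
planted 2-fold-squared change, which sacrifices most of the sensitivity
the signature definition needs; this trade-off, not convention alone,
drove the default. The Holm implementation itself is oracle-tested
(exact agreement with step-down enumeration) and its family-wise error is
verified on null simulations.

## Signature and private genes

The signature is the up/down partition of DEG calls, ordered by effect
size. The private-gene threshold is the mean (configurably median)
TMM-normalized log2-CPM of the reference gene (*IL2RA* by default) across
the opposing-population (tTconv) libraries; an up-DEG is private when its
opposing-population mean is at or below that threshold (the boundary is
inclusive by default and configurable — the measure-zero boundary is
irrelevant in practice). The reference gene itself is excluded from
membership. Membership is monotone in the threshold and invariant to
non-opposing samples.

## Trajectory classification

All 18 libraries are harmonized in one pass (joint filter, TMM, weights,
one six-group model), and three Treg-lineage contrasts are tested:
thymus→naive, naive→memory, thymus→memory. Contrasts are oriented *later
minus earlier*: log2FC < 0 and status `down` mean expression falls across
the transition (was higher in the earlier compartment), matching the
"change upon transition" reading of the trajectory grid. Each analyzed
private gene is assigned its (C1-status, C2-status) cell of the 3×3 grid.
Genes in the (down, up) cell — lower after egress but rising again in
memory — are split by an expression-level tiebreak comparing mean Treg
log2-CPM in thymus versus memory; the thymus→memory contrast is computed
and reported for transparency but does not drive the tiebreak. The
thymus-enriched aggregate is (down, stable) ∪ (down, down) ∪ {(down, up)
with thymus > memory}.

Because the trajectory hypotheses are only posed for the pre-specified
private set, their p-values are adjusted within that family by default;
`trajectory_adjust_scope: genome` adjusts across all filtered genes
instead. Private genes removed by the joint 18-library filter are
reported as dropped, mirroring the attrition expected when thymic-only
discoveries are re-tested in a harmonized analysis.

The clustered heatmap matrix z-scores each gene across the Treg libraries
and orders rows by average-linkage hierarchical clustering on Euclidean
distance; zero-variance rows become all zeros and are placed after the
dendrogram in gene-id order; the two first-level cluster memberships are
returned so the thymus-high/periphery-high split can be quantified.

## Enrichment

Preranked GSEA ranks all analyzed genes by signed log2FC (ties broken by
raw p then gene id; a DEG-only ranking is available since either reading
of "the DEG list ranked by fold-change" is defensible). The enrichment
score is the signed maximum deviation of the running sum (hits weighted by
|metric|^p, p = 1 by default; misses step down by 1/(N−hits)); the
running sum is accumulated so that endpoints are exact (a full set scores
exactly 1). Significance uses gene-label permutations — random same-size
gene sets — with `NES = ES / mean(|null ES| of the same sign)` and the
add-one estimator `p = (1 + #at-least-as-extreme) / (1 + #same-sign)`;
small instances can enumerate all subsets exhaustively instead of
sampling, which makes the estimator exactly testable. The adaptive
multilevel p-value refinement of fgsea is deliberately not reimplemented:
classic permutation p-values are exactly verifiable against enumeration.
Over-representation uses the upper-tail hypergeometric test with BH
correction and the enrichment ratio `(k/n)/(K/N)`.

## Synthetic experiments

The generator emulates the study design the analysis assumes: 18
libraries = 3 thymic donors × {tTreg, tTconv} + 3 blood donors ×
{naive/memory × Treg/Tconv}. Counts are negative binomial
(gamma–Poisson) with variance `μ + φμ²`; class effects are exact
multiplicative shifts of μ, the mean–variance form the precision weights
are designed for. Defaults: 15,000 genes; dispersion φ = 0.1 (a
between-donor biological CV near 0.32, typical for sorted human bulk
RNA-seq); donor effects N(0, 0.15²) on the log2 scale, shared across a
donor's populations, which keeps samples aggregating by condition rather
than donor in the MDS check while still inflating residual variance;
library sizes log-normal around 2×10⁷ with CV 0.15 (a desk-scale
surrogate for production depth); planted |log2FC| = 2; planted fractions
4.5% up, 4% down, 2% private (private genes are up-DEGs over and above
the up fraction), mirroring the relative class sizes of an
~13,000-expressed-gene experiment.

Planted expression levels are stated in absolute log2-CPM. Since CPM is
relative, the generator calibrates the null-gene baselines by a single
scalar shift (solved by bisection) so the geometric-mean nominal total of
the *thymic* libraries is exactly 10⁶ — the thymic analysis is where the
absolute reference threshold is measured, and every other stage uses only
scale-invariant comparisons. Planted values (reference gene, DEG and
private baselines) are never shifted, so the configured reference level
(log2-CPM 4 in conventional cells, elevated 4 log2 units in Tregs) is
realized on the observed scale once TMM has removed per-sample composition
offsets.

Planted classes are placed so the truth table is well-defined rather than
noise-limited: private baselines sit in [reference−2, reference−1]
(satisfying the private rule with a ≥1 log2 margin), non-private up-DEG
baselines at or above reference+1 (so they cannot satisfy it), and
down-DEG baselines high enough that the suppressed state stays above the
1-CPM detection floor. Trajectory cells are allocated over private genes
with fractions mirroring the relative cell sizes of the study design
(54% down-stable, 20% down-up, 9% up-stable, …). For down-up genes,
symmetric ±lfc steps would return memory exactly to the thymic level and
make the thymus-vs-memory tiebreak a coin flip, so the step opposite the
planted winner is 1.5×lfc, leaving a 0.5×lfc planted gap; the
thymus-greater fraction defaults to 33/48.

What the generator does *not* emulate — GC/length bias, batch effects
beyond donor, correlated gene modules, outlier samples, and the long-tail
abundance distribution of real transcriptomes — bounds what passing
recovery tests show: they demonstrate that the estimators and rules
recover the classes they define under the stated noise model, not that
real-data headline counts would be reproduced.

## Numerical choices and degenerate inputs

Trimming ranks, ranking ties and written row order all break ties by gene
id; clustering places zero-variance rows deterministically last; MDS axis
signs are canonicalized. The trigamma inversion uses Newton iteration
with the standard asymptotic starting point; all-equal variances short-
circuit to `d₀ = ∞`. Permutation nulls with no same-sign scores yield a
missing NES with a warning rather than a fabricated value. A single
pipeline seed fans out to stage seeds through a fixed `SeedSequence`
spawn order, making full runs byte-identical for identical inputs,
configuration and seed.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the default 15,000-gene ×
18-library experiment end to end, a 200-replicate null batch at 2,000
genes for type-I error and Holm family-wise error, a 5,000-gene
power/precision run, 20 random 100×6 matrices against the TMM oracle, and
1,000 random p-vectors against the Holm oracle — sizes chosen to exercise
every code path at full design dimensionality while keeping a complete
run in the low minutes on one CPU.

## Known limitations

Holm-vs-BH cannot both be the default; the choice is documented above and
configurable. The 6-group model assumes homoskedastic (after weighting)
within-group noise and no donor random effect in the design — donor
shifts cancel from contrast estimates in expectation but inflate residual
variance, making tests mildly conservative. The private rule compares
normalized log2-CPM means (a raw-CPM switch is provided); with three
opposing libraries the threshold estimate carries a sampling SE of ~0.3
log2 units. GSEA p-values are permutation-resolution-limited to
1/(1+nperm).
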