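# Methods

This note documents the models, defaults and numerical choices behind
`decidecon`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the acceptance script, not
asserted from memory.

## Scientific setting

In primate models of intrauterine inflammation, neutrophils accumulate in
the chorio-decidua — the maternal-facing layer of the fetal membranes.
Because the tissue sits at the interface of two genomes, the question
"are these infiltrating neutrophils maternal or fetal?" can be answered
from bulk RNA-seq alone: sites where the maternal and fetal genotypes
diverge (informative SNPs) act as natural barcodes, and the allele
frequencies of a query tissue's reads reveal the mixture of genomes it
contains. The same experiments profile the transcriptional response of
these neutrophils to LPS with and without TNF blockade (the anti-TNF
antibody Adalimumab), which motivates the package's second half: a
negative-binomial differential-expression stage and a partition of
LPS-induced genes by their TNF dependence, plus the qPCR-style relative
expression and nonparametric group statistics used for validation assays.

## Origin deconvolution

### Genotype calling

Reference genotypes come from per-site A/C/G/T pileups of two samples that
are unambiguous proxies for the two genomes (maternal blood neutrophils;
fetal lung). A site is called homozygous when the major base frequency is
at least `hom_threshold` (default 0.9, boundary inclusive), heterozygous
when the two top bases each reach `het_band` (default 0.2) and jointly
reach `hom_threshold`, and ambiguous otherwise or when depth is below
`min_depth` (default 20 reads). These defaults are deliberately
conservative: a true heterozygote at depth 20 fails the 0.2 minor band
with probability < 1e-3, while a 0.9 hom threshold tolerates ~10% error
plus mapping noise. All are configurable.

### Informative-SNP discovery

A site is informative when both calls are non-ambiguous, the implied
alt-allele dosages differ, both depths reach `min_depth`, and the site's
gene is highly expressed — operationalised as the top quartile
(`high_expression_quantile = 0.75`) of per-gene mean depth across the two
reference samples. Under Mendelian inheritance a mother-fetus pair can
differ by at most half a dosage unit, so the discovery predicate is
`g_m != g_f`, not a larger gap. Sites carrying a third allele above twice
the expected error count (`2 * depth * e / 3` per wrong base) are dropped
as violations of the bi-allelic assumption. Fewer than `min_informative`
(default 5 — the floor observed per animal pair in this study design)
surviving SNPs raises a warning, not an error: the floor is an observed
property, not a requirement. Coordinates are 1-based throughout, matching
VCF.

### Mixture model and estimation

Let f be the fraction of a query sample's reads of maternal origin. At an
informative SNP with maternal/fetal alt dosages g_m, g_f, the expected alt
fraction is p(f) = f·g_m + (1−f)·g_f; a symmetric per-read substitution
error e (spread uniformly over the three wrong bases) maps this to
p′(f) = p(1−e) + (1−p)e/3. Alt read counts are modelled
Binomial(depth, p′(f)) independently across SNPs; sites uncovered in the
query are skipped (all-zero coverage is an estimation error). The
likelihood is maximised on a grid over [0, 1] (step 0.001 by default): the
1-D likelihood is cheap, the grid cannot miss the optimum by more than one
step, and it makes the brute-force oracle comparison in the tests exact.
The 95% CI is the profile-likelihood set {f : logL(f) ≥ max − 1.92}
(asymptotic chi-square with 1 df). The categorical call is `maternal` when
f̂ ≥ 0.9, `fetal` when f̂ ≤ 0.1, `mixed` otherwise; the 0.9 cut is a
reporting convention, not a fitted constant, and is exposed as a
parameter.

Two estimator properties are verified by simulation (see
`tests/test_acceptance.py`): over 200 runs at 20 SNPs, depth 500,
e = 0.005 and true f ∈ {0, 0.25, 0.5, 0.75, 1}, the mean absolute error is
below 0.02 and the profile CI covers the truth in ≥ 90% of runs. The
pure-source identities (f̂ exactly 1 or 0) hold in the error-free limit;
with e > 0 and finite depth the boundary estimate fluctuates within a few
grid steps of the boundary, which is why the exact identity is stated at
e = 0.

## Differential expression

The DE stage is a deliberate, documented substitution for a full NB GLM
engine: at desk scale a transparent method-of-moments Wald test is
adequate, fully testable, and free of external fitting machinery. It is
not claimed to re-implement shrinkage-based estimators.

* **Normalisation** — median-of-ratios size factors over genes with
  nonzero counts in every sample, rescaled to geometric mean exactly 1.
* **Dispersion** — method of moments. The default pools across genes:
  within-group sample variances satisfy E[s²] = μ + αμ², so
  α̂ = Σ(s² − m) / Σ m² summed over genes and contrast groups, clipped at
  zero and floored at 1e-8. With thousands of genes this estimate is
  precise enough that the Wald normal reference is calibrated at n = 5 per
  group (verified: null rejection rate at p < 0.05 stays inside
  [0.03, 0.07] over 50 simulated matrices). A `per-gene` mode exposes the
  raw gene-wise estimator; with 5 samples per group it is noisy and makes
  the normal-reference test anticonservative, which is why it is not the
  default. The pooled default assumes a roughly common dispersion across
  genes — true of the synthetic generator, approximate for real data.
* **Test** — log2 fold change of normalised group means with pseudocount
  0.5 added to both means (zeros otherwise undefined); delta-method SE
  from Var(mean) ≈ (μ + αμ²)/n per group; two-sided p from the normal
  reference; Benjamini-Hochberg adjustment across genes.

One test cross-checks the log2 fold changes against an independent NB GLM
implementation (pydeseq2) on a simulated matrix; agreement is r > 0.98.

## TNF-dependence partition

With thresholds t = (baseMean > 10, LPS fold ≥ 4, padj < 0.05,
suppression fold 1.5):

* **induced** — baseMean strictly above 10, linear LPS/CTRL fold change of
  at least 4 (inclusive), adjusted p strictly below 0.05. The significance
  conjunct can be disabled (`padj_max=None`) because the induced-set
  definition in the source analyses pairs a DEG filter with fold/baseMean
  filters without stating the conjunction explicitly; the conjunction is
  the safer reading and the default.
* among induced, by the Adalimumab-vs-LPS linear fold change r:
  **dependent** when r ≤ 1/1.5 (boundary inclusive toward dependence,
  matching a "fold decrease ≥ 1.5" reading), **upregulated** when r ≥ 1.5
  (inclusive), **independent** in the open band between.

The partition is exhaustive and exclusive by construction and is
property-tested on random records; the bookkeeping invariant
dependent + independent + upregulated = induced total always holds. The
summary reports the dependent fraction among induced genes (null when
nothing is induced).

## qPCR relative expression and group statistics

Relative expression uses the delta-delta-Ct scheme with amplification
efficiency fixed at 2 (no efficiency correction): rel = 2^−(Ct_target −
Ct_ref) with an 18S-style endogenous reference, and fold-over-control =
rel divided by the calibrator-group mean of rel, per gene. Two identities
follow and are asserted exactly: the calibrator-group mean fold is 1, and
adding a constant to every Ct (target and reference alike) leaves all
folds unchanged.

Group comparisons default to the two-tailed Mann-Whitney U test, the test
used throughout this kind of validation work; an unpaired t test is
available behind a flag since both appear in practice. For n1 + n2 ≤ 12
the p value is exact: the U distribution is enumerated over all
C(n1+n2, n1) labelings of the observed pooled multiset with midranks for
ties, and p = 2 × min(tail probabilities), capped at 1 — an
enumeration-exact two-sided convention (small-sample two-sided definitions
vary across software; this one is stated and tested against a full
enumeration oracle). Larger samples use the tie-corrected normal
approximation. Summaries report mean ± SEM (sd/√n; null for n = 1), flag
significance at p ≤ 0.05, and flag comparisons whose group sizes cannot
reach 0.05 at all (`low_n`).

## Synthetic data: what it emulates and what it does not

The generator provides the statistical structure the analysis stages
assume, with one independent random stream per (seed, operation, unit) so
adding genes or sites never perturbs earlier draws.

* **Genotypes** — per-gene site counts Binomial(gene_length, het_rate);
  parental dosages independent Hardy-Weinberg draws at alt frequency 0.3
  (chosen to make divergent sites abundant; configurable); fetal dosage by
  uniform transmission of one allele per parent. Defaults 200 genes ×
  1.5 kb × het rate 1e-3 give ≈ 300 candidate sites per pair — a
  human-like exonic heterozygosity scale.
* **Pileups** — depth Poisson around mean_depth × gene expression weight
  (log-normal weights, σ = 1, mean 1 — so "high expression" has an
  unambiguous synthetic meaning); base counts multinomial with symmetric
  error e ≤ 0.05 spread over the three wrong bases. Default depth 50,
  e = 0.005. The study itself does not report depth or error rate, so
  these are stated assumptions, not reconstructions.
* **Counts** — NB(mean = baseline × condition effect × size factor,
  dispersion α = 0.05) for Control / LPS / LPS + anti-TNF groups; planted
  induced genes get an LPS fold change (default 6), planted dependent
  genes an additional 3-fold Adalimumab attenuation, planted upregulated
  genes a 2-fold further increase; sample size factors log-normal
  (σ = 0.15, geometric mean 1). Planted class sizes default to
  (60, 20, 5) among 2000 genes.
* **Ct tables** — target Ct shifts per condition with Gaussian well noise,
  constant reference gene.

Not emulated: read-level artifacts (mapping bias, duplicates, indels,
multi-allelic sites), gene-to-gene dispersion variation, library-specific
GC effects, batch structure, and any dependence between the origin mixture
and expression. Passing tests therefore demonstrate correctness of the
estimators under their stated models — not robustness to alignment
artifacts or to dispersion heterogeneity in real tissue.

## Problem sizes and determinism

Simulation-based checks use 200-gene genotype panels, 2000-gene count
matrices with 5 samples per group, 200 origin replicates and 50 null DE
matrices; these sizes make every moment-based check tight (binomial /
NB standard errors a small fraction of the tested tolerances) while the
full suite runs in seconds. Every stochastic routine takes an explicit
integer seed and is a pure function of (parameters, seed); hypothesis
property tests run derandomised.

## Known limitations

* The origin model assumes exactly two source genomes and bi-allelic
  sites; microchimerism below the grid resolution (0.001) is invisible.
* Pooled-dispersion Wald p values are approximate when true dispersions
  vary strongly across genes; the per-gene mode is honest about its noise
  but anticonservative at n = 5.
* The exact Mann-Whitney enumerates C(n1+n2, n1) labelings; the default
  exact limit of 12 keeps this below 1000 evaluations.
* Genotype calls inherit reference-sample purity: contamination of the
  reference samples biases dosages and hence f̂ toward the contaminant.
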