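# Methods

This note documents the statistical model behind each module, the
conventions chosen where several were defensible, and what the synthetic
data generator does and does not emulate.

## Study design and estimands

The package targets the retrospective two-stage case-control design: a
discovery and a replication sample, each with case/control genotype counts
for one biallelic SNP (major allele G, minor allele A), merged by summing
counts once the Breslow-Day test finds the stage ORs homogeneous.  Because
sampling is on outcome, the identifiable effect measure is the odds ratio,
and every embedded or estimated effect in the package is an OR.

## Contingency statistics

- **Genetic models.** Allelic analysis expands each subject into two
  alleles (AA → 2 A, AG → 1 A + 1 G).  Dominant pools AG+AA against GG;
  recessive pools AG+GG against AA; additive codes A-dosage 0/1/2 and is
  fitted as a single-predictor logistic regression on the grouped six-cell
  table (frequency weights), so its per-allele OR is a maximum-likelihood
  trend estimate rather than a cross-product.
- **OR, CI, p.** Cross-product OR with the Woolf log-scale CI and a
  two-sided Wald p on ln OR.  The unadjusted p-value convention of the
  reference analyses (Wald vs score vs Pearson) is not fully determined;
  Wald on ln OR is primary and Pearson χ² is exposed alongside
  (`pearson_chi2`); the two agree within ~10% on every desk-scale table we
  reproduce.  Zero cells get the Haldane-Anscombe +0.5 on all four cells,
  applied only when needed.
- **HWE.** Pearson χ² with 1 df against p², 2pq, q² expectations computed
  from the sample allele frequency.  A monomorphic sample returns χ² = 0,
  p = 1 (vacuously in equilibrium) rather than an error.
- **Merging.** "Merged set" = element-wise count sums (this exactly
  reproduces the published merged rows); an inverse-variance fixed-effect
  combiner is provided separately as `inverse_variance_pool` and is not
  used in the primary path.
- **Breslow-Day.** Delegated to statsmodels' stratified-table machinery:
  the statistic is computed around the Mantel-Haenszel common OR with the
  Tarone adjustment on by default, df = strata − 1.
- **Power.** Two-sided two-sample proportion z-test without continuity
  correction, per-group n = subjects (not alleles):
  `power = Φ((|p₁−p₂| − z_{α/2}·SE₀)/SE₁)` with SE₀ pooled under the null
  and SE₁ unpooled.  This is the variant that reproduces the published
  81.0% figure from the case/control MAFs and sample sizes, and matches
  the classical sample-size formula family used by standard power
  calculators.

## Logistic models and interaction tests

`fit_logistic` is maximum likelihood via IRLS (statsmodels GLM, binomial
family), tolerance 1e-8, at most 100 iterations.  Frequency weights make
grouped contingency-cell data exactly equivalent to the expanded
individual-level table (coefficients agree to < 1e-6 in tests; a grouped
2×2 fit equals the closed-form cross-product OR).  Separation is flagged
when any |β| exceeds 15 and raised as an error rather than silently
returned; rank-deficient designs are rejected with the collinear columns
named.

The multiplicative G×E interaction test fits `outcome ~ G + E (+
covariates)` with and without the G×E product and reports the LRT
`χ² = 2Δℓ` with 1 df, plus `exp(β_GE)` with its Wald CI.  Unadjusted
interaction p-values are computed from the published eight-cell strata
(they need only grouped counts); adjusted versions require
individual-level covariates and run on any cohort table with those
columns.  Subgroup genotype ORs exclude the stratifying variable from the
model by default.

ANCOVA is ordinary least squares with group dummies; the group effect is a
partial F-test against the covariate-only model and adjusted means are
evaluated at the grand covariate means (the classical convention).
Mann-Whitney uses exact enumeration when n₁·n₂ ≤ 400 and there are no
cross-sample ties, otherwise the tie-corrected normal approximation with
continuity correction.  Spearman uses average ranks with the
t-approximation p.

## Permutation empirical p-values

The permutation null holds the genotype column totals and case/control row
totals of the 2×3 table fixed and redistributes genotype counts between
rows.  Drawing the case row from a multivariate hypergeometric
distribution is distributionally identical to shuffling case/control
labels over subjects and is O(1) per permutation, so the default 100,000
permutations run in well under a second.  The tracked statistic matches
the genetic model under test: Pearson χ² of the recoded 2×2 for
allelic/dominant/recessive, the Cochran-Armitage trend χ² (the score
statistic of the dosage logistic model) for additive.  The estimator
`(1 + b)/(1 + m)` never returns 0.  An exhaustive enumerator over all case
rows compatible with the margins (`exact_permutation_p`) serves as the
oracle on desk-size tables.

The published empirical p-values for low-signal models differ from any
single-statistic permutation scheme by more than Monte-Carlo error (e.g. a
0.324 asymptotic vs 0.533 empirical recessive pair); the permuted
statistic behind those numbers is not recoverable, so this implementation
documents the discrepancy and validates its empirical p against the
exhaustive oracle and against asymptotic p-values at desk scale instead.

## Modified Gensini score

Stenosis bands are implemented as half-open real intervals so continuous
estimates map unambiguously while integer percentages land in the printed
bands: [0,25] → 1, (25,50] → 2, (50,75] → 4, (75,90] → 8, (90,100) → 16,
{100} → 32.  Multipliers: 5 left main; 2.5 proximal LAD and proximal
circumflex; 1.5 mid LAD; 0.5 second diagonal and posterolateral; 1 for the
other vocabulary segments.  Unknown segment labels are errors (never a
silent multiplier of 1).  Acute total occlusion is scored as a
non-critical lesion: points forced to the lowest band (1) and the weighted
contribution additionally capped at 5, which guarantees the 0-5 range for
every multiplier including the left main (1×5 = 5).  The exact arithmetic
intended by "non-critical (0-5)" is ambiguous; this cap rule is a
documented design choice.  Severity dichotomization uses strict
`score > cutoff`, with the sample median as the default cutoff (30 in the
reference cohort).

## Synthetic cohort generator

The generator emulates the study conditions, not an arbitrary population:

| parameter | default | basis |
| --- | --- | --- |
| n cases / controls | 2317 / 2404 | study sample sizes |
| control MAF | 0.306 | published control MAF |
| genotype OR (dominant) | 1.28 | published merged dominant OR |
| interaction ORs (T2DM, hyperlipidemia, BMI>25) | 1.46, 1.55, 1.37 | ratios of the published stratified ORs |
| covariate prevalences | 0.278 smoking, 0.243 drinking, 0.255 T2DM, 0.228 hyperlipidemia, 0.373 hypertension, 0.379 BMI>25 | control margins of the published strata |
| covariate ORs | 1.5, 1.2, 2.0, 2.0, 1.8, 1.4 | standard epidemiological effect sizes (not published) |
| baseline prevalence | 0.08 | plausible CAD prevalence at reference levels |
| severity log-mean / log-sd | ln 30 / 0.95 | published median 30 and IQR ≈ 18-66 |
| carrier severity shift | 1.19 | published carrier/non-carrier median ratio 35/29.5 |

Disease risk follows `logit(p) = β₀ + β_G·g + Σβ_E·e + Σβ_GE·g·e` with
β = ln OR, in a source population 20× the requested cohort (doubled
automatically on sampling failure); cases and controls are then sampled
without replacement — the retrospective analogue of the study design,
preserving OR interpretation.  Age and sex are drawn (normal 60±10;
55% male) but deliberately excluded from the risk model: the study is
age- and sex-matched, so the generator reproduces the matched null for
those variables.  BMI is continuous (normal 24±3.3) and thresholded at 25
for the subgroup flag.  Case severity is log-normal with a multiplicative
carrier shift; lesion sets are constructed by greedy decomposition of each
case's target score into segment×band contributions (largest fitting band
per randomly ordered segment), so computed scores land within ~1 point of
their targets, plus one acute occlusion in a configurable 10% of cases.

Under interactions, the *marginal* (crude) genotype OR exceeds the
conditional 1.28 by design; parameter recovery therefore checks the
generating (adjusted) model.  What the generator does **not** emulate:
linkage disequilibrium or multi-SNP haplotypes, covariate-covariate
correlation (risk factors are independent Bernoulli given BMI), age/sex
confounding, genotyping error, or longitudinal follow-up.  Passing
recovery tests show the estimators are consistent for the embedded
mechanism, not that real cohorts satisfy these independence assumptions.

## MDR conventions

- "100-time cross-validation" is 10-fold stratified CV repeated 10 times:
  100 held-out evaluations, with CVC reported out of 100 (the published
  "94/100"-style denominators cannot come from a single 10-fold split).
- Every candidate combination is evaluated on the same pre-computed folds;
  CVC counts per-evaluation within-size wins (argmax with first-listed
  tie-break); the per-size winner maximizes CVC, ties broken by mean
  testing accuracy; the overall best maximizes CVC across sizes, then
  accuracy, then smaller size.
- Testing accuracy is *balanced* accuracy (MDR-software convention); with
  near-balanced cohorts it is close to the plain percent-correct of the
  published footnote.
- Cell labeling: high-risk iff cell cases/controls ≥ training
  case:control ratio (ties high); nonempty zero-control cells high; empty
  cells low — and the low default also classifies test cells unseen in
  training.
- Permutation significance re-runs the entire search on label-permuted
  data; p = (1 + exceedances)/(1 + permutations).
- Entropy graphs use base-2 entropies; edge strength classes default to
  strong ≥ 2% of H(Y), moderate ≥ 1%, weak below (the published graphs
  give colors, not thresholds).

Published MDR testing accuracies and entropy percentages depend on the
individual-level dataset and are not reproduced from counts; the engine is
instead validated by brute-force oracle equivalence on small data, chance
behavior on permuted labels, recovery of embedded interactions in
synthetic cohorts, and exact identities (XOR synergy = 100% of H(Y);
duplicated factor redundancy = −I(A;Y)).

## Numerical choices and problem sizes

Degenerate inputs raise errors naming the offending cell/column/row.
Fixed seeds give bit-identical cohorts, folds and permutation streams; the
pipeline derives independent per-stage child seeds from one global seed
via spawn keys, so toggling a stage never shifts another stage's draws.
Test-suite simulation sizes are chosen for tight-but-fast checks:
parameter recovery runs 100 study-scale cohorts; type-I calibration runs
1000 null simulations of n = 2000 (interaction LRT) and 1000 permutation
analyses at 499 resamples; MC-vs-exhaustive permutation checks use ~50-subject
tables where full enumeration is trivial.

## Known limitations

Single SNP only (no LD, no haplotypes, no PLINK/VCF ingestion);
no exact tests beyond the continuity correction; no random-effects
meta-analysis; no Firth correction (separation is reported, not repaired);
no covariate-adjusted or model-based MDR variants; lesion simulation
targets score distributions, not anatomically realistic lesion co-occurrence.
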