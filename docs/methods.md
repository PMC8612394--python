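# Methods

## Study design being emulated

The pipeline analyses a case–control survival trait: survival to age
85+ (case) versus death or last follow-up between 75 and 85 (control).
Cases demonstrate survival to 85 whether or not a death age is recorded;
controls include individuals alive at last follow-up inside [75, 85),
which deliberately mirrors the field's usual definition even though some
of those controls would eventually pass 85. A configuration switch
(`exclude_alive_controls`) drops alive-censored controls for sensitivity
analysis. Boundary conventions are exact: age 85.0 is a case, 75.0 a
control, anything below 75 is excluded.

Two candidate genes supply the SNP sets for the primary scan — in the
default synthetic study, a 63-SNP gene on chromosome 15 and an 8-SNP
gene on chromosome 12, echoing a stress-response sensor/effector gene
pair. All 63 × 8 = 504 cross-gene pairs are fitted; LD clumping reduces
them to independent representatives before multiple-testing correction.

## Synthetic genotype generator

Genotypes come from a latent-Gaussian threshold model. Each haplotype
carries a multivariate-normal latent vector per LD block; the minor
allele at SNP j is present when the latent value is below Φ⁻¹(MAF_j),
and a genotype is the sum of two independent haplotypes. Because the
two haplotypes are iid, the genotype correlation between two SNPs equals
the allele-indicator correlation, so a target genotype R² is hit by
solving corr(1{Z₁<t₁}, 1{Z₂<t₂}) = √R² for the latent correlation ρ by
bisection on the bivariate-normal orthant probability (monotone in ρ).
Two loci with unequal MAFs cannot reach R² = 1: the attainable bound is
((min(p₁,p₂) − p₁p₂)/√(p₁q₁p₂q₂))², and configurations beyond it are
rejected with that bound in the message. Pairwise-calibrated latent
matrices are eigenvalue-clipped to the nearest PSD correlation matrix
when needed; sampling uses the eigendecomposition square root, so a
target R² of 1 at equal MAFs yields exactly identical genotype columns.

Default study fixture: n = 6,142 individuals (≈ 2,564 expected cases /
3,578 controls), 63 + 8 SNPs, eight LD blocks in the large gene
(sizes 8×7 + 7) and a single block in the small gene, within-block
target R² = 0.45 and independence across blocks. Because SNPs in strong
LD share genealogy, each block jitters a base MAF by at most 12%; block
bases span 0.02–0.47, the planted interacting SNPs have MAFs 0.06 and
0.14. A within-block target of 0.45 sits comfortably above the 0.1
clumping threshold and below the attainability bound for the jittered
frequencies. No real LD values were available to copy, so the block
layout is an emulation choice, not an observed structure.

The trait model is the generative twin of the analysis model:
logit P(case) = intercept + Σ mains·g + Σ interactions·(g_a·g_b) +
Σ covariate effects·x. The default plants a single cross-gene
interaction of log-odds 0.60 with no main effects. Covariate effects
(education −0.35, smoking −0.33, female +0.14) are log-odds consistent
with the case/control covariate contrasts of a large ageing cohort, and
the intercept 0.08 was calibrated analytically (first-order, at
covariate means) so the marginal case fraction lands near 2,564/6,142.
Cases receive ages uniform on [85, 95), controls uniform on [75, 85) —
only the interval, not the distribution, is dictated by the trait
definition — and an optional exclusion fraction receives ages below 75
to exercise the exclusion path. Missing genotype calls are
missing-completely-at-random at a configurable rate (default 0.2% in the
study fixture); the case indicator is drawn from the post-missingness
matrix with missing contributions counted as zero, keeping the generator
a pure function of its inputs.

Reproducibility: one master seed is expanded into independent substreams
per stage (genotypes, missingness, covariates, trait), so identical
configurations give byte-identical outputs and changing, say, the
missingness rate does not perturb the trait draw.

## Quality control

Two filter protocols run on the same input snapshot and individuals/SNPs
passing either protocol are retained (union retention — the point is to
trade slightly laxer QC for sample size). Per protocol: individuals are
dropped for missingness > 5%, heterozygous-call fraction outside
mean ± 3 SD, any PC outside mean ± 8 SD, or being a duplicate genotype
vector (first occurrence kept); SNPs are dropped for MAF < 1%, call rate
< 95%, or HWE exact P < 10⁻⁷. The second protocol is a second
configurable threshold set (defaults equal the first): the union
mechanism, not any particular second threshold set, is the reproducible
content. Filters are computed once on the pre-filter snapshot and
applied jointly; no iterative re-estimation. The heterozygosity statistic
is the raw heterozygous-call fraction over non-missing SNPs (an
F-statistic variant would need reference allele frequencies the input
does not carry). The sex-mismatch check is a documented no-op stub: it
requires sex-chromosome data that the generator does not model.

The HWE test is the exact conditional test: given the allele counts, the
heterozygote count follows a hypergeometric-type distribution
P(h) ∝ n!/(n_AA! h! n_aa!)·2ʰ, and the P-value sums the probabilities of
all heterozygote counts no more probable than the observed one.
Monomorphic tables return 1. A chi-square approximation misbehaves
exactly where the 10⁻⁷ threshold operates (rare alleles), hence the
exact test.

## Interaction scan

Per pair, the model is logit P(case) = β₀ + β₁g₁ + β₂g₂ + β₁₂g₁g₂ + γ'x
on complete cases (rows missing either genotype, any covariate, or the
label are dropped per fit; n_used is recorded). β₁₂ is tested by a 1-df
LRT by default — the interaction framework is likelihood-based and the
LRT is better behaved than Wald at moderate counts — with Wald as an
option; the two agree asymptotically (median |log₁₀ ratio| < 0.1 at the
study scale, asserted in the suite). Marginal per-SNP P-values come from
separate single-SNP logistic fits, matching how a standalone single-locus
analysis would be run, not from the joint model's main-effect terms.

Fitting is Newton/IRLS with step-halving; convergence at max|score| <
10⁻⁸ or relative log-likelihood change < 10⁻¹⁰, at most 100 iterations.
Rank-deficient designs raise an error naming the collinear columns.
Complete separation (any |β| > 15) marks the fit non-converged and the
P-value missing rather than reporting an unstable number. A pair is
non-testable when its interaction product is constant or fewer than 5
individuals carry minor alleles at both loci (the `min_cell` guard).

Two scan designs: the cross-gene candidate scan (all |A|×|B| pairs,
deterministic rsid order) and the fixed-SNP scan (one SNP against every
other; its main effect is always in the model, consistent with treating
the fixed SNP as an always-present covariate). Sex-stratified runs
filter the cohort and drop sex from the covariate list.

## LD clumping and multiple testing

LD is the squared Pearson correlation of additive genotype codes over
pairwise-complete individuals of the analysis cohort (cases + controls;
no external reference panel). Clustering is greedy and
significance-seeded, in the style of standard clumping tools: pairs are
consumed smallest-p first, each contributing its gene's SNP as the next
cluster seed if unassigned; a cluster absorbs all unassigned gene-mates
with R²(seed, ·) ≥ 0.1. SNPs appearing in no testable pair are clustered
afterwards in rsid order. Everything is deterministic; ties break
lexicographically. Per (cluster-A × cluster-B) cell the representative
is the member pair with the smallest interaction P-value (verified
brute-force-optimal in the suite), the number of independent tests is
the number of cells, and the Bonferroni threshold is α divided by it.
"A pair's type-I error" and "its interaction P-value" are treated as the
same quantity. SNPs are clustered per gene (not pair-level clumping):
LD regions are a per-gene concept and per-gene clustering makes the
cell-count arithmetic (8 × 1 → 8) explicit.

## SIPRS

For fixed SNP\* and threshold t, the index includes every testable,
converged pair with p₁₂ ≤ t, sorted by p₁₂. Per-individual scores:
beta weighting Σ b₁₂ᵏ·g\*·gᵏ (keeping both risk-increasing and
protective associations, the direct interaction analogue of a weighted
PRS) or count weighting Σ 1{g\*·gᵏ > 0} (a genetic-dose count). Neither
form is asserted as "the" canonical published formula; both are exposed.
Missing genotypes contribute zero. Scores are standardized (mean 0,
SD 1) before evaluation.

Evaluation: logistic label ~ score + covariates; the score's LRT
P-value; pseudo-R² as the Nagelkerke increment of the score-bearing
model over the covariate-only model (both R²s computed against the
intercept-only null; McFadden offered via config) — increment-over-
covariates rather than full-model R², so the reported "variance
explained" belongs to the score, not the covariates; AUC of the full
model's fitted probabilities with a DeLong (midrank) 95% CI. The
default sweep grid is nine log-spaced thresholds from 5·10⁻⁵ to 0.05;
empty thresholds are recorded as zero-pair rows and the sweep continues.

In-sample evaluation (scan and evaluate on the same cohort) reproduces
the classic design but is anti-conservative under the null: the pairs
were selected for small P-values on the very data being scored. The
suite demonstrates this inflation explicitly, and `split_sample_sweep`
(scan on a random half, evaluate held-out) restores calibration; it is
the recommended mode for honest significance statements.

## Numerical and interface choices

* PLINK 1 bed/bim/fam (v1.00, SNP-major), A1 = minor allele, 1-based bim
  positions; the codec round-trips bit-exactly and is byte-verified in
  the suite. Gene tags travel in a `.snps.tsv` sidecar since the format
  has no gene column.
* TSV outputs: tab-separated, UTF-8, '.' decimal, `NA` for missing,
  floats at `%.10g`; every pipeline run writes a metadata record with
  seed, package version and per-stage SHA-256 checksums, and identical
  config + seed reproduces byte-identical files.
* Degenerate inputs: monomorphic SNPs are non-testable, not errors;
  a cohort with only one outcome class yields a non-converged fit
  (separation guard) rather than a fabricated estimate; empty clump
  cells are dropped and logged.

## Problem sizes used in the checks

The suite and acceptance script work at the generator's study scale
(n = 6,142, 71 SNPs) for the single-run analyses, and at reduced scale
for replicate-based checks: 200 replicates at n = 6,142 for planted-
effect recovery, 1,000 null pairs at n = 2,000 for type-I-error
calibration, 60 null replicates at n = 700 with 30 candidate partners
for the SIPRS selection-bias and split-sample demonstrations, and a
two-block 800-individual configuration for the byte-identity rerun.
These sizes give the binomial/KS assertions their stated power while
keeping the default run quick on a laptop.

## What the synthetic data does and does not show

The generator reproduces marginal MAFs, block LD with calibrated R²,
covariate structure, a logistic trait with planted interactions, MCAR
missingness, and exclusion-age noise. It does not model recombination
gradients within blocks, population structure beyond iid PCs, sex
chromosomes, genotyping-intensity artefacts, informative missingness,
or linkage between the two genes (they sit on different chromosomes).
Passing tests therefore certify the statistical machinery — calibration,
recovery, determinism, exactness of the combinatorial pieces — not the
biology of any particular cohort; effect sizes recovered here say
nothing about what a real population would show.

## Known limitations

* The union-QC second protocol defaults to the first's thresholds;
  users emulating a specific published pairing must supply both.
* In-sample SIPRS P-values are selection-inflated by construction; use
  the split-sample mode for inference.
* The greedy seeded clustering is order-deterministic but, like all
  single-pass clumping, not a global optimum of any partition criterion.
* Controls alive at last follow-up are genuine controls under the trait
  definition; cohorts with heavy censoring just below 85 will
  misclassify some future long-survivors, attenuating estimates.
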