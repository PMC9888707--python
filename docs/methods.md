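# Methods

## The phenotype

Degree of hearing loss (degree HL) is an ordinal severity scale derived from
the worse-ear air-conduction pure-tone average (PTA), the arithmetic mean of
the hearing thresholds (dB HL) at 500, 1000 and 2000 Hz.  The published
audiological bins are integer ranges (0-15, 16-25, 26-40, 41-55, 56+); since
a PTA is a mean and can be fractional, the package treats the bins as
half-open real intervals with the boundary belonging to the lower degree
((15, 25] → 1, etc.), which reproduces the integer table exactly and
classifies every finite PTA.  When an individual has several audiograms the
default is the most recent exam (a `worst`-ever mode is available); bone-
conduction PTAs are computed but never used for degree assignment.

EHR phenotyping uses phecode instance counts: ≥ 2 instances → case, 0 →
control, exactly 1 → missing.  The hybrid rule assigns degree HL from
audiometry whenever an audiogram exists (regardless of phecode status),
keeps phecode controls without audiometry at degree 0, and excludes phecode
cases and NA individuals without audiometry, recording a reason per
exclusion.  Binary labels used for carrier tables are case = degree ∈
{2,3,4}, control = degree ∈ {0,1}.

## Variant qualification

Genotype QC precedes frequency filtering: calls covered by fewer than 7
reads are set missing, and a variant is retained only if at least one
homozygous-alternate call, or one heterozygous call with alternate-read
fraction ≥ 0.15, survives.  Qualification then requires reference rarity
(gnomAD AFR and NFE AF ≤ 0.001 — the threshold is inclusive because the
removal rule is "greater than 0.001"; a variant absent from the reference is
treated as AF 0 and kept), cohort rarity (AF < 0.01, strict, computed
missing-aware after QC), and predicted deleteriousness (frameshift /
stop-gain / canonical-splice, or missense with REVEL > 0.6, strict).  Both
inequality conventions are configurable.  Gene burden sums alternate
*alleles* (homozygote = 2) over a gene's qualifying variants; a
variant-counting mode (homozygote = 1) is provided since published "summed"
descriptions do not always distinguish the two.  Missing genotypes
contribute zero — no imputation is attempted for rare variants.

## Association machinery

All quantitative tests are OLS of degree HL on the burden or dosage with
sex, age, age² and genetic PCs 1-20 as covariates (age² is always derived,
never supplied).  Per-gene and per-variant scans run through a
Frisch-Waugh-Lovell residualisation: outcome and predictors are projected
off the covariate block once, and slope, classical SE, and Wald p are
recovered with the full model's residual degrees of freedom — algebraically
identical to refitting the full design per unit, and verified against
statsmodels and a normal-equations oracle in the tests.  Binary contrasts
(each degree k ∈ 1..4 versus degree 0, including phecode-derived zeros) use
logistic regression with separation detection (non-convergence or a
diverging coefficient flags the result and withholds the p-value).  The
two-sided Fisher exact test uses the probability-mass rule (sum of
hypergeometric probabilities ≤ the observed table's), the common convention,
and is checked against full enumeration.

Genomic inflation is λ = median(χ²₁ quantiles of the p-values) / 0.4549364,
so uniform p-values give λ = 1.  Threshold calibration follows the
permutation procedure: the phenotype vector is randomly permuted
(covariates stay attached to individuals), the scan is re-run along an
increasing threshold grid (case-carrier counts in steps of 5, or a MAF grid
for the GWAS), and the first threshold whose permuted-phenotype λ —
averaged over `n_perms` permutations, default 10; a single pass reproduces
the one-permutation variant of the procedure — falls below `lambda_max`
is chosen.  "Very minimal inflation" is quantified as λ ≤ 1.05 by default,
a choice this package makes explicit because published descriptions give no
number.  A single λ estimated from a few hundred tests has sampling SD
≈ 0.1, so calibration decisions (and the package's own null-calibration
test) use the permutation-averaged λ; the observed scan is instead checked
for uniform p-values by Kolmogorov-Smirnov.

Benjamini-Hochberg q-values follow the step-up definition
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j capped at 1.  The effective m may exceed the number
of supplied p-values when only the smallest are available (the implicit
remainder at p = 1 cannot change any minimum); FDR is computed separately
for the known-gene scan (case carriers > 0) and the exome-wide scan
(case carriers > 25, with m equal to the number of genes surviving the
filter), never pooled.  Replication uses (a) the Bonferroni min-p rule —
a gene replicates when min p < α/m over a battery of m externally defined
models — and (b) the exact binomial upper tail P(X ≥ k | n, p₀) for counting
re-appearing signals at p < 0.05.

## Risk scores

PRS application is a weighted sum of effect-allele dosages: a weight on the
reference orientation flips the dosage as 2 − d, irreconcilable alleles are
skipped and counted, and missing dosages are imputed at twice the
effect-allele frequency.  Predictive power is the incremental R² — classical
(unadjusted) R² of covariates + score minus covariates alone, on the same
individuals — with a bootstrap SE over individuals (B = 1000 by default).
Top-quantile stratification uses the empirical quantile with strict `>`,
intersects the two exposure conditions, and reports the odds ratio of
degree HL ≥ 2 with Haldane-Anscombe 0.5 correction for empty cells and a
Woolf log-OR normal CI (published analyses of this design report no CI; the
Woolf interval is this package's choice).

## The synthetic cohort generator

The generator emulates the data structure of a mixed-ancestry,
EHR-linked, exome-sequenced cohort; it is the test bed for the whole
pipeline, with ground truth retained for parameter recovery.

**Demographics.** n = 20,000 by default; 51% male; ages uniform on 25-90
years (median ≈ 58); a two-component ancestry mixture (75% EUR / 25% AFR)
separated on PC1, with 20 PCs total.

**Rare variants.** 173 known hearing-loss genes (packaged synthetic
stand-in list with the canonical composition: 66 DFNA, 97 DFNB, 10 dual)
plus 30 additional genes; variant counts 1 + Poisson(11) per gene; base
allele frequencies log-uniform on [2×10⁻⁵, 5×10⁻³] with lognormal
ancestry-specific shifts (σ = 0.5); genotypes Binomial(2, AF) within
ancestry.  Annotations: consequence classes at realistic exome proportions
(55% missense, 30% synonymous, 15% loss-of-function classes), REVEL uniform
for missense, gnomAD AFR/NFE frequencies as the population AF times
lognormal noise (σ = 0.35) with 15% of variants absent from the reference,
sparse ClinVar labels, and per-genotype read depth (Poisson(30) with a 1%
low-coverage mixture) and alternate reads (binomial around 0.5 for
heterozygotes with a 3% poorly-supported component) to exercise QC.

**Common variants.** 200 dosage variants, MAF uniform on [0.05, 0.5],
Hardy-Weinberg genotypes plus clipped Gaussian dosage noise, imputation
quality uniform on [0.2, 1] so the R² filter removes ~12%.

**Liability model.** On the degree-HL scale,
L = 0.65·(age−58)/15 + 0.15·male + Σ PC terms + 0.05·B + Σ_g β_g·b_g + PRS + ε,
where B is the truth-deleterious burden in known HL genes (deleterious =
loss-of-function or missense REVEL > 0.6, before frequency filtering —
biology does not know reference databases; the qualified set recovers about
half of these alleles, a realistic attenuation), per-gene β_g default to
zero, the PRS term is scaled at generation time so its share of Var(L) is
exactly the configured 5%, and ε ~ N(0, 0.96²).

**Audiograms.** Liability is mapped through its empirical quantile u to a
base PTA = −10 + 120·u^γ on [−10, 110] dB.  A strictly linear quantile map
(γ = 1) would make the population PTA uniform — 71% of the cohort
audiogram-positive — so γ is calibrated (γ ≈ 6.2 by default) to give an
18% population rate of PTA > 25 dB, a realistic figure for a hospital
cohort with median age 58; γ = 1 remains available.  Per-ear thresholds at
250-8000 Hz add an ear asymmetry (SD 2.5 dB), a fixed presbycusis-like
frequency profile whose 500/1000/2000 Hz offsets sum to zero, and 1.5 dB
measurement noise, rounded to integer dB; bone-conduction rows subtract a
nonnegative air-bone gap.  Audiograms are emitted for a subset of expected
size 5.3% of the cohort, selected with probability ∝ exp(4.8·u) — the bias
strength is a free parameter (no published mechanism exists for who gets an
audiogram) chosen so that ≈58% of audiogram holders are audiogram-positive,
matching the observed degree distribution among graded individuals.

**Phecodes.** Status (case ≥ 2 instances / NA = 1 / control = 0) is drawn
conditionally on audiogram positivity A = (worse-ear PTA > 25), computed
for everyone from the same threshold values the audiogram table would
contain.  Within the audiogram subset the conditional probabilities are
solved by Bayes' rule from the realised subset positivity so that
P(A | case) = 0.65 and P(A | control) = 0.27 at the configured subset case
and control rates (0.30 / 0.35); because the subset holds only ~1,000
individuals, Bernoulli draws would leave ≈2.5 percentage points of sampling
noise on those fractions, so statuses inside the subset are allocated by
largest-remainder quota in randomised order — the conditional law is the
configured one, only its within-subset realisation is variance-reduced.
Outside the subset, plain Bernoulli draws at population rates (case 30%/4%
and NA 15%/5% given A = 1/0) yield an overall phecode case rate of ≈9%.
Case instance counts are 2 + Poisson(1.5).

**Reproducibility.** All randomness derives from one root seed through
named substreams (individuals / rare / common / phenotype / prs), so a
fixed seed yields byte-identical outputs and each stage is independently
replayable.

**What the generator does not emulate.** No linkage disequilibrium,
relatedness, or sequence-level realism; consequence classes are drawn
independently of position; audiogram frequencies share one severity profile
rather than individual audiogram shapes; phecode counts carry no temporal
structure.  Tests passing on this generator demonstrate the correctness and
calibration of the statistical machinery under the study's data structure,
not the biological findings themselves.

## Parameter-recovery conventions

Recovery tests regress against the generator's latent liability (exposed in
the ground-truth record for exactly this purpose): the 95% Wald CI of the
injected total-burden effect (0.05 per allele) must cover the truth in ≥
90/100 phenotype replicates at n = 20,000 (genotypes held fixed, noise
redrawn — coverage conditional on the design, the standard convention), and
the injected 5% PRS variance share must be recovered as incremental R² =
0.05 ± 0.01.  The observed degree-HL phenotype is deliberately *not* used
for recovery: the hybrid rule pins most controls at degree 0 and coarsens
the rest into five bins, so marginal coefficients on the observed scale are
attenuated by construction — the same conservatism the real design accepts.

## Problem sizes

Default test-suite problem sizes are chosen to keep every check
well-powered while remaining desk-scale: the calibration cohort uses the
full default n = 20,000; the null-calibration scan uses n = 10,000 with 500
simulated genes (more variants per gene and higher allele frequencies than
the default so that ~300 genes clear the >25 case-carrier filter at ~1,850
cases); oracle-equivalence checks use tens of replicates at n ≤ 300.

## Known limitations

- The packaged known-gene list is a synthetic stand-in with the correct
  class composition; real analyses should supply a curated list.
- The logistic fit relies on statsmodels' Newton solver; quasi-separated
  designs are flagged rather than penalised (no Firth correction).
- The GWAS scan is plain OLS per dosage column; no mixed-model or
  saddlepoint correction, so it inherits their limitations for very
  unbalanced binary outcomes (the study phenotype here is quantitative).
- Multiallelic VCF records must be pre-split; the reader refuses them.
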