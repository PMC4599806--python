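# Methods

This note records the statistical model, the choices made where the design
was genuinely open, and what the synthetic-data experiments do and do not
demonstrate.

## Parental-origin dosage construction

Genotypes are biallelic SNPs coded as minor-allele counts. For a
mother-offspring pair the maternally-derived (`g_md`) and
paternally-derived (`g_pd`) minor-allele dosages are determined by table
lookup: homozygous offspring force `(0,0)` or `(1,1)`; a heterozygous
offspring with a homozygous mother has a forced origin (`(0,1)` for a
major-homozygous mother, `(1,0)` for minor-homozygous). The one ambiguous
case — mother and offspring both heterozygous — is resolved in
expectation: under random mating and transmission equilibrium the
probability that the offspring's minor allele came from the mother given
both are heterozygous is `1 - MAF`, so the pair receives
`(g_md, g_pd) = (1-MAF, MAF)`. The identity `g_md + g_pd = G_O` holds
exactly for every consistent pair. Pairs with a missing mother or
offspring call are non-informative for origin, and `(mother, offspring)`
in `{(0,2),(2,0)}` is a Mendelian inconsistency; both are excluded from
parental-origin fits per SNP but retained for additive fits, which is why
additive analyses have larger N.

The MAF entering the ambiguous split is estimated from mothers only
(founders): pooling offspring would count transmitted maternal alleles
twice and bias the frequency toward the mothers'. A pooled estimate is
available by argument. The dosage is deterministic (an expected value);
stochastic hard-label assignment exists only inside the permutation
module.

An `exclude_ambiguous` mode drops double heterozygotes instead. Both
modes give unbiased point estimates under the generative assumptions: the
expected dosage is the conditional mean of the true transmission given
the observed genotypes (Berkson-type error, mean-independent of the
regressors), and ambiguity exclusion selects on genotype only. In the
package's paired simulations (300 replicates, n = 8000, maternal effect
1.4) the two modes differ by +0.013 ± 0.009 — no systematic attenuation
in either direction. Any conservativeness of the expected-dosage approach
in real data would have to come from violations of random mating or
transmission equilibrium, which the simulator deliberately does not
model.

## Regression and weighting

Both models are fitted by weighted least squares. Sampling weights are
inverse inclusion probabilities from the stratified design, with survey-
weight ("pweight") semantics: point estimates solve the weighted normal
equations and the variance is the heteroskedasticity-consistent sandwich
built from weight-scaled scores `w_i e_i x_i` with an HC1-style
small-sample factor `n/(n-k)`. With unit weights this is OLS with robust
standard errors. The linear algebra is implemented directly (the
permutation and calibration loops need tens of thousands of small fits);
unit tests verify exact agreement with explicit normal equations and with
statsmodels' `WLS(...).fit(cov_type="HC1")`.

Wald p-values use the standard-normal reference, consistent with
combining z-statistics across studies. The equality hypothesis
`b_MD = b_PD` is a 1-df contrast on the robust covariance (the classical
covariance version is also reported); at the sample sizes involved the
normal and F references are numerically indistinguishable. Covariates are
offspring sex plus grandparental-ancestry proportions over nine strata
(Israel, Morocco, other North Africa, Iran, Iraq, Kurdistan, Yemen, other
Asia/Balkans, Ashkenazi), each proportion the fraction of the four
grandparents from that stratum, with the Ashkenazi stratum dropped as
reference to avoid complete multicollinearity. Constant covariate columns
are dropped with a warning; any other rank deficiency is an error naming
the collinear columns. Missing data are handled complete-case per trait.

## QC and trait preparation

Per-SNP filters, with strict-violation boundaries (a SNP exactly on a
threshold is retained): call rate < 0.95 excludes; Hardy-Weinberg
chi-square p below a Bonferroni cut (0.05 divided by the number of SNPs
at entry) excludes; mother-offspring Mendelian-inconsistency rate above
0.5% excludes. HWE is tested among mothers so transmitted alleles are not
double-counted. Using the entry SNP count in the Bonferroni denominator
makes the filter idempotent. Monomorphic SNPs get chi-square 0, p 1
rather than an error.

Traits: repeats are averaged on the raw scale (waist 2, blood pressure 3,
insulin 2), then insulin and triglycerides are natural-log transformed
(mean-then-log). Subjects on trait-relevant medication (diabetes, lipid-
lowering, BP-lowering) are excluded from the corresponding trait analyses
only, and all exclusions are logged with reasons.

## Discovery screen

A SNP moves forward if, for any examined trait, its maternal or paternal
Wald p beats the within-gene Bonferroni cut (0.05 / SNPs in that gene)
while the equality test is nominally significant (p < 0.05). Replication
significance uses 0.05 divided by the full discovery panel size (182
SNPs, threshold 2.75e-4).

## Permutation inference

Under no POE the maternal/paternal labelling of an offspring's alleles is
uninformative given the offspring genotype, so the null is built by
re-randomizing labels, refitting model 2 and recording the maternal Wald
z; the empirical two-sided p is `(r+1)/(B+1)`. The default scheme
(`swap`) flips each pair's `(g_md, g_pd)` with probability 1/2: dosage
magnitudes, offspring genotypes and the phenotype vector are preserved
exactly, so the additive signal survives (it lives in the sum) and only
the split under test is destroyed. Because the phenotype is independent
of the labelling under the null, this is a sign-flip randomization on a
regressor independent of the error, and it is calibrated: permutation
p-values are Kolmogorov-Smirnov-uniform both under the global null and
under a pure additive effect in the package's simulations.

Two alternative schemes exist for sensitivity analysis. `redraw` assigns
hard Bernoulli(1/2) origin labels to every single-minor-allele offspring;
replacing the ambiguous pairs' fractional dosages with hard labels
changes the dosage-column variance slightly, making it mildly
conservative when an additive effect is present. `redraw_mother`
additionally respects the mother's genotype (forced origins kept,
ambiguous pairs redrawn Bernoulli(1-MAF)); since forced labels retain
most of a true maternal signal, it is extremely conservative under the
alternative and is not a general-purpose null.

A deliberate property of all three schemes: because the additive
component is preserved, the empirical p for the maternal effect is
conservative relative to the parametric Wald p whenever the variant has
any additive association. A permutation that shuffles phenotypes instead
would reproduce the parametric p under the alternative but tests the
wrong null (it destroys the additive effect too), and is intentionally
not offered.

## Meta-analysis

Per-study z is beta/SE when the SE was reported directly, otherwise the
signed normal quantile of the two-sided p (sign from beta); SEs for
studies reporting only (beta, p) are back-calculated as |beta|/|z|. The
z-based combination uses sqrt(n) weights,
`z* = sum(sqrt(n_i) z_i)/sqrt(sum n_i)` — these weights reproduce the
published combined p-values from the bundled per-study rows to within
input rounding; an unweighted variant is available. Inverse-variance
pooling uses `w_i = 1/SE_i^2`. Both are fixed-effect; Cochran's Q is
emitted as a heterogeneity diagnostic only.

## Heritability

The parent-offspring estimator `h2 = 2 r` uses the weighted Pearson
correlation of mother and offspring trait values, optionally after
residualizing either side on covariates; estimates are clamped to [0, 1]
with a flag. The fraction of heritability attributed to one variant's POE
is the relative drop in h2 after residualizing the offspring trait on the
two parental-origin dosages (or on the additive genotype, for
comparison). Residualization also shrinks the offspring-trait variance by
the variant's explained variance, so the recovered fraction carries a
factor `sqrt(Var_o / (Var_o - b^2 pq))` relative to the naive covariance
share; the simulation oracle in the test suite accounts for this. This is
a simple estimator: it attributes the full mother-offspring covariance to
additive inheritance and ignores shared environment.

## Synthetic families

The generator draws mother and father genotypes i.i.d. from Hardy-
Weinberg proportions at the configured MAF (per-stratum overrides
possible), transmits one allele per parent uniformly at random, and
records the true origin of every offspring allele in a sealed truth block
that survives father-hiding — the simulator never applies the dosage
rule, so the estimator is always tested against an independent generative
process. The phenotype follows the model-2 mean structure plus Gaussian
noise.

Default conditions emulate a discovery-scale study: 1235 mother-offspring
pairs; one SNP at MAF 0.2 with a maternal-only effect of 1.4 BMI units
and no paternal effect; intercept 26 kg/m² and residual SD 4.5 kg/m²
(chosen as a realistic adult-BMI spread that makes an effect of this size
detectable at n ≈ 1200, since trait-level noise is not otherwise pinned
down); nine equiprobable ancestry strata with all four grandparents
sharing the family's stratum; sex Bernoulli(0.5) with a 1 kg/m² main
effect (all analyses adjust for sex); optional stratified sampling with
known inclusion probabilities (weights = 1/probability). All randomness
flows from one root seed through named substreams (genotypes, phenotype,
sampling), so stages can be re-run independently and a fixed seed fixes
every downstream number bit-for-bit.

What the generator does not emulate: linkage disequilibrium between SNPs,
assortative mating, transmission distortion, genotyping error, extended
pedigrees, shared-environment trait covariance, or non-Gaussian trait
tails. Passing tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to those real-data features; in
particular the unbiasedness of the expected-dosage mode depends on random
mating and transmission equilibrium holding.

## Numerical choices and scales

Problem sizes in the test suite and acceptance script were chosen to make
Monte-Carlo error small relative to the tolerances: closed-form genotype
frequency checks at n = 50 000 (4 Monte-Carlo SEs), parameter recovery
over 500 replicate studies at the discovery scale, equality-test
calibration over 2000 replicates at n = 600 against the exact central 99%
binomial interval, and permutation uniformity over 200 runs of 199
permutations. Empirical p-values use the add-one convention to avoid
zeros. Allele orientation re-estimates and flips coding whenever the
coded allele's frequency exceeds 0.5; ties in allele-frequency-based
minor-allele choice break deterministically by allele name. SNPs with
MAF < 0.01 or monomorphic are flagged and skipped in POE analysis
(the dosage split degenerates); the analyses this package targets involve
common variants (MAF > 0.06).

## Known limitations

No mixed-model/kinship correction for extended pedigrees (replication-
style designs are combined through summary statistics instead); no
genotype imputation, phasing, or use of siblings to resolve ambiguous
pairs; no random-effects meta-analysis; the heritability estimator is the
simple parent-offspring correlation form and its variant-attribution
depends on which covariates are residualized first.
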