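# Methods

## The combined main-effect + interaction test

For SNP dosage `g ∈ {0,1,2}` (minor-allele counts) the statistic has five
components.

**Main effect.** The null logistic model (intercept + confounders, no
genotype) is fit by IRLS; the genotype score is `U_0 = Σ_i g̃_i (y_i −
p̂_i)` where `g̃` is the genotype residualized on the covariates under the
null weights `ŵ_i = p̂_i(1−p̂_i)` (the *efficient* score), with expected
information `V_0 = Σ_i g̃_i² ŵ_i`. Using the efficient-score residual per
subject, rather than `g_i(y_i−p̂_i)`, makes the per-subject contributions
usable for empirical covariance estimation with the case-only components
(needed only when the structural zero is disabled by flag). A null fit
whose linear predictor diverges (quasi-separation) flags the component
failed rather than crashing.

**Case-only components.** Among the cases belonging to a component with
known active fraction `q`, the model is `logit P(active) = log(q/(1−q)) +
α + β g` with `α` free. With the intercept profiled, the constant offset
is absorbed and the score statistic for `β = 0` reduces to `U = Σ (g_i −
ḡ)(a_i − ā)` with `V = ā(1−ā) Σ (g_i − ḡ)²`. Keeping `α` free is the
load-bearing choice: with the intercept pinned at `logit(q)`, any
intervention *main* effect (which shifts `P(active | case)` away from `q`)
would bias the interaction score. The test-suite size study verifies this
directly: with intervention main effects of OR 0.8–1.25 present and no
genotype effect, the combined test's empirical size at α = 0.05 stays in
the binomial 99% band over 2,000 replicates.

Component case subsets: E-alone and E+P cases by hormone-trial
membership (mutually exclusive by design: post-hysterectomy vs with
uterus); DMQ restricts dietary-modification cases to the top quartile of
baseline percent energy from fat; calcium/vitamin D counts only cases
arising after its year-1 randomization (enforced by construction, since
only women event-free at year 1 are randomized).

**Covariance assembly.** Diagonal: expected informations. Structural
zeros: (main, case-only) pairs — asymptotic independence from
randomization — and the (E-alone, E+P) pair, zero outright by
disjointness. Remaining case-only pairs share cases, so their entry is
the empirical sandwich cross term `Σ_{i ∈ both} u_i^{(A)} u_i^{(B)}` over
per-subject score contributions. A unit test with artificially shared
randomization draws confirms the sandwich term tracks the true replicate
covariance when components are genuinely correlated.

**Combination.** `X² = Uᵀ V⁻ U` with the Moore–Penrose pseudo-inverse at
relative tolerance `1e-10`, restricted to non-degenerate components;
`df = rank` of the restriction. Degenerate components (monomorphic within
the relevant case set, single-arm case sets, empty subsets) reduce `df`
so genome-wide scans stay total.

## Ranking and FDR

SNPs are sorted by combined p ascending (ties broken by SNP id for
determinism). The default estimate is the plain rank-based `FDR_i = p_i ·
N / i`, *not* monotonized: the published top-20 table this package's
ranking is checked against prints a rank-1 FDR larger than the rank-2 FDR,
which identifies the estimator (a step-up adjustment forbids that
inversion). The Benjamini–Hochberg step-up variant (cumulative minimum
from the bottom, clipped at 1) is available by flag. Recomputing the
published FDR column from the printed p-values reproduces every row to
within the precision the 3-significant-figure inputs can support (~0.5%).

## Interaction profiles

The case-only genotype-stratified OR is `OR_g = (n_active,g /
n_control,g) / (q/(1−q))` with log-scale Wald 95% CIs, `se = √(1/n_a +
1/n_c)`. A single zero cell triggers the Haldane–Anscombe +0.5 correction
of both cells, flagged in the output; a genotype stratum with no cases
yields a missing OR and reduces the LRT df. The 2-df LRT compares the
offset model with genotype-level indicators (reference level 0) to the
intercept-only offset model; because the indicator model is saturated in
genotype levels, both maximized likelihoods have closed form (per-level
vs pooled active fractions), verified against numerical maximization to
1e-6. Joint multi-SNP case-only models are ordinary offset-logistic GLM
fits (statsmodels) with per-SNP Wald p-values; a perfectly collinear SNP
pair among cases is rejected with an error naming the pair.

## Genotype statistics

LD is the squared Pearson correlation of unphased dosages (composite LD)
— appropriate because the case-control sample is unphased — handled
pairwise-complete, undefined (NaN) for constant vectors, and invariant to
allele-coding flips. Locus binning scans position-sorted SNPs greedily: a
SNP joins the current locus if its r² with the locus's *first* SNP (the
anchor) is ≥ 0.2, else opens a new locus; chromosome changes always open
one. The anchor convention makes the rule deterministic where "adjacent
regions" alone would not. PCA standardizes each SNP by `√(2p̂(1−p̂))`
after mean-centering and mean-imputing missing dosages (EIGENSTRAT
convention, since the components are destined for stratification
adjustment), drops monomorphic columns, and reports variance fractions
against the total standardized variance.

## The synthetic trial generator

What it emulates: a ~68,000-subject default cohort (tests and examples
use 500–30,000) in a partial factorial design — hormone therapy split
into two non-overlapping trials by hysterectomy status, dietary
modification, and a calcium/vitamin D component randomized at year 1
among event-free subjects; assignment fractions default to 0.5/0.5/0.4/0.5
and participation rates are set so expected component sizes match the
published enrollment pattern. Outcomes follow a discrete-time (per-year)
logistic hazard with default baseline 0.004/year over 8 years of
follow-up, reproducing a realistic ~3% cumulative incidence; covariates
(log risk score, log BMI) and genotypes enter as log-ORs, and
genotype-by-intervention interaction is expressed as a per-genotype
triple of intervention ORs — the scale on which the stratified case-only
estimates are reported, so parameter-recovery tests close the loop
exactly. The OR scale throughout (rather than hazard ratios from full
survival machinery) matches the case-only estimand.

Genotypes: per-block Gaussian-copula haplotypes. Each LD block draws a
base allele frequency (±5% relative jitter per SNP — tightly linked SNPs
share similar frequencies, which also keeps high allelic-correlation
targets attainable); a latent AR(1) Gaussian is thresholded at the
frequency, with the latent correlation calibrated by bivariate-normal
inversion so the *allelic* correlation between adjacent SNPs hits the
target (default 0.9, giving adjacent r² ≈ 0.81). Two independent
haplotypes per subject give Hardy–Weinberg genotypes. Ancestry structure
is a per-group additive frequency shift (default four groups, 86%
majority), which the PCA separates on PC1. The default block layout
(1,764 two-SNP blocks + 1,460 singletons = 4,988 SNPs in 3,224 loci)
mirrors the SNP-to-locus ratio of the motivating scan.

Matching is greedy risk-set matching: cases in event-time order, exact
match on ethnicity, hysterectomy, and per-component membership, control
event-free at the case's event time (later cases may serve as controls),
nearest age within a ±2-year caliper, sampling without replacement;
unmatched cases are flagged, not fatal. The caliper and the greedy
algorithm are this package's choices — standard for nested case-control
designs but not uniquely determined by the design being emulated.

Receptor status (ER/PR) is assigned to cases independently of genotype at
configurable marginal rates; the label exists to exercise subtype
filters, not to encode biology.

All randomness flows from one master seed through named SeedSequence
substreams (covariates, genotypes, membership, outcomes, receptor), so
stage-level reproducibility survives code reordering within other stages.

**Direct case-control samplers.** Besides the full cohort generator, the
module provides `simulate_case_only_sample` (cases of one component:
`P(active|g) = expit(logit q + log OR_g)`, the exact induced distribution
of the cohort model) and `simulate_null_case_control` (a matched
case-control sample under the genotype-null with intervention main
effects present and trial-like membership overlap). Large-replication
studies — 2,000 null replicates for test size, 50,000 cases for OR
recovery — use these samplers at the scale the question is posed, while
cohort-level tests verify at smaller n that the full generator induces
the same distributions.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: accrual dynamics, adherence/drop-in, competing
risks, early stopping, true haplotype mosaics or allele-frequency spectra,
risk-score miscalibration, and genotype-correlated receptor subtypes.

## Discrimination analysis

Nested in-sample logistic models: M0 (confounders + four assignment
indicators), M1 (+ per-SNP indicators for one and two minor alleles), M2
(+ indicator × assignment products). AUC is the Mann–Whitney concordance
probability with ties counting ½ (exactly the all-pairs count, verified
against brute force). The ΔAUC test resamples matched *pairs* with
replacement — matching makes pairs, not subjects, the exchangeable unit —
refits both models per replicate, and uses a two-sided normal
approximation with the bootstrap SE (default 1,000 replicates; under 100
triggers a warning flag). AUCs are in-sample by default (a
cross-validation switch is out of scope here); with age a matching
factor, in-sample AUCs are expected to run low. A fit with
quasi-separation falls back to an L2-penalized IRLS refit (intercept
unpenalized, α = 0.01), flagged on the model object.

## Numerical choices

* IRLS null fits: tolerance 1e-10 on the step, divergence declared when
  the linear predictor exceeds 25 in absolute value.
* Pseudo-inverse / rank tolerance: 1e-10 relative to the largest
  eigenvalue.
* MAF ties at exactly 0.5: minor allele is the lexicographically smaller
  label, so dosage orientation is deterministic.
* Zero cells in OR tables: +0.5 on both cells, flagged; both-zero
  strata: missing.
* Copula calibration: bisection on the latent correlation with the
  bivariate normal CDF, cached by rounded frequency pair; targets beyond
  the Fréchet bound for the given marginals saturate at the attainable
  maximum.

## Known limitations

* The case-only components require the randomization-independence
  assumption; the machinery offers no protection if it is applied to
  non-randomized exposures.
* The sandwich cross terms are estimated from the realized sample and are
  noisy for small overlapping case sets; structural zeros are exact only
  under the design assumptions that justify them.
* The main-effect model is unconditional logistic with matching variables
  as covariates, not a conditional (matched-pair) likelihood.
* `bin_adjacent_loci` compares to a locus anchor; rules that compare each
  SNP to its immediate predecessor give different bins in long decaying
  blocks.
* The generator's outcome model is discrete in years; event times carry
  no within-year resolution, so risk-set matching ties are coarser than
  in continuous-time data.
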