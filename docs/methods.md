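# Methods

## Score construction

The weighted genetic risk score is the inner product of risk-allele
dosages with log-odds-ratio weights, GRS_i = Σ_j ln(OR_j)·g_ij; the risk
allele count is the unweighted sum. Per-SNP odds ratios are *allelic*
ORs from the case/control 2×2 allele-count cross-product, not
coefficients of a genotypic logistic fit: for biallelic counts the two
conventions differ only under deviation from allelic (log-additive)
risk, the allelic table is the standard way susceptibility ORs for
risk-allele panels are reported, and it is exactly testable by hand
arithmetic. Empty cells receive the Haldane–Anscombe +0.5 on all four
cells, so monomorphic SNPs still yield finite (if uninformative)
estimates. Confidence intervals are Wald on the log scale.

Individuals with any missing panel call are excluded everywhere before
scoring (`filter_complete`). This uniform rule trades a little sample
size for determinism: scores of partially genotyped individuals would
depend on which SNPs happened to be missing.

Dosages count the risk allele *as declared in the weight table*. VCF
records whose ALT is the risk allele contribute the ALT count, whose
REF is the risk allele contribute 2 − ALT count; a record whose allele
pair does not match the panel in either order is rejected outright —
silent strand flipping corrupts scores far more often than it rescues
records.

## Strata

Quartiles are rank-based with stable tie-breaking by input order and
the remainder of n/4 assigned to the lowest quartiles first, rather
than value-based cut-points: the RAC is an integer with heavy ties, and
value-based quartiles would be irreproducible across software. With
1001 cases this yields 251/250/250/250, so an extreme-quartile contrast
uses 501 individuals. Disease-enrichment contrasts use quartiles over
the combined cohort; subphenotype and survival contrasts among cases
use quartiles recomputed among cases only — an extreme-quartile case
comparison should not be diluted by where controls happen to fall.

Binned prevalence orders everyone by GRS and cuts fixed-size groups
(default 100), merging the remainder into the first, lowest-score
group, where prevalence is flattest and the distortion smallest.

## Regression models

Logistic fits use Newton–Raphson maximum likelihood (statsmodels) with
Wald CIs and p-values; ordinal outcomes (damage index levels, CKD
stages) use the proportional-odds cumulative-logit model, reporting one
common OR for being in a higher category. Perfect separation is raised
as an error, never returned as a silent huge estimate; in per-SNP scans
it is flagged per SNP and the scan continues. p-values are unadjusted
throughout — the analysis is a profile of one exposure against many
prespecified outcomes, not a discovery scan. Two covariate models are
supported: model 1 adjusts for age (age at last follow-up; the natural
"current age" in a retrospective cohort), model 2 additionally for age
at diagnosis to separate early-onset effects from cumulative-burden
effects.

ROC AUC uses the Mann–Whitney identity with tied pairs counted one
half; paired score comparisons use DeLong's structural-components
variance (equivalent to the paired jackknife) with a two-sided normal
p. Identical rankings give zero variance; p = 1 by convention.
Onset-age-stratified AUCs share the full control set across strata with
left-closed bin edges.

Predictive values apply Bayes' rule at an assumed population prevalence
rather than the cohort case fraction, since case/control sampling does
not estimate prevalence. Score ≥ cutoff counts as test-positive. The
inverse mode recovers sensitivity from (specificity, prevalence,
positive rate) via positive_rate = πs + (1−π)(1−sp), which lets
published screening summaries be completed into a full 2×2.

## Survival analysis

Time is age from birth, with affected individuals contributing their
event age and everyone else their age at last follow-up as censored;
there is no left truncation at diagnosis by default (events before
study entry are part of the retrospective record). The two-group test
is the Gehan–Breslow generalized Wilcoxon: pooled pair scores U_i,
statistic W = Σ U_i over the high group, permutation variance
n₀n₁/(N(N−1))·ΣU_i², normal two-sided p; for combined N ≤ 10 an exact
p is computed by exhaustive label enumeration. Early-survival weighting
suits score effects that act on onset timing. Hazard ratios come from a
Cox partial-likelihood fit with Efron tie handling (ages in years tie
often); the headline p reported next to each HR is the Gehan p, with
the Cox Wald p kept alongside. "Mean survival" per quartile is the
Kaplan–Meier 50% point — the age by which half the quartile is
affected — and mean event ages include affected individuals only, so
the two summaries answer different questions and can move in opposite
directions when censoring differs between quartiles.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at the scale of a ~1000-case / ~2800-control discovery cohort:

- **Genotypes**: 57 independent biallelic SNPs, risk-allele frequencies
  uniform on (0.05, 0.95), dosages binomial(2, p) (Hardy–Weinberg).
  True ORs are log-normal (location ln 1.15, scale 0.15 — the typical
  effect size of genome-wide-significant SLE loci); draws below 1 are
  re-oriented (OR → 1/OR, p → 1−p) because the risk allele is by
  definition the allele with OR ≥ 1.
- **Disease**: P(case) = logistic(α + Σ w_j g_ij) with α solved
  numerically so expected prevalence matches the case fraction of the
  emulated cohort (1001/3803). Under the defaults this produces
  approximately Gaussian case and control score distributions about one
  unit apart with SD near 1, AUC ≈ 0.75 — the regime real SLE panels
  occupy.
- **Onset**: age at diagnosis is a truncated-exponential
  proportional-hazards draw on (0, admin_censor_age], log-hazard linear
  in the centred GRS (default 0.13/unit, giving a few-year onset gap
  between extreme quartiles). Exponential (constant baseline hazard)
  event times keep recovery tests analytic; a Weibull shape would be
  the natural extension.
- **Events**: first damage, cardiovascular/arterial/venous events,
  ESRD, nephritis debut and death occur after diagnosis as exponential
  residuals with per-event GRS effects, censored at end of follow-up
  (death or administrative age 85). ESRD drives CKD stage 5 so the
  renal invariants hold by construction.
- **Subphenotypes**: ACR criteria and antiphospholipid serology are
  logistic in the GRS with baseline prevalences matching a
  well-characterised SLE cohort (renal disorder 34%, anti-dsDNA 62%,
  ...); serology is missing at random at a configurable rate (default
  20%) to mirror incomplete antibody testing.

What the generator does **not** emulate: linkage disequilibrium between
panel SNPs, population structure and relatedness, genotyping error,
secular trends in diagnosis and treatment, and correlation among
subphenotypes beyond what the shared GRS induces. Passing tests
therefore demonstrate that the estimators recover the generative
parameters under the model's assumptions — not that those assumptions
hold in any particular patient cohort.

All draws derive from one mandatory seed via deterministically spawned
substreams, so identical configurations produce byte-identical outputs.

## Numerical choices

- Logistic Newton tolerance 1e-10, max 100 iterations; coefficients
  with |β| > 25 are treated as separation. Ordinal fits use BFGS with
  gradient tolerance 1e-12 (agrees with the binary logit to ~1e-10 in
  the two-category reduction).
- Cox fits run at step precision 1e-9; |β| > 15 or SE > 50 flags a
  monotone likelihood.
- The disease-model intercept is bracketed by the score range ±50 and
  solved by Brent's method to 1e-10.
- Degenerate inputs are explicit: all-identical scores reject quartile
  assignment, a no-informative-pairs Gehan test returns statistic 0 /
  p 1 flagged, an all-censored group has an undefined median, an
  administrative censor age of 0 produces a fully censored cohort.

## Problem sizes

Unit and property tests run at n between a few hundred and 20 000;
recovery checks use n = 20 000 (allelic and logistic ORs) and n = 4000
(Cox HR), calibration batteries 1000 × n = 200 (Gehan type-I error) and
500 × n = 400 (quartile-OR coverage); qualitative discrimination
patterns average 50 seeded replicates at n = 1500. These sizes put
Monte-Carlo noise well inside the asserted bands while keeping the full
suite and the acceptance script each under a minute of compute.

## Known limitations

- The allelic-OR weighting ignores LD; correlated panel SNPs would
  double-count shared signal.
- DeLong variance across onset strata reuses the shared controls; the
  stratum AUCs are therefore correlated and their pairwise comparisons
  approximate.
- The proportional-odds model is fit without a parallel-lines test.
- Weights estimated and applied in the same cohort are optimistically
  biased for discrimination (winner's curse); external validation is
  the user's responsibility.
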