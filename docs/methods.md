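# Methods

This note documents the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Signature model

For each gene, expression is standardized per gene (mean 0, SD 1, computed
with ddof = 0 over the aligned cohort) and a univariate logistic regression
of binary mutation status on the standardized expression is fitted by
Newton's method (L-BFGS fallback when the Hessian is singular, e.g. under
complete separation). Standardization is not strictly required by the
model but makes slopes comparable across genes and stabilizes the
optimization; an optional `log2(x + 1)` pre-transform is available for
RSEM-like non-negative inputs and is off by default.

The association p-value is a likelihood-ratio test of the one-covariate
model against the intercept-only model (chi-square, 1 df). A Wald p-value
was deliberately not used: under complete or quasi-complete separation the
Wald statistic collapses toward zero (the Hauck–Donner effect), which
would assign the *smallest* weights to exactly the most strongly
associated genes. The likelihood-ratio statistic remains finite and
monotone in the strength of separation because the fitted log-likelihood
is bounded above by 0.

Weights are `w = min(-log10 p, 10) / 10`. The trim at 10 damps the
influence of astronomically small p-values; dividing by the fixed cap
(rather than per-signature min–max scaling) keeps weights on one absolute
scale across cancer types, at the cost that a signature need not contain a
weight of exactly 1. Genes with positive slope form the up profile,
negative slope the down profile. Degenerate genes (constant expression, or
a pathological fit) are recorded with beta 0 / p 1 and join neither
profile; that boundary is measure-zero for continuous data.

Gene-level p-values are used only as weights, never as significance calls,
so no multiple-testing correction is applied.

## Enrichment score

Given profile weights `w` in a sample's descending-expression gene order
(ties broken by gene id ascending for platform-independent
reproducibility), the score is the signed maximal deviation between the
cumulative foreground `F(i) = sum(w[:i]) / sum(w)` and cumulative
background `B(i) = sum(1 - w[:i]) / sum(1 - w)`, evaluated at the prefix
maximizing `|F - B|` with ties resolved to the smallest prefix. ES lies in
[-1, 1] by construction; genes outside the profile carry weight 0 and
contribute only to the background. Degenerate profiles (all weights 0, or
all 1) are rejected.

Normalization divides ES by the mean `|ES|` over `n_perm` random
re-assignments of the weight vector across rank positions (default
`n_perm = 1000`, seed 17). If that mean is below 1e-12 — possible only
when every ordering is equivalent, e.g. all-equal weights — NES is defined
as 0. Because the permutation null depends only on the multiset of weights
and the size of the gene universe, not on any sample's ordering, the
denominator is computed once per profile with a freshly seeded generator
and shared by all samples; this is distributionally identical to
per-sample permutation and makes identically-weighted profiles cancel
exactly in `pds = nes_up - nes_down`.

The absolute scale of these scores is a property of this normalization;
only orderings and signs are comparable across scoring schemes, and all
downstream analyses (splits, Cox, AUC, t-tests) use only those.

## Survival statistics

Log-rank tests, Cox fits and Kaplan–Meier curves are computed with
`lifelines`. Cox uses the Efron approximation for tied event times
(matching the R default) with Newton stopping tightened to 1e-12 so the
partial-likelihood optimum is resolved well below the 1e-6 comparisons
used in validation; a non-converging fit is retried with a 1e-6 ridge
penalty and flagged, never silently accepted.

Two splits are provided. The *fraction* split labels the `round(q*n)`
highest scores high (half-up rounding, score ties broken by sample id
ascending); with `q` equal to a cohort's mutation rate it mirrors
mutation-based group sizes for a like-for-like comparison of prognostic
value. The *median* split labels strictly-above-median scores high, so a
single threshold demarcates the groups and median-valued samples land in
the low group deterministically.

The meta combination is the sample-size-weighted Stouffer method,
`meta_z = sum(n_i z_i) / sqrt(sum(n_i^2))`, invariant to rescaling all
weights. The meta p is two-sided with the direction (sign of meta z)
reported separately; folding direction into a one-sided p would
double-count it. Dataset inclusion for meta-analysis requires strictly
more than 40 samples and strictly over 20% mortality; cancer-type
inclusion requires at least 20 mutant patients and at least a 10% mutation
rate (both inclusive). When overall and disease-specific survival both
exist, disease-specific is the intended input.

AUC is Mann–Whitney concordance computed from midranks, which handles
tied scores exactly. The drug-sensitivity comparison is a classic
equal-variance two-sided Student's t-test on Activity Area between the
median-split groups, applied only when at least 10 responses exist; Welch
correction was considered and not adopted, keeping the test literally the
named one.

## Synthetic cohorts

The generator plants the structure the analysis assumes: Gaussian
background expression (`noise_sd` 1), mutant samples shifted by
`effect` SD upward on the up-truth genes and downward on the down-truth
genes; Bernoulli mutation labels (default rate 0.47, the overall rate in
the packaged mutation table); true deficiency defined as the standardized
contrast mean(up truth) − mean(down truth); exponential survival with
hazard `baseline_hazard * exp(surv_log_hr * deficiency)` (defaults
0.01/month and 0.5 per SD) under independent exponential censoring whose
rate is solved by root finding so the expected censored fraction equals
`censor_rate` (default 0.3); and drug Activity Area
`max(0, 3.0 - drug_effect * deficiency + N(0, 0.5))`.

Gaussian expression rather than RSEM-like counts is a deliberate
simplification: every downstream step is rank- or regression-based, so
only the ordering geometry of the effect matters. Consequently the
synthetic validation demonstrates correctness of the statistical machinery
and end-to-end recovery of planted structure; it does not demonstrate
robustness to count noise models, normalization artifacts, batch effects,
tumor purity or stromal admixture, which real cohorts exhibit.

Default study sizes (2000 genes with 50+50 truth genes, n = 200 for
mutation recovery, n = 300 for prognosis, 1000 permutations, 1000 null
replicates for calibration) keep a full validation run at about half a
minute while leaving the statistical checks well-powered.

## Known limitations

- The score scale is tied to the permutation normalization; scores from
  differently normalized rank-enrichment schemes are not numerically
  comparable, only rank-comparable.
- Signature fitting is univariate per gene; correlated genes share credit
  and no covariate adjustment is attempted.
- Mutation calls arrive pre-binarized; classifying which mutations are
  protein-altering is upstream of this package.
- Real-cohort effects (platform differences, purity, subtype structure)
  are outside what the synthetic tests can certify.
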