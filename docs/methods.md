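# Methods

## The synthetic cohort generator

The generator emulates a community cohort of dementia-free adults aged
60+ with a single baseline biomarker assessment and up to 16 years of
follow-up. It is the test bed for every downstream stage; its defaults
define the study conditions the test suite and the acceptance script
run under.

**Biomarkers.** The six markers are drawn from a Gaussian copula. Each
target Spearman correlation ρ is mapped to the latent Pearson
correlation 2·sin(πρ/6) — for a bivariate normal, Spearman correlation
is (6/π)·arcsin(r/2) and is invariant under the monotone marginal
transforms, so sample Spearman correlations converge to the targets
exactly. The published matrix prints only the six strongest pairs
(0.86 p-tau217–p-tau181, 0.65 NfL–GFAP, 0.62 p-tau217–t-tau, 0.61
p-tau181–t-tau, 0.55 p-tau217–NfL, 0.53 p-tau181–NfL); the remaining
pairs are stated only to be positive and significant, and the defaults
fill them with weaker positive values (0.10–0.45). If a user-supplied
matrix maps to an indefinite latent matrix, an eigenvalue-clipping
nearest-positive-definite repair is applied and logged. Marginals are
log-normal for the five concentrations and logit-normal for the bounded
amyloid ratio; no marginal distributions are published, so the defaults
were chosen once to give medians and IQRs plausible for serum assays in
older adults (e.g. NfL median ≈ 16 pg/ml, amyloid ratio median ≈ 0.06)
and are configuration, not assertions about the source cohort.

**Covariates.** Age is truncated normal on [60, 101] (latent mean 72.8,
sd 10.6); sex, education, eight disease flags, APOE ε4 (with a 2.1%
missing fraction), MMSE and memory complaints are drawn independently
with the published margins. Only marginal structure is matched — joint
disease structure is out of scope. Biomarkers are independent of age
and the other covariates by design (see Limitations).

**Dementia process.** Time to dementia follows a Weibull
proportional-hazards model, H(t|x) = s·t^k·exp(βᵀx) with shape k = 1.4
(incidence rising with time in an ageing cohort), sampled by inverse
transform. Covariate log-hazards default to values giving the expected
direction and rough magnitude of the published adjusted associations
(age 0.9 per decade, APOE ε4 0.5, education protective). The biomarker
effect is threshold-shaped — flat below the marker's 25th percentile on
its standardized latent scale, then linear — mimicking the published
dose-response curves; the amyloid ratio enters with its z-score negated
(low values pathological) and a larger direct coefficient (0.30) than
its association strength alone would suggest, because its positive rank
correlation with the strongly hazard-increasing markers otherwise makes
the low-is-risk orientation anti-predictive; with the default value its
net discrimination is weakly positive (population AUC ≈ 0.53),
matching the weak published amyloid associations.

**Baseline-hazard calibration.** The Weibull scale s is not set
directly: `calibrate_baseline_hazard` runs Brent root-finding on log s
against a common-random-numbers Monte-Carlo estimate (default
n = 100,000, fixed internal seed) of the all-cause incidence rate over
the full covariate/biomarker distribution — including competing death,
dropout and administrative censoring — so that the expected events per
100 person-years equal the target (default 1.82). With all covariate
effects zero and shape 1 the process is exponential with censoring,
where events/person-years equals the rate exactly; the calibration
reproduces that closed form, which the tests assert.

**Competing death and censoring.** Death is an independent Weibull
(shape 1.5) whose log hazard depends on age and disease count but not
on biomarkers by default, so cause-specific censoring in the AD
analyses is non-informative unless a user configures biomarker
coefficients into the death model. Administrative censoring is at 16
years. Dementia events are labelled AD vs other dementia by an
independent Bernoulli draw (default 0.582), the simplest mechanism
consistent with a reported subtype fraction; there are no
subtype-specific hazards.

**Dropout.** Withdrawal is a baseline logistic decision (younger, more
educated, healthier and lower-NfL participants more likely to leave;
default marginal rate ≈ 6%), realized uniformly within the first six
months of follow-up. Making withdrawal an (almost) immediate
post-baseline event matters: if withdrawal could occur years into
follow-up, early dementia and death would preempt it, the observed
dropout flag would depend on the outcome path, and a baseline-only
retention model would be misspecified. With immediate withdrawal, the
inverse-probability weights from a logistic retention model on baseline
covariates and biomarkers are correctly specified, and the weighted Cox
estimate removes the selection bias — which is the property the IPW
acceptance test verifies, using an amplified-dropout configuration
(28% withdrawal driven by GFAP, an unadjusted NfL model) where the bias
is large enough to detect over 100 replicates at n = 2,000 each.

## Preprocessing conventions

Values below a marker's detection limit are replaced by exactly 0
(single-value, not-missing-at-random imputation), with the count
returned and logged. z-scores use the mean and sample (ddof = 1) sd of
the whole baseline sample, so subgroup analyses inherit the full-sample
scale. Quartiles cut at the 25th/50th/75th sample percentiles with
linear interpolation between order statistics (the source does not name
a percentile convention; this one is fixed and documented), and a value
exactly at a boundary goes to the lower quartile — deterministic and
order-independent. Participants missing any of the six biomarkers are
excluded from the analytical sample; missing covariates exclude a
participant only from operations that use them, and all percentages use
non-missing denominators.

## Survival stage

Partial-likelihood maximization is delegated to lifelines with Efron
tie handling (the only method lifelines implements; event times here
are continuous, so ties are rare) and tightened Newton convergence
(step norm < 1e-12), which makes small-sample fits agree with an
independent score-equation oracle to better than 1e-6. The restricted
cubic spline uses the standard 3-knot construction: columns x and
[(x−t₁)₊³ − (x−t₂)₊³(t₃−t₁)/(t₃−t₂) + (x−t₃)₊³(t₂−t₁)/(t₃−t₂)]/(t₃−t₁)²,
linear outside the boundary knots with continuous first and second
derivatives. Spline dose-response curves report
HR(x) = exp(η(x) − η(ref)) with delta-method pointwise CIs; the
reference is the marker's 25th percentile by default (the published
figures do not state theirs) and is exposed as an argument. The trend
test refits the model with the risk-ordered quartile index (1–4) as a
single continuous term and reports its Wald p (ordinal scores; quartile
medians would be an alternative the source does not distinguish). The
PH diagnostic regresses scaled Schoenfeld residuals on survival time
(identity transform, as described in the source); its null calibration
is verified under bounded follow-up, where the identity-transform score
test is well behaved — under unbounded heavy-tailed follow-up times the
asymptotic null is noticeably miscalibrated, which users porting the
diagnostic to uncensored designs should know. Death is treated as
censoring throughout (cause-specific hazards); subdistribution
(Fine–Gray) modelling is deliberately out of scope. IPW uses stabilized
weights P(retained)/P(retained|x), truncated at the 1st/99th percentiles
(logged), with a robust sandwich variance in the weighted fit.

## Cut-point and prediction stage

Candidate cut points are the unique observed marker values ("raw
biomarker cut-offs"); midpoints between order statistics were rejected
to keep cut-offs interpretable as observed concentrations. A value
exactly at the cut-off is positive; for the amyloid ratio, positive
means ≤ cut-off. Ties in Youden's index within a resample resolve to
the mean of the tied candidates (deterministic, unbiased between them).
Bootstrap resamples are drawn as multinomial case weights; single-class
resamples are redrawn and counted. Cut-offs are derived on the 80%
training split only and frozen before touching the test split; a
full-sample derivation is possible by passing the full frame but is not
the default.

At the 10-year horizon, a participant is positive if a qualifying event
occurred at t ≤ 10, negative if event-free with follow-up ≥ 10, and
otherwise excluded from classification (their horizon outcome is
unobserved; counting them as negatives would deflate sensitivity and
NPV). The alternative treat-as-negative convention is available behind
`censored_as_negative=True` since the source does not state its rule.
Single-biomarker AUCs use the continuous marker; combination predictors
use the ordinal count of elevated flags or binary at-least-k /
exactly-k / pair-AND rules over p-tau217, NfL and GFAP. AUC is the
tie-aware Mann-Whitney estimator with a DeLong CI by default
(participant bootstrap optional); confusion metrics carry
percentile-bootstrap CIs (2,000 resamples by default) and report
zero-denominator metrics as missing, never as 0. Two identities hold
exactly on every report and are asserted in the tests: accuracy =
sens·prev + spec·(1−prev) on the classified set, and PPV/NPV equal
their Bayes recombinations from sensitivity, specificity and
prevalence.

## Pipeline and determinism

`run_all` executes simulate → preprocess → describe → survival →
cut-points → predict, each stage communicating only through file
artifacts. Simulation, splitting, bootstrap and CI estimation use
separate seeds recorded in the manifest, so a stage can be re-run
without perturbing upstream randomness; fixed seeds give byte-identical
artifacts (asserted via manifest checksums). The demo configuration
used by the determinism test runs n = 2,148 with 500 bootstrap and 500
CI resamples; the cut-point default elsewhere is B = 5,000.

## Problem sizes used in validation

Copula calibration is checked at n = 100,000 (Spearman within ±0.01);
incidence-rate calibration at n = 50,000 (within 5% all-cause, 7% AD —
the AD rate adds Bernoulli subtype noise); Cox coefficient recovery at
n = 5,000 (within 3 SE); the binormal Youden threshold (two unit-variance
Gaussians at prevalence 1/2, population optimum at the midpoint of the
means) at n = 2,000 with B = 500; oracle equivalence exhaustively at
n ≤ 30 (cut points), n ≤ 200 (AUC) and n ≤ 6 (partial likelihood).

## What passing tests do and do not show

The generator matches the published marginal and rank-correlation
structure, incidence rates and censoring pattern, but real cohorts
differ in ways the defaults deliberately omit: biomarkers correlate
with age and comorbidity (here they are independent of covariates, so
synthetic discrimination — AUCs around 0.65–0.70 — runs below the
published 0.71–0.83, which partly reflects the age–biomarker channel);
disease flags are jointly structured, not independent; assay noise,
batch effects and fasting status are not modelled; dementia subtypes
have no subtype-specific biomarker profile. Passing tests therefore
validate the statistical machinery and its conventions, not the
clinical performance of any particular cut-off. Cut-offs estimated here
are properties of the synthetic distributions and must not be read as
clinical thresholds.
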