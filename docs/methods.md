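# Methods

This note records the modelling choices behind `mciscore`: what is
estimated, how the point system is constructed, what the synthetic
cohorts do and do not emulate, and the numerical conventions that matter
when reproducing results.

## Outcome definition

A participant enters the analysis cognitively normal (CN) at a month-0
baseline and is followed on a visit grid. The event is the **first**
visit diagnosed MCI; its time is that visit's month divided by 12 (time
is stored in years as month/12 exactly, so the 6-month grid loses
nothing to rounding). Later diagnoses — including reversions to CN after
a first MCI — do not change the outcome: the converted group is defined
by the first hit. Participants whose first non-CN diagnosis is AD are
excluded as direct converters (the CN→MCI process of interest never
produced an observable MCI state for them), as are participants with
only a baseline visit. Non-converters are censored at their last CN
visit. Visits with unrecognized diagnosis labels are mapped to an OTHER
category with a warning and ignored in the scan; they neither trigger
events nor extend follow-up.

Inclusion requires age 61–90 (both ends inclusive), a per-participant
missing rate of at most 10% over the nine tracked candidate risk factors
(age, race, education, APOE e4, family history of dementia, MMSE, CDR,
systolic and diastolic blood pressure), and a global CDR that is a valid
code (0, 0.5, 1, 2, 3) when present. Filters are applied per sex after
stratification; re-applying them to their own output is a no-op.

## Survival modelling

Cox proportional-hazards fits are delegated to statsmodels `PHReg`,
wrapped so that the package controls the contract: at least two events,
zero-variance covariates rejected up front, Efron tie handling by
default (ties are guaranteed by the visit grid) with Breslow available,
and age forcibly retained in multivariable models. Covariates are
standardized internally for conditioning and the coefficients rescaled
afterwards — the partial likelihood is invariant under this affine
reparameterization. Optimization runs BFGS first (plain Newton can
diverge from the flat start on this likelihood) and then polishes with
Newton from the BFGS optimum, keeping the polish only if it does not
reduce the log-likelihood. Monotone likelihoods (e.g. perfect
separation) are detected as an absurd effect size or standard error on
the standardized scale (>10) and reported as a divergence warning with
the coefficient capped at |β| = 20.

Default model covariates are age in years (continuous) and 0/1
indicators for APOE e4 carriage, MMSE ≤ 26 and CDR 0.5. Continuous
entry of MMSE/CDR is equally supported — every encoding travels with the
survival record — but the indicator coding matches the categories the
instrument ultimately uses, so it is the default. Covariate means Mᵢ are
arithmetic means (proportions for indicators) over the fitting cohort.

The overall survival function S₀(t) is the Kaplan–Meier product-limit
estimate (lifelines), exposed as a right-continuous step function;
subjects censored at t leave the risk set after the events at t.

## Point-system construction

The instrument follows the classic regression-to-points recipe:

1. βᵢ from the multivariable Cox model.
2. Clinically meaningful categories per factor; the reference value Wᵢ
   of a category is the within-category **median** of observed values
   for continuous factors, or the coded level for indicator factors.
   Default layout: age bands 61–70 / 71–80 / 81–90, APOE no/yes,
   MMSE >26 / ≤26, CDR 0.0 / 0.5 — all configurable.
3. The first (lowest-risk) category's W is the base reference W_iREF.
4. Dᵢ = βᵢ·(Wᵢ − W_iREF).
5. A base constant B represents one point. Default `B="auto"` uses the
   Framingham convention of half an age decade, B = β_age·5 years, which
   reproduces the familiar 0/2/4 age column.
6. Pᵢ = Dᵢ/B rounded to the nearest integer, ties away from zero.
7. Absolute risk at horizon t* (default 12 years, the maximum follow-up):

       risk(score) = 1 − S₀(t*) ^ exp( R + B·score − Σᵢβᵢ·Mᵢ ),

   with R = Σᵢβᵢ·W_iREF the reference-profile contribution. This reading
   of the reference term is the one that makes the map self-consistent:
   substituting the unrounded score Σᵢβᵢ(xᵢ − W_iREF)/B collapses the
   exponent to the mean-centred linear predictor Σᵢβᵢ(xᵢ − Mᵢ), so the
   unrounded-score risk equals the direct Cox prediction exactly (tested
   to 1e-10), and the rounded-score risk differs by at most the effect
   of half a point per factor in the exponent. It also makes the map
   invariant to which category is declared the reference.

The score→risk lookup is built by evaluating the map at every achievable
integer total and binning into 10-percentage-point bands. A fitted
instrument serializes to JSON with its categories, points, bands and
risk parameters.

### The packaged published instruments

The published female/male instruments ship as constants: per-factor
integer points (female 0/2/4 age, 2 APOE, 1 MMSE ≤26, 14 CDR 0.5; male
0/2/4, 3, 5, 9) and the published score→risk bands. Their S₀(t*) and β
were not published, so these instruments report risk bands, not exact
probabilities, and `absolute_risk` on them raises. Two quirks are worth
knowing:

- The published table's footnote states a maximum total of 23, but the
  table cells sum to 21 for both sexes; the package follows the cells.
- The female points are gapped: because CDR 0.5 contributes 14 at once,
  totals 8–13 are unreachable, so the 21–30% band (scores 9–12) cannot
  be produced by any category combination. The package surfaces this
  via the risk grid rather than papering over it.

Scoring requires age in [61, 90] and CDR ∈ {0, 0.5}; anything else is a
hard error, since the instruments define no categories there.

## Evaluation

- **AUC** is tie-corrected pairwise concordance (midranks). The CI uses
  the DeLong placement variance with a normal approximation, clipped to
  [0, 1].
- **Youden cutoff** maximizes sensitivity + specificity − 1 over the
  observed score values, with "high risk" meaning value ≥ cutoff (so the
  reported cutoff itself is high-risk) and ties broken toward the lowest
  threshold.
- **Hosmer–Lemeshow** groups by predicted-risk deciles (configurable
  count, or explicit groups such as score bands), computes
  χ² = Σ (O − nπ̄)²/(nπ̄(1−π̄)) with df = groups − 2 (floored at 1), and
  merges groups whose mean prediction is exactly 0 or 1 into a
  neighbour. When validating an instrument, predicted 12-year risks are
  compared with raw observed event fractions; subjects censored before
  the horizon deflate the observed rates, so on heavily-censored data
  this check is conservative about calibration.
- **Dichotomized C** for a binary high/low classification is
  (sensitivity + specificity)/2, which equals the AUC of the binary
  predictor.
- **External validation** scores a prepared cohort, ranks by absolute
  risk when the instrument has risk parameters and by total score
  otherwise (the two orderings are monotonically equivalent; the
  cutoff's units differ), and runs the full battery at a supplied or
  Youden-chosen cutoff. Sex differences in predicted risk use Welch's
  unequal-variance t-test.

## Synthetic cohorts

The generator emulates the *structure* of an aging-cohort diagnostic
stream, not any real dataset: ages uniform on 61–90; APOE e4 carriage
Bernoulli(0.3); education uniform 8–20 years; MMSE = 30 − Binomial(6,
0.3) floored at 24; CDR 0.5 with probability 0.1; family history
Bernoulli(0.4); blood pressures normal (133±17 / 74±10 mmHg); race
categorical. Conversion times are drawn from h(t) = h₀·exp(β·x) with
exponential (default) or Weibull baseline; censoring is administrative
at 12 years plus, with probability 0.2, a uniform non-informative
dropout; observed diagnoses land on a 6-month visit grid (the first
scheduled visit at or after the latent conversion time carries MCI, so
observed times are biased upward by up to one interval — recovery
tolerances account for this). Baseline-only and direct-to-AD
contaminants are appended at configurable rates (default 5% each), and
light MCAR missingness (2% per non-core field) exercises the 10% filter.

Default true coefficients make CDR dominate, mirroring the published
instruments qualitatively: hazard ratios of 2 per age decade for both
sexes; APOE 1.5 (F) / 2.0 (M); MMSE ≤26 1.3 (F) / 2.7 (M); CDR 0.5
8 (F) / 6 (M). Baseline rates (0.00743/y female, 0.01156/y male) were
solved in closed form so the expected 12-year conversion fraction over
the covariate and censoring distributions is 15% and 23% respectively,
the rates characteristic of the study populations this emulates.

What passing tests on these cohorts shows: the pipeline's estimators
recover known truth under a correctly specified proportional-hazards
world with independent covariates and non-informative censoring. What
they do not show: behaviour under real covariate correlations,
informative dropout, diagnostic noise, or site effects — none of which
the generator models.

## Problem sizes and numerics

Unit tests run on cohorts of a few hundred participants per sex;
parameter-recovery checks use 20 seeds at n = 2000 per sex and require
fitted coefficients within 3 standard errors of truth in ≥95% of
(seed, covariate) pairs and instrument points within ±1 of the true
pattern. Oracle checks (pairwise-concordance AUC, exhaustive Youden
search, grid-search partial-likelihood maximizer) run on instances of
n ≤ 200 where brute force is exact. Tolerances: 1e-4 against the
grid-search Cox oracle, 1e-8 for Efron/Breslow agreement on tie-free
data, 1e-9 for hand-computed statistics, 1e-10 for the score/risk
algebraic identity.

## Known limitations

- No time-varying covariates, stratified Cox, or proportional-hazards
  diagnostics; no imputation (complete-case fitting) and no multiple
  visit-mode handling.
- The published instruments cannot produce absolute risks, only bands,
  because their S₀ and β are unavailable; the package does not attempt
  to re-estimate them.
- The Hosmer–Lemeshow comparison against raw event fractions ignores
  censoring before the horizon (see above).
- Risk-grid export is data-only; plotting is left to the caller.
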