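# mciscore

Sex-specific point-based risk scoring for the conversion of cognitively
normal (CN) older adults to mild cognitive impairment (MCI).

Clinicians and epidemiologists who follow aging cohorts want a bedside
instrument: a handful of integer points per risk factor whose sum maps to
an absolute probability of converting to MCI within a horizon. This
package implements the full derivation pipeline for such an instrument
from longitudinal diagnostic records, separately for women and men, and
ships the published female/male instruments (SRSS-CNMCI) as packaged
constants ready to score profiles.

## What it does

1. **Cohort assembly** — parse visit streams (one row per participant-visit
   with a CN/MCI/AD diagnosis), derive time-to-conversion outcomes with a
   first-hit definition (time to the first MCI diagnosis; non-converters
   censored at the last CN visit; direct CN→AD converters and
   baseline-only records excluded), filter to ages 61–90 with ≤10%
   missing covariates, stratify by sex, and report standardized-difference
   covariate balance.
2. **Survival modelling** — sex-stratified Cox proportional-hazards fits
   (Efron tie correction by default; age always retained) and the overall
   Kaplan–Meier survival function S₀(t).
3. **Point-system construction** (Sullivan/Framingham method) — for each
   factor *i* with coefficient βᵢ, categories with reference values Wᵢ
   (within-category medians) and base reference W_iREF, the points are

       Pᵢ = round( βᵢ·(Wᵢ − W_iREF) / B ),

   with B one point's worth of log-hazard (default: half an age decade,
   β_age·5). A total score maps to absolute risk through

       risk(score) = 1 − S₀(t*) ^ exp( Σᵢβᵢ·W_iREF + B·score − Σᵢβᵢ·Mᵢ ),

   where Mᵢ is the cohort mean/proportion of factor *i* and t* = 12 years.
   At the unrounded score this is algebraically identical to the direct
   Cox prediction.
4. **Evaluation** — AUC (tie-corrected concordance, DeLong CI), the
   Youden-optimal high/low-risk cutoff, the dichotomized C-statistic,
   Hosmer–Lemeshow calibration, external validation, Welch comparison of
   predicted risks between the sexes, and the age distribution of
   high-risk participants.
5. **Synthetic cohorts** — a seeded generator producing ADNI-like visit
   grids (6-month spacing, 12-year follow-up) from a known
   proportional-hazards truth, with contaminant records to exercise every
   exclusion filter. All analyses here run on these synthetic cohorts.

## Worked example: scoring with the published instruments

```python
from mciscore import BaselineProfile, apply_instrument, published_instruments

female, male = published_instruments()

profile = BaselineProfile(participant_id="p1", sex="female", age=85,
                          apoe4_carrier=True, mmse=25, cdr_global=0.5)
pred = apply_instrument(profile, female)
print(pred.points, pred.total, pred.band)
```

prints

```
{'age': 4, 'apoe4': 2, 'mmse_le26': 1, 'cdr05': 14} 21 >50%
```

an 85-year-old female APOE e4 carrier with MMSE 25 and CDR 0.5 scores
4 + 2 + 1 + 14 = 21 points, in the open-ended top band: predicted
12-year conversion risk above 50%. The published instruments carry
integer points and score→risk bands only (their underlying S₀ and β were
never published), so they band rather than compute exact risks;
instruments you derive yourself carry the full absolute-risk map.

## The analysis, end to end

The numbered drivers under `analysis/` replay the whole study on
synthetic cohorts and write their tables under `results/`:

```sh
python analysis/01_simulate_cohorts.py      # derivation + external cohorts
python analysis/02_derive_cohorts.py        # outcomes, filters, balance
python analysis/03_fit_survival_models.py   # univariate + multivariable Cox, KM
python analysis/04_build_instruments.py     # point instruments, grids, tables
python analysis/05_evaluate_and_validate.py # ROC/Youden/HL, external validation
```

On the default cohorts (seeds fixed in the scripts) the final step prints,
among other lines:

```
female derivation: AUC 0.729 (95% CI 0.650-0.809), cutoff 17.6% risk (J=0.333), dichotomized C 0.666
male derivation: AUC 0.718 (95% CI 0.645-0.791), cutoff 24.0% risk (J=0.321), dichotomized C 0.660
predicted 12-year risk, female vs male: 18.3% vs 28.2% (Welch t=-6.87, p=1.85e-11)
```

A `mciscore` console command exposes the same steps for your own CSVs
(`simulate`, `build-score`, `apply`, `grid`, `evaluate`, `validate`);
`mciscore --help` lists them.

## Layout

- `src/mciscore/` — the library: `cohort`, `survival`, `scoring`,
  `evaluation`, `synthetic`, `cli`.
- `analysis/` — the numbered study drivers above.
- `tests/` — pytest suite, including brute-force oracles
  (`tests/oracles.py`) for the concordance, cutoff and partial-likelihood
  code paths.
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  conventions and known limitations.
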