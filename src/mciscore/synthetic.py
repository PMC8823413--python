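"""Synthetic longitudinal cohorts with known proportional-hazards truth.

Emulates the structure of an aging-cohort diagnostic stream: baseline
covariates drawn per sex, a latent conversion time from a proportional
hazards model h(t) = h0(t)·exp(β·x), administrative censoring at 12 years
plus optional non-informative dropout, and visits on a 6-month grid — the
first scheduled visit at or after the latent conversion time carries the
MCI diagnosis.  Contaminant records (baseline-only participants and direct
CN→AD converters) are injected at configurable rates to exercise the
exclusion filters.  Every draw flows from one seeded generator, so a spec
determines its output byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .cohort import BaselineProfile, SurvivalRecord
from .exceptions import InputError

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "write_cohort", "prepare_cohorts", "make_worked_fixtures"]


def _default_beta_female() -> dict[str, float]:
    # hazard ratios: 2 per age decade, 1.5 APOE e4, 1.3 MMSE<=26, 8 CDR 0.5
    return {"age": log(2) / 10, "apoe4": log(1.5), "mmse_le26": log(1.3), "cdr05": log(8.0)}


def _default_beta_male() -> dict[str, float]:
    # hazard ratios: 2 per age decade, 2 APOE e4, 2.7 MMSE<=26, 6 CDR 0.5
    return {"age": log(2) / 10, "apoe4": log(2.0), "mmse_le26": log(2.7), "cdr05": log(6.0)}


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic study cohort.

    Covariate distributions mirror a community aging cohort (ages uniform
    on 61–90, 30% APOE e4 carriage, MMSE near ceiling, 10% questionable
    CDR); the true log-hazard coefficients act on the same encodings the
    pipeline fits (age in years centred at ``age_center``, 0/1 indicators
    for the rest).  Baseline hazard rates are set so the expected 12-year
    conversion fraction lands near the ~15% (female) and ~23% (male) seen
    in the study population this emulates.
    """

    n_female: int = 300
    n_male: int = 300
    seed: int = 0
    # covariates
    age_range: tuple[int, int] = (61, 90)
    apoe4_p: float = 0.3
    education_range: tuple[int, int] = (8, 20)
    mmse_binomial: tuple[int, float] = (6, 0.3)  # MMSE = 30 - Binomial(n, p), floor 24
    mmse_min: int = 24
    cdr05_p: float = 0.1
    fhd_p: float = 0.4
    sbp: tuple[float, float] = (133.0, 17.0)
    dbp: tuple[float, float] = (74.0, 10.0)
    race_levels: tuple[str, ...] = ("White", "Black", "Asian", "Other")
    race_probs: tuple[float, ...] = (0.85, 0.08, 0.04, 0.03)
    # hazard
    beta_female: dict[str, float] = field(default_factory=_default_beta_female)
    beta_male: dict[str, float] = field(default_factory=_default_beta_male)
    age_center: float = 75.0
    baseline_hazard: str = "exponential"  # or "weibull"
    # per-year exponential rates solved so the expected conversion fraction
    # (over the covariate distribution and censoring scheme) is 0.15 / 0.23
    hazard_rate_female: float = 0.00743
    hazard_rate_male: float = 0.01156
    weibull_shape: float = 1.0
    # observation scheme
    censor_years: float = 12.0
    dropout_rate: float = 0.2
    visit_interval_months: int = 6
    # contamination and missingness
    baseline_only_rate: float = 0.05
    direct_to_ad_rate: float = 0.05
    missing_rate: float = 0.02  # MCAR on non-core fields

    def __post_init__(self):
        for name in ("apoe4_p", "cdr05_p", "fhd_p", "dropout_rate",
                     "baseline_only_rate", "direct_to_ad_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        if self.visit_interval_months <= 0:
            raise InputError("visit interval must be positive")


@dataclass
class SyntheticCohort:
    """Generated tables plus the ground truth behind them."""

    visits: pd.DataFrame  # participant_id, month, diagnosis
    baseline: pd.DataFrame  # one row per participant
    truth: pd.DataFrame  # true event time, censor time, linear predictor, flags
    spec: CohortSpec


_MISSABLE = ("education", "family_history_dementia", "systolic_bp", "diastolic_bp", "race")


def _draw_profile(rng: np.random.Generator, spec: CohortSpec, pid: str, sex: str) -> dict:
    n_mmse, p_mmse = spec.mmse_binomial
    mmse = max(spec.mmse_min, 30 - int(rng.binomial(n_mmse, p_mmse)))
    return {
        "participant_id": pid,
        "sex": sex,
        "age": int(rng.integers(spec.age_range[0], spec.age_range[1] + 1)),
        "education": int(rng.integers(spec.education_range[0], spec.education_range[1] + 1)),
        "apoe4_carrier": bool(rng.random() < spec.apoe4_p),
        "family_history_dementia": bool(rng.random() < spec.fhd_p),
        "mmse": mmse,
        "cdr_global": 0.5 if rng.random() < spec.cdr05_p else 0.0,
        "systolic_bp": round(float(rng.normal(*spec.sbp)), 1),
        "diastolic_bp": round(float(rng.normal(*spec.dbp)), 1),
        "race": spec.race_levels[int(rng.choice(len(spec.race_levels), p=spec.race_probs))],
    }


def _linear_predictor(profile: dict, beta: dict[str, float], age_center: float) -> float:
    return (
        beta["age"] * (profile["age"] - age_center)
        + beta["apoe4"] * profile["apoe4_carrier"]
        + beta["mmse_le26"] * (profile["mmse"] <= 26)
        + beta["cdr05"] * (profile["cdr_global"] == 0.5)
    )


def _draw_event_time(rng: np.random.Generator, spec: CohortSpec, rate: float, lp: float) -> float:
    e = rng.exponential(1.0)  # unit-rate cumulative hazard draw
    if spec.baseline_hazard == "exponential":
        return e / (rate * np.exp(lp))
    if spec.baseline_hazard == "weibull":
        # H0(t) = (rate * t) ** shape
        return (e / np.exp(lp)) ** (1.0 / spec.weibull_shape) / rate
    raise InputError(f"unknown baseline hazard {spec.baseline_hazard!r}")


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate visits, baseline and ground-truth tables for one spec.

    Per participant: draw covariates, a latent conversion time T from the
    proportional-hazards model and a censoring time C (administrative cap,
    possibly an earlier uniform dropout); the first grid visit at or after
    min(T, C) carries the MCI diagnosis when T <= C, otherwise the record
    ends censored at the last CN visit.  Contaminants are appended after
    the regular participants with flags in the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    interval_y = spec.visit_interval_months / 12.0
    grid_months = np.arange(0, int(spec.censor_years * 12) + 1, spec.visit_interval_months)

    visit_rows, base_rows, truth_rows = [], [], []
    expected_events = 0.0

    for sex, n, beta, rate in (
        ("female", spec.n_female, spec.beta_female, spec.hazard_rate_female),
        ("male", spec.n_male, spec.beta_male, spec.hazard_rate_male),
    ):
        prefix = "F" if sex == "female" else "M"
        n_base_only = int(round(spec.baseline_only_rate * n))
        n_direct_ad = int(round(spec.direct_to_ad_rate * n))
        total = n + n_base_only + n_direct_ad
        for i in range(total):
            pid = f"{prefix}{i:05d}"
            profile = _draw_profile(rng, spec, pid, sex)
            lp = _linear_predictor(profile, beta, spec.age_center)
            contaminant = ""
            if i >= n + n_base_only:
                contaminant = "direct-to-AD"
            elif i >= n:
                contaminant = "baseline-only"

            t_event = _draw_event_time(rng, spec, rate, lp)
            c = spec.censor_years
            if rng.random() < spec.dropout_rate:
                c = min(c, float(rng.uniform(interval_y, spec.censor_years)))

            if contaminant == "baseline-only":
                months, dx = [0], ["CN"]
            elif contaminant == "direct-to-AD":
                m_ad = int(rng.choice(grid_months[1:]))
                months = [int(m) for m in grid_months if m <= m_ad]
                dx = ["CN"] * (len(months) - 1) + ["AD"]
            elif t_event <= c:
                m_event = int(grid_months[np.searchsorted(grid_months, t_event * 12.0)])
                months = [int(m) for m in grid_months if m <= m_event]
                dx = ["CN"] * (len(months) - 1) + ["MCI"]
                expected_events += 1
            else:
                m_last = int(grid_months[grid_months <= c * 12.0].max())
                months = [int(m) for m in grid_months if m <= m_last]
                dx = ["CN"] * len(months)

            for m, d in zip(months, dx):
                visit_rows.append({"participant_id": pid, "month": m, "diagnosis": d})
            base_rows.append(profile)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "sex": sex,
                    "true_event_time": t_event,
                    "censor_time": c,
                    "linear_predictor": lp,
                    "contaminant": contaminant,
                }
            )

    if expected_events == 0:
        warnings.warn("spec produced no conversion events", stacklevel=2)

    baseline = pd.DataFrame(base_rows)
    if spec.missing_rate > 0:
        for col in _MISSABLE:
            mask = rng.random(len(baseline)) < spec.missing_rate
            if mask.any():
                baseline[col] = baseline[col].astype(object)
                baseline.loc[mask, col] = None

    return SyntheticCohort(
        visits=pd.DataFrame(visit_rows),
        baseline=baseline,
        truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


def write_cohort(cohort: SyntheticCohort, outdir, prefix: str = "cohort") -> dict[str, str]:
    """Write visits/baseline/truth CSVs with a seed-bearing metadata header."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    header = f"# seed={cohort.spec.seed} n_female={cohort.spec.n_female} n_male={cohort.spec.n_male}\n"
    for name in ("visits", "baseline", "truth"):
        path = os.path.join(outdir, f"{prefix}_{name}.csv")
        with open(path, "w") as fh:
            fh.write(header)
            getattr(cohort, name).to_csv(fh, index=False)
        paths[name] = path
    return paths


def prepare_cohorts(cohort: SyntheticCohort, **inclusion_kwargs):
    """Run a generated cohort through outcome derivation and inclusion filters.

    Returns the sex-stratified :class:`~mciscore.cohort.SexCohorts` ready
    for model fitting, exactly as reading the written CSVs would.
    """
    from .cohort import apply_inclusion, derive_outcomes, profiles_from_dataframe, visits_from_dataframe

    visits = visits_from_dataframe(cohort.visits)
    records, exclusions = derive_outcomes(visits)
    profiles = profiles_from_dataframe(cohort.baseline)
    cohorts = apply_inclusion(profiles, records, **inclusion_kwargs)
    cohorts.exclusions = exclusions + cohorts.exclusions
    return cohorts


# ---------------------------------------------------------------------------
# Hand-checkable worked fixtures


def make_worked_fixtures() -> dict[str, object]:
    """Small deterministic fixtures matching the package's worked examples.

    - ``inclusion_profiles`` / ``inclusion_records``: 10 participants of
      whom 2 are outside the 61–90 age range and 1 exceeds the 10% missing
      rate, so the inclusion filters retain 7.
    - ``km_events_only``: events at 1, 2, 3, 4 years (S(2.5) = 0.5).
    - ``km_mixed``: n=4 with event@1y, censored@2y, event@3y, censored@4y
      (S(3) = 3/4 · 1/2 = 0.375).
    - ``hl_two_group``: two calibration groups of 5 with mean predicted
      risks 0.2 and 0.6 and observed events 1 and 4 (χ² = 1/1.2).
    - ``grid_profiles``: 24 baseline profiles per sex covering every
      category combination of the published instruments.
    """
    fx: dict[str, object] = {}

    def prof(pid, sex, age, apoe, mmse, cdr, **kw):
        defaults = dict(education=16, family_history_dementia=False,
                        systolic_bp=130.0, diastolic_bp=75.0, race="White")
        defaults.update(kw)
        return BaselineProfile(
            participant_id=pid, sex=sex, age=age, apoe4_carrier=apoe,
            mmse=mmse, cdr_global=cdr, **defaults,
        )

    profiles = [
        prof("W01", "female", 65, False, 29, 0.0),
        prof("W02", "female", 72, True, 27, 0.0),
        prof("W03", "female", 85, False, 25, 0.5),
        prof("W04", "male", 61, False, 30, 0.0),
        prof("W05", "male", 78, True, 26, 0.0),
        prof("W06", "male", 90, False, 28, 0.5),
        prof("W07", "female", 70, True, 29, 0.0),
        prof("W08", "male", 60, False, 29, 0.0),  # below age range
        prof("W09", "female", 95, False, 28, 0.0),  # above age range
        # 2 of the 9 tracked factors missing -> rate 2/9 > 0.10
        prof("W10", "male", 75, None, 28, 0.0, education=None),
    ]
    records = [
        SurvivalRecord(p.participant_id, p.sex, time=2.0, event=(i % 3 == 0))
        for i, p in enumerate(profiles)
    ]
    fx["inclusion_profiles"] = profiles
    fx["inclusion_records"] = records

    fx["km_events_only"] = [
        SurvivalRecord(f"K{i}", None, time=float(t), event=True) for i, t in enumerate((1, 2, 3, 4))
    ]
    fx["km_mixed"] = [
        SurvivalRecord("Q0", None, time=1.0, event=True),
        SurvivalRecord("Q1", None, time=2.0, event=False),
        SurvivalRecord("Q2", None, time=3.0, event=True),
        SurvivalRecord("Q3", None, time=4.0, event=False),
    ]

    fx["hl_two_group"] = {
        "predicted": np.array([0.2] * 5 + [0.6] * 5),
        "observed": np.array([1, 0, 0, 0, 0, 1, 1, 1, 1, 0], dtype=bool),
        "group_index": np.array([0] * 5 + [1] * 5),
    }

    grid = {}
    for sex in ("female", "male"):
        rows = []
        i = 0
        for age in (65, 75, 85):
            for apoe in (False, True):
                for mmse in (28, 25):
                    for cdr in (0.0, 0.5):
                        rows.append(prof(f"G{sex[0].upper()}{i:02d}", sex, age, apoe, mmse, cdr))
                        i += 1
        grid[sex] = rows
    fx["grid_profiles"] = grid
    return fx
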