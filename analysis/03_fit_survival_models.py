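"""Fit sex-stratified Cox models and the overall Kaplan-Meier curves.

Per sex: a univariate screen over all candidate risk factors, then the
multivariable model on age (forced), APOE e4, MMSE<=26 and CDR 0.5, and
the cohort Kaplan-Meier survival function that later anchors the
absolute-risk map.  Model summaries and curves land in results/.
"""

import pathlib

import pandas as pd

from mciscore import SurvivalRecord, fit_cox, km_survival, univariate_screen

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

SCREEN = ["age", "education", "apoe4", "fhd", "mmse", "cdr", "sbp", "dbp"]
MODEL = ["age", "apoe4", "mmse_le26", "cdr05"]


def records_from_csv(path):
    df = pd.read_csv(path)
    covs = [c for c in df.columns if c not in ("participant_id", "sex", "time", "event")]
    return [
        SurvivalRecord(str(r.participant_id), str(r.sex), float(r.time), bool(r.event),
                       {c: float(getattr(r, c)) for c in covs})
        for r in df.itertuples(index=False)
    ]


for sex in ("female", "male"):
    records = records_from_csv(OUT / f"derivation_cohort_{sex}.csv")
    complete = [r for r in records
                if all(r.covariates.get(c) == r.covariates.get(c) for c in SCREEN)]
    print(f"{sex}: {len(records)} records, {len(complete)} complete cases for screening")

    screen = univariate_screen(complete, SCREEN)
    screen.to_csv(OUT / f"univariate_{sex}.csv", index=False)
    hits = screen[screen.p < 0.05].covariate.tolist()
    print(f"  univariate p<0.05: {hits}")

    model = fit_cox(records, MODEL, forced=("age",))
    summary = model.summary()
    summary.to_csv(OUT / f"multivariable_{sex}.csv", index=False)
    print("  multivariable model:")
    for row in summary.itertuples(index=False):
        print(f"    {row.covariate:<10} beta={row.coef:+.3f}  HR={row.hr:.2f} "
              f"({row.hr_ci_low:.2f}-{row.hr_ci_high:.2f})  p={row.p:.3g}")

    curve = km_survival(records)
    curve.to_dataframe().to_csv(OUT / f"km_{sex}.csv", index=False)
    print(f"  S0(12y) = {curve.survival_at(12.0):.3f}\n")
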