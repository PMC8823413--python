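"""Evaluate the fitted instruments and validate them on the external cohort.

Per sex: discrimination (AUC with DeLong CI), the Youden-optimal
high/low-risk cutoff, the dichotomized C-statistic at that cutoff, and
Hosmer-Lemeshow calibration over score bands — first on the derivation
cohort, then on the independent external cohort using the derivation
cutoff.  Also reports the Welch comparison of predicted risks between the
sexes and the age distribution of high-risk participants.
"""

import json
import pathlib

import pandas as pd

from mciscore import (
    Instrument,
    SurvivalRecord,
    apply_instrument,
    external_validate,
    high_risk_age_distribution,
    read_baseline,
    sex_risk_compare,
)

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
DATA = OUT / "data"


def records_from_csv(path):
    df = pd.read_csv(path)
    covs = [c for c in df.columns if c not in ("participant_id", "sex", "time", "event")]
    return [
        SurvivalRecord(str(r.participant_id), str(r.sex), float(r.time), bool(r.event),
                       {c: float(getattr(r, c)) for c in covs})
        for r in df.itertuples(index=False)
    ]


profiles = {"derivation": {}, "external": {}}
for label in profiles:
    for p in read_baseline(DATA / f"{label}_baseline.csv"):
        profiles[label][p.participant_id] = p

risks_by_sex = {}
cutoffs = {}
for sex in ("female", "male"):
    inst = Instrument.from_json(OUT / f"instrument_{sex}.json")
    records = records_from_csv(OUT / f"derivation_cohort_{sex}.csv")

    report = external_validate(inst, profiles["derivation"], records)
    cutoffs[sex] = report.cutoff
    with open(OUT / f"evaluation_{sex}.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    report.roc_points.to_csv(OUT / f"roc_{sex}.csv", index=False)
    if report.calibration_table is not None:
        report.calibration_table.to_csv(OUT / f"calibration_{sex}.csv", index=False)
    print(f"{sex} derivation: AUC {report.auc:.3f} "
          f"(95% CI {report.auc_ci[0]:.3f}-{report.auc_ci[1]:.3f}), "
          f"cutoff {report.cutoff:.1%} risk (J={report.youden_j:.3f}), "
          f"dichotomized C {report.dichotomized_c:.3f}")
    if report.hosmer_lemeshow is not None:
        hl = report.hosmer_lemeshow
        print(f"  Hosmer-Lemeshow chi2={hl.statistic:.2f}, df={hl.df}, p={hl.p_value:.3f}")

    ext_records = records_from_csv(OUT / f"external_cohort_{sex}.csv")
    ext = external_validate(inst, profiles["external"], ext_records, cutoff=report.cutoff)
    with open(OUT / f"validation_{sex}.json", "w") as fh:
        json.dump(ext.to_dict(), fh, indent=2)
    print(f"{sex} external:   AUC {ext.auc:.3f} "
          f"(95% CI {ext.auc_ci[0]:.3f}-{ext.auc_ci[1]:.3f}) "
          f"at the derivation cutoff, dichotomized C {ext.dichotomized_c:.3f}")

    scored = [(p, apply_instrument(p, inst).risk) for pid, p in profiles["derivation"].items()
              if any(r.participant_id == pid for r in records)]
    risks_by_sex[sex] = scored

welch = sex_risk_compare([r for _, r in risks_by_sex["female"]],
                         [r for _, r in risks_by_sex["male"]])
print(f"\npredicted 12-year risk, female vs male: "
      f"{welch.mean1:.1%} vs {welch.mean2:.1%} "
      f"(Welch t={welch.statistic:.2f}, p={welch.p_value:.3g})")

# tabulate per sex at its own cutoff, then stack
tabs = []
for sex in ("female", "male"):
    prof_s = [p for p, _ in risks_by_sex[sex]]
    risk_s = [r for _, r in risks_by_sex[sex]]
    tab = high_risk_age_distribution(risk_s, prof_s, cutoff=cutoffs[sex])
    tabs.append(tab[tab.sex == sex])
age_tab = pd.concat(tabs, ignore_index=True)
age_tab.to_csv(OUT / "high_risk_age_distribution.csv", index=False)
print("\nhigh-risk participants by age band (each sex at its own cutoff):")
print(age_tab.to_string(index=False))
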