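"""Construct the sex-specific point instruments from the fitted models.

Re-fits the multivariable Cox model per sex (the fit is cheap and keeps
this step self-contained), builds the category scheme with within-band
median reference values, converts coefficients to integer points with the
half-age-decade base constant, attaches the 12-year absolute-risk map,
and exports score tables, risk-band tables and the full 24-cell risk
grids — for the fitted instruments and, for side-by-side comparison, the
packaged published ones.
"""

import pathlib

from mciscore import (
    build_category_scheme,
    build_instrument,
    fit_cox,
    km_survival,
    published_instruments,
    risk_grid,
)

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

def records_from_csv(path):
    import pandas as pd

    df = pd.read_csv(path)
    covs = [c for c in df.columns if c not in ("participant_id", "sex", "time", "event")]
    from mciscore import SurvivalRecord

    return [
        SurvivalRecord(str(r.participant_id), str(r.sex), float(r.time), bool(r.event),
                       {c: float(getattr(r, c)) for c in covs})
        for r in df.itertuples(index=False)
    ]


MODEL = ["age", "apoe4", "mmse_le26", "cdr05"]

for sex in ("female", "male"):
    records = records_from_csv(OUT / f"derivation_cohort_{sex}.csv")
    model = fit_cox(records, MODEL, forced=("age",))
    scheme = build_category_scheme(records)
    curve = km_survival(records)
    inst = build_instrument(model, scheme, b="auto", horizon=12.0,
                            s0_curve=curve, sex=sex)
    inst.to_json(OUT / f"instrument_{sex}.json")
    inst.score_table().to_csv(OUT / f"score_table_{sex}.csv", index=False)
    inst.band_table().to_csv(OUT / f"band_table_{sex}.csv", index=False)
    risk_grid(inst).to_csv(OUT / f"risk_grid_{sex}.csv", index=False)
    print(f"{sex}: B = {inst.B:.4f} (half an age decade), "
          f"scores {inst.min_score}..{inst.max_score}, "
          f"S0(12y) = {inst.risk_params.s0:.3f}")
    for f in inst.factors:
        labels = "/".join(c.label for c in f.categories)
        print(f"  {f.name:<10} [{labels}] -> points {f.points}")

for inst in published_instruments():
    tag = f"published_{inst.sex}"
    inst.score_table().to_csv(OUT / f"score_table_{tag}.csv", index=False)
    inst.band_table().to_csv(OUT / f"band_table_{tag}.csv", index=False)
    risk_grid(inst).to_csv(OUT / f"risk_grid_{tag}.csv", index=False)
print("published instruments exported for comparison "
      "(risk bands only; their S0 and beta were not published)")
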