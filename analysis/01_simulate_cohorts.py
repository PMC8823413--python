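"""Generate the synthetic derivation and external-validation cohorts.

Writes visit, baseline and ground-truth CSVs for two independent cohorts:
a derivation cohort of 300 participants per sex, and a smaller external
cohort (170 female / 120 male) drawn from the same generative model with a
different seed.  Both include baseline-only and direct-to-AD contaminant
records so the downstream exclusion filters have work to do.
"""

import pathlib

from mciscore import CohortSpec, generate_cohort, write_cohort

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "data"

derivation = CohortSpec(n_female=300, n_male=300, seed=20260101)
external = CohortSpec(n_female=170, n_male=120, seed=20260202)

for label, spec in (("derivation", derivation), ("external", external)):
    cohort = generate_cohort(spec)
    paths = write_cohort(cohort, OUT, prefix=label)
    n_events = (
        cohort.visits.groupby("participant_id").last().diagnosis.eq("MCI").sum()
    )
    print(f"{label}: {len(cohort.baseline)} participants "
          f"({spec.n_female}F/{spec.n_male}M regular + contaminants), "
          f"{n_events} convert to MCI")
    for name, path in paths.items():
        print(f"  {name}: {path}")
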