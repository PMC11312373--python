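"""Joint and modification analysis of diet quality and inflammation.

Cross-classifies MED-diet tertiles with INFLA-Score quartiles (reference:
worst diet, highest inflammation) and refits the quartile model within
each tertile to see whether a good diet attenuates the inflammation
effect.
"""

import pandas as pd

from inflascore import (
    CohortConfig,
    ModelSpec,
    bin_tertiles,
    derive_outcomes,
    generate_cohort,
    joint_fit,
    med_score,
    modification_fit,
)

cohort = generate_cohort(CohortConfig(n_participants=30_000, seed=5))
analysis = pd.concat([cohort, derive_outcomes(cohort)], axis=1)
diet = analysis.dropna(subset=["energy_kcal"]).copy()
diet["med_t"] = bin_tertiles(med_score(diet, diet["sex"]))

spec = ModelSpec(outcome="premature_death",
                 adjust=("age_baseline", "sex_male", "bmi"))

joint = joint_fit(diet, "med_t", "infla_q", spec)
best = joint.loc[joint["hr"].idxmin()]
print("12-cell joint analysis (reference = T1,Q4 — worst diet, most inflamed):")
print(f"  lowest-risk cell: {best['cell']} "
      f"HR {best['hr']:.2f} ({best['ci_low']:.2f}-{best['ci_high']:.2f})")

mod = modification_fit(diet, "med_t", spec)
print("\nQ4-vs-Q1 HR within each MED tertile:")
for stratum, grp in mod.groupby("stratum"):
    q4 = grp.set_index("term").loc["Q4"]
    print(f"  {stratum}: {q4['hr']:.2f} ({q4['ci_low']:.2f}-{q4['ci_high']:.2f}), "
          f"p-trend {grp['p_trend'].iloc[0]:.3f}")

# Under the default generator diet does not modify the hazard, so the
# three tertile estimates should be mutually consistent; a real
# protective diet would show the T3 estimate pulled toward 1.
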