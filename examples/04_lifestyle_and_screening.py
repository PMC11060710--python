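"""Lifestyle association with aging pace, and screening-age thresholds.

Regresses PhenoAgeAccel on the healthy-lifestyle factor count (adjusted),
then locates the chronological age at which each biological-age group's
5-year absolute cancer risk crosses a 2% screening threshold.
"""

import numpy as np

from phenorisk import (
    GeneratorConfig, generate_cohort, phenoage_from_table,
    regress_accel_on_lifestyle, risk_by_age_curve,
)

table = phenoage_from_table(
    generate_cohort(GeneratorConfig(n_participants=40_000, seed=19)).table)
table["aging_group"] = np.where(table["phenoaccel"] >= 0, "older", "younger")

for sex, grp in table.groupby("sex"):
    covs = grp[["age", "height", "family_history", "townsend"]
               + [f"pc{k}" for k in range(1, 11)]]
    reg = regress_accel_on_lifestyle(grp["phenoaccel"], grp["lifestyle_index"], covs)
    print(f"{sex:>6}: {reg.slope:+.2f} years of PhenoAgeAccel per healthy "
          f"factor (95% CI {reg.ci95[0]:.2f} to {reg.ci95[1]:.2f}, p={reg.p_value:.1e})")

print("\nage at which 5-year absolute risk reaches 2%:")
for sex, grp in table.groupby("sex"):
    curves = risk_by_age_curve(grp, threshold_pct=2.0)
    for name in ("younger", "older"):
        c = curves[name]
        age = "not reached" if c.crossing_age is None else f"{c.crossing_age:.1f}"
        print(f"  {sex}, biologically {name:<8}: {age}")
print("Biologically older groups cross the screening threshold earlier — "
      "the gap is the screening head start conferred by measuring aging pace.")
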