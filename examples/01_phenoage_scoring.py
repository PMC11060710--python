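"""Score PhenoAge for two hypothetical participants from their blood panel.

Builds a two-row biomarker table, computes the mortality linear predictor,
the 120-month mortality score, and PhenoAge in years.  The second
participant differs only by a raised C-reactive protein and red-cell
distribution width — an inflamed profile — and scores biologically older
despite the same chronological age.
"""

import pandas as pd

from phenorisk import compute_phenoage, compute_xb, mortality_score

panel = pd.DataFrame({
    "albumin": [46.2, 46.2],          # g/L
    "creatinine": [77.6, 77.6],       # umol/L
    "glucose": [4.82, 4.82],          # mmol/L
    "crp": [0.09, 0.60],              # mg/dL  <- inflamed in row 2
    "lymphocyte_pct": [29.9, 29.9],   # %
    "mcv": [90.9, 90.9],              # fL
    "rdw": [13.0, 14.5],              # %      <- raised in row 2
    "alp": [75.0, 75.0],              # U/L
    "wbc": [6.1, 6.1],                # 10^3 cells/uL
})
age = [57.0, 57.0]

xb = compute_xb(panel, age)
pheno, score = compute_phenoage(xb, return_score=True)

for i, label in enumerate(["healthy profile", "inflamed profile"]):
    print(f"{label}: xb = {xb[i]:+.3f}, 10-yr mortality score = {score[i]:.4f}, "
          f"PhenoAge = {pheno[i]:.1f} years")
print(f"\nSame chronological age (57); the inflamed profile is "
      f"{pheno[1] - pheno[0]:.1f} years biologically older.")
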