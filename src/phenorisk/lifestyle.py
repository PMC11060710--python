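"""Five-factor healthy-lifestyle index and its association with aging pace.

The index counts healthy factors out of five — no current smoking, no
alcohol consumption, regular physical activity, normal BMI, healthy diet —
and collapses to three categories: favorable (4-5 factors), intermediate
(2-3), unfavorable (0-1).  The association of interest is a linear
regression of PhenoAgeAccel on the factor count: a negative slope means
each additional healthy factor is associated with a biologically younger
profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "FACTORS",
    "derive_factors",
    "lifestyle_index",
    "categorize_index",
    "factor_audit",
    "LifestyleRegression",
    "regress_accel_on_lifestyle",
]

FACTORS = (
    "no_current_smoking",
    "no_alcohol",
    "regular_activity",
    "normal_bmi",
    "healthy_diet",
)


def derive_factors(raw: pd.DataFrame, missing_as_unhealthy: bool = True) -> pd.DataFrame:
    """Derive the five boolean factors from raw questionnaire fields.

    Expected raw columns (missing values allowed):

    - ``smoking_status`` in {never, former, current} and ``years_since_quit``
      (no current smoking = never, or former with quit >= 30 years ago)
    - ``alcohol_status`` in {never, former, current} (no alcohol = never)
    - ``vigorous_min_week``, ``moderate_min_week``, ``vigorous_days_week``,
      ``moderate_days_week`` (regular activity = >= 75 vigorous or >= 150
      moderate minutes/week, an equivalent mix 2*vigorous + moderate >= 150,
      or >= 1 vigorous session plus moderate activity >= 5 days/week)
    - ``bmi`` (normal = 18.5 <= BMI < 30; non-positive BMI is an error)
    - ``healthy_diet`` boolean, precomputed upstream (the dietary component
      cut-offs are questionnaire-specific and consumed as a flag)

    With ``missing_as_unhealthy`` (default) a missing component marks the
    factor unhealthy and is logged; otherwise missingness propagates.
    """
    if "bmi" in raw.columns:
        bmi_vals = raw["bmi"].to_numpy(float)
        if np.any(bmi_vals[~np.isnan(bmi_vals)] <= 0):
            raise ValueError("BMI must be positive")

    def col(name, default=np.nan):
        if name in raw.columns:
            return raw[name]
        return pd.Series(default, index=raw.index)

    smoking = col("smoking_status").astype("string")
    quit_years = pd.to_numeric(col("years_since_quit"), errors="coerce")
    no_smoke = (smoking == "never") | ((smoking == "former") & (quit_years >= 30))
    no_smoke = no_smoke.mask(smoking.isna())

    alcohol = col("alcohol_status").astype("string")
    no_alc = (alcohol == "never").mask(alcohol.isna())

    vig = pd.to_numeric(col("vigorous_min_week"), errors="coerce")
    mod = pd.to_numeric(col("moderate_min_week"), errors="coerce")
    vig_d = pd.to_numeric(col("vigorous_days_week", 0), errors="coerce")
    mod_d = pd.to_numeric(col("moderate_days_week", 0), errors="coerce")
    active = (
        (vig >= 75) | (mod >= 150)
        | ((2 * vig.fillna(0) + mod.fillna(0)) >= 150)
        | ((vig_d.fillna(0) >= 1) & (mod_d.fillna(0) >= 5))
    )
    active = active.mask(vig.isna() & mod.isna())

    bmi = pd.to_numeric(col("bmi"), errors="coerce")
    normal_bmi = ((bmi >= 18.5) & (bmi < 30)).mask(bmi.isna())

    diet = col("healthy_diet")
    diet = diet.astype("boolean") if diet.notna().any() else pd.Series(pd.NA, index=raw.index, dtype="boolean")

    out = pd.DataFrame({
        "no_current_smoking": no_smoke.astype("boolean"),
        "no_alcohol": no_alc.astype("boolean"),
        "regular_activity": active.astype("boolean"),
        "normal_bmi": normal_bmi.astype("boolean"),
        "healthy_diet": diet,
    }, index=raw.index)

    n_missing = int(out.isna().to_numpy().sum())
    if n_missing and missing_as_unhealthy:
        logger.info("lifestyle: %d missing factor cells treated as unhealthy", n_missing)
        out = out.fillna(False)
    out["lifestyle_index"] = out[list(FACTORS)].sum(axis=1).astype("Int64")
    out["lifestyle_category"] = categorize_index(out["lifestyle_index"])
    return out


def lifestyle_index(factors: pd.DataFrame) -> pd.Series:
    """Count of healthy factors (0-5) from boolean factor columns."""
    return factors[list(FACTORS)].astype(float).sum(axis=1).astype(int)


def categorize_index(index) -> pd.Series:
    """Map the 0-5 index to favorable (4-5) / intermediate (2-3) / unfavorable (0-1)."""
    idx = pd.Series(index).astype(float)
    if ((idx < 0) | (idx > 5)).any():
        raise ValueError("lifestyle index must lie in 0..5")
    labels = np.select([idx >= 4, idx >= 2], ["favorable", "intermediate"], "unfavorable")
    labels = np.where(idx.isna(), None, labels)
    return pd.Series(pd.Categorical(labels, categories=["unfavorable", "intermediate", "favorable"],
                                    ordered=True), index=idx.index, name="lifestyle_category")


def factor_audit(factors: pd.DataFrame, sex: pd.Series) -> pd.DataFrame:
    """Per-sex counts and shares of each factor and category (baseline-table style)."""
    rows = []
    for s, grp in factors.groupby(sex.values, observed=True):
        n = len(grp)
        for f in FACTORS:
            k = int(grp[f].astype(bool).sum())
            rows.append({"sex": s, "item": f, "count": k, "pct": 100.0 * k / n})
        for cat, k in grp["lifestyle_category"].value_counts().items():
            rows.append({"sex": s, "item": f"category:{cat}", "count": int(k),
                         "pct": 100.0 * k / n})
    return pd.DataFrame(rows)


@dataclass
class LifestyleRegression:
    slope: float       # PhenoAgeAccel years per additional healthy factor
    se: float
    p_value: float
    ci95: tuple
    n: int
    model: object      # fitted statsmodels results, for inspection


def regress_accel_on_lifestyle(accel, n_factors, covariates: pd.DataFrame | None = None,
                               ) -> LifestyleRegression:
    """OLS of PhenoAgeAccel on the healthy-factor count, with adjustment.

    Covariates typically include age, family history of cancer, Townsend
    deprivation index, height and ancestry principal components; run within
    sex.  Raises on a rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(accel, dtype=float)
    x = np.asarray(n_factors, dtype=float)
    parts = {"n_factors": x}
    if covariates is not None:
        for c in covariates.columns:
            parts[c] = covariates[c].to_numpy(float)
    X = pd.DataFrame(parts)
    if len(X) < X.shape[1] + 2:
        raise ValueError("too few observations for the requested adjustment")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify offending columns via QR pivoting on the correlation structure
        bad = []
        M = design.to_numpy()
        for j in range(1, M.shape[1]):
            sub = M[:, list(range(j)) + [j]]
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(M[:, :j]):
                bad.append(design.columns[j])
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int().loc["n_factors"]
    return LifestyleRegression(
        slope=float(res.params["n_factors"]), se=float(res.bse["n_factors"]),
        p_value=float(res.pvalues["n_factors"]), ci95=(float(ci[0]), float(ci[1])),
        n=int(res.nobs), model=res,
    )
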