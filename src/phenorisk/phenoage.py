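"""PhenoAge: a biological-age clock from nine clinical-chemistry biomarkers.

PhenoAge maps a Gompertz proportional-hazards mortality score, built from
chronological age and nine blood biomarkers, onto the age scale.  The linear
predictor is

    xb = b0 + sum_j beta_j * x_j + beta_age * age,       x_crp = ln(CRP)

the 120-month mortality score is

    M = 1 - exp(-exp(xb) * (exp(gamma*120) - 1) / gamma)

and PhenoAge (years) inverts a univariate age-only Gompertz model:

    PhenoAge = offset + ln(-c1 * ln(1 - M)) / c2.

Phenotypic Age Acceleration (PhenoAgeAccel) is the residual of PhenoAge
regressed on chronological age: positive values mean biologically older than
expected for one's age.

Units are fixed: albumin g/L, creatinine umol/L, glucose mmol/L, CRP mg/dL
(natural log taken), lymphocyte %, mean cell volume fL, red-cell distribution
width %, alkaline phosphatase U/L, white-cell count 10^3 cells/uL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BIOMARKERS",
    "PhenoAgeCoefficients",
    "PHENOAGE_2018",
    "crp_mgL_to_mgdL",
    "winsorize",
    "winsorize_panel",
    "compute_xb",
    "mortality_score",
    "compute_phenoage",
    "compute_phenoaccel",
    "phenoage_from_table",
    "PRSWeightSet",
    "read_prs_weights",
    "score_prs",
]

#: canonical biomarker column order used throughout the package
BIOMARKERS = (
    "albumin",
    "creatinine",
    "glucose",
    "crp",
    "lymphocyte_pct",
    "mcv",
    "rdw",
    "alp",
    "wbc",
)


@dataclass(frozen=True)
class PhenoAgeCoefficients:
    """Complete coefficient set of the two-stage Gompertz mortality clock.

    ``intercept_xb`` and the ``beta_*`` terms define the mortality linear
    predictor; ``gompertz_gamma`` (per month) and ``horizon`` (months) define
    the mortality score; ``outer_offset``/``c1``/``c2`` map the score back to
    years.  The defaults are the published constants; :func:`retrain_phenoage
    <phenorisk.gompertz.retrain_phenoage>` returns a replacement set fitted to
    a cohort.
    """

    intercept_xb: float = -19.907
    beta_albumin: float = -0.0336
    beta_creatinine: float = 0.0095
    beta_glucose: float = 0.1953
    beta_lncrp: float = 0.0954
    beta_lymphocyte_pct: float = -0.0120
    beta_mcv: float = 0.0268
    beta_rdw: float = 0.3306
    beta_alp: float = 0.00188
    beta_wbc: float = 0.0554
    beta_age: float = 0.0804
    outer_offset: float = 141.50
    c1: float = 0.00553
    c2: float = 0.09165
    gompertz_gamma: float = 0.0076927
    horizon: float = 120.0
    provenance: str = "published-2018"

    @property
    def biomarker_betas(self) -> dict[str, float]:
        return {
            "albumin": self.beta_albumin,
            "creatinine": self.beta_creatinine,
            "glucose": self.beta_glucose,
            "crp": self.beta_lncrp,  # applied to ln(CRP)
            "lymphocyte_pct": self.beta_lymphocyte_pct,
            "mcv": self.beta_mcv,
            "rdw": self.beta_rdw,
            "alp": self.beta_alp,
            "wbc": self.beta_wbc,
        }

    @property
    def cumulative_gompertz_factor(self) -> float:
        """(exp(gamma*horizon) - 1) / gamma — the integrated baseline hazard
        multiplier over the scoring horizon."""
        g = self.gompertz_gamma
        return (math.exp(g * self.horizon) - 1.0) / g

    @property
    def affine_constant(self) -> float:
        """k such that PhenoAge = outer_offset + (xb + k)/c2 exactly."""
        return math.log(self.c1 * self.cumulative_gompertz_factor)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "PhenoAgeCoefficients":
        return cls(**d)


#: published coefficient set
PHENOAGE_2018 = PhenoAgeCoefficients()


def crp_mgL_to_mgdL(crp_mgL):
    """Convert C-reactive protein from mg/L to the mg/dL the clock expects.

    Never applied implicitly: callers must opt in.
    """
    return np.asarray(crp_mgL, dtype=float) / 10.0


def winsorize(values, lower_pct: float = 0.01, upper_pct: float = 0.99):
    """Cap values below/above the given empirical quantiles (type-7).

    Skew in clinical-chemistry panels is tamed by setting the bottom and top
    tails to the corresponding percentile values before scoring.  NaNs are
    ignored when computing quantiles and passed through unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot winsorize an empty vector")
    if not (0.0 <= lower_pct < upper_pct <= 1.0):
        raise ValueError(f"need 0 <= lower_pct < upper_pct <= 1, got {lower_pct}, {upper_pct}")
    finite = v[~np.isnan(v)]
    if finite.size == 0:
        raise ValueError("cannot winsorize an all-missing vector")
    lo, hi = np.quantile(finite, [lower_pct, upper_pct])  # type-7 linear interpolation
    return np.clip(v, lo, hi)


def winsorize_panel(
    table: pd.DataFrame,
    columns=BIOMARKERS,
    lower_pct: float = 0.01,
    upper_pct: float = 0.99,
    by_sex: bool = False,
    log_scale_crp: bool = False,
) -> pd.DataFrame:
    """Winsorize each biomarker column of a participant table.

    Defaults pool the sexes (configurable) and cap CRP on the raw scale;
    ``log_scale_crp=True`` caps ln(CRP) instead and exponentiates back, which
    changes nothing at the default symmetric percentiles but is exposed
    because the choice is a genuine dialect.
    """
    out = table.copy()

    def _one(df):
        res = df.copy()
        for col in columns:
            if col == "crp" and log_scale_crp:
                res[col] = np.exp(winsorize(np.log(df[col].to_numpy(float)), lower_pct, upper_pct))
            else:
                res[col] = winsorize(df[col].to_numpy(float), lower_pct, upper_pct)
        return res

    if by_sex:
        parts = [_one(g) for _, g in out.groupby("sex", sort=False)]
        return pd.concat(parts).loc[out.index]
    return _one(out)


def compute_xb(panel, age, coef: PhenoAgeCoefficients = PHENOAGE_2018):
    """Mortality linear predictor from a biomarker panel and age.

    ``panel`` is a DataFrame (or mapping of arrays) with the nine canonical
    biomarker columns; CRP enters as its natural log.
    """
    if isinstance(panel, pd.DataFrame):
        get = lambda c: panel[c].to_numpy(dtype=float)  # noqa: E731
    else:
        get = lambda c: np.asarray(panel[c], dtype=float)  # noqa: E731
    crp = get("crp")
    if np.any(crp <= 0):
        raise ValueError("CRP must be strictly positive (natural log is taken)")
    age = np.asarray(age, dtype=float)
    xb = np.full_like(np.broadcast_to(age, np.broadcast_shapes(age.shape, crp.shape)).astype(float),
                      coef.intercept_xb)
    for name, beta in coef.biomarker_betas.items():
        x = np.log(crp) if name == "crp" else get(name)
        xb = xb + beta * x
    return xb + coef.beta_age * age


def mortality_score(xb, coef: PhenoAgeCoefficients = PHENOAGE_2018):
    """Gompertz mortality score M over the scoring horizon, in (0, 1)."""
    xb = np.asarray(xb, dtype=float)
    return -np.expm1(-np.exp(xb) * coef.cumulative_gompertz_factor)


def compute_phenoage(xb, coef: PhenoAgeCoefficients = PHENOAGE_2018, return_score: bool = False):
    """PhenoAge in years from the linear predictor.

    The textbook two-step form ``offset + ln(-c1*ln(1-M))/c2`` underflows for
    very low-risk xb (M rounds to 0) and saturates for very high risk (M
    rounds to 1).  Because ln(-ln(1-M)) = xb + ln(c1 * (e^{gamma*h}-1)/gamma)
    identically, the affine form is used for evaluation; it is exact, never
    NaN, and agrees with the two-step form to floating-point precision
    wherever the latter is representable.
    """
    xb = np.asarray(xb, dtype=float)
    phenoage = coef.outer_offset + (xb + coef.affine_constant) / coef.c2
    if return_score:
        return phenoage, mortality_score(xb, coef)
    return phenoage


def compute_phenoaccel(phenoage, age, return_fit: bool = False):
    """Phenotypic Age Acceleration: residual of PhenoAge ~ chronological age.

    Ordinary least squares with intercept; residuals have mean zero and zero
    covariance with age on the fitting sample by construction.
    """
    y = np.asarray(phenoage, dtype=float)
    x = np.asarray(age, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("phenoage and age must be 1-d vectors of equal length")
    if y.size < 3:
        raise ValueError("need at least 3 observations to residualize")
    if np.ptp(x) == 0:
        raise ValueError("chronological age has zero variance; residual undefined")
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    if return_fit:
        return resid, intercept, slope
    return resid


def phenoage_from_table(
    table: pd.DataFrame,
    coef: PhenoAgeCoefficients = PHENOAGE_2018,
    age_col: str = "age",
    winsorize_first: bool = True,
) -> pd.DataFrame:
    """Convenience: winsorize, score and residualize a participant table.

    Returns a copy with ``xb``, ``mortality_score``, ``phenoage`` and
    ``phenoaccel`` columns appended.
    """
    work = winsorize_panel(table) if winsorize_first else table.copy()
    xb = compute_xb(work, work[age_col].to_numpy(float), coef)
    phenoage, score = compute_phenoage(xb, coef, return_score=True)
    out = table.copy()
    out["xb"] = xb
    out["mortality_score"] = score
    out["phenoage"] = phenoage
    out["phenoaccel"] = compute_phenoaccel(phenoage, out[age_col].to_numpy(float))
    return out


# ---------------------------------------------------------------------------
# Polygenic risk score from per-variant dosages


@dataclass
class PRSWeightSet:
    """Per-variant effect sizes for an additive polygenic score.

    ``eaf`` (effect-allele frequency) is optional; when present, missing
    dosages are imputed as ``2*eaf``, otherwise the variant is dropped for
    that participant (with a warning counter).
    """

    variant_ids: list
    effect_alleles: list
    weights: np.ndarray
    eaf: np.ndarray | None = None
    provenance: str = "unspecified"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.variant_ids)) != len(self.variant_ids):
            dupes = {v for v in self.variant_ids if self.variant_ids.count(v) > 1}
            raise ValueError(f"duplicate variant ids in weight set: {sorted(dupes)}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite PRS weights")
        if self.eaf is not None:
            self.eaf = np.asarray(self.eaf, dtype=float)

    def __len__(self):
        return len(self.variant_ids)


def read_prs_weights(path, provenance: str | None = None) -> PRSWeightSet:
    """Read a tab-delimited weight file: variant_id, effect_allele, weight[, eaf]."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "effect_allele", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight file missing columns: {sorted(missing)}")
    return PRSWeightSet(
        variant_ids=df["variant_id"].astype(str).tolist(),
        effect_alleles=df["effect_allele"].astype(str).tolist(),
        weights=df["weight"].to_numpy(float),
        eaf=df["eaf"].to_numpy(float) if "eaf" in df.columns else None,
        provenance=provenance or str(path),
    )


def score_prs(dosages, weights: PRSWeightSet, variant_ids=None):
    """Additive PRS: per-participant sum of dosage x effect size.

    ``dosages`` is variants x participants (rows align to ``variant_ids``,
    which defaults to the weight set's own order); entries must lie in
    [0, 2] or be NaN.  Missing dosages are imputed as 2*eaf when allele
    frequencies are available, else that variant is skipped for the affected
    participant.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    ids = list(weights.variant_ids) if variant_ids is None else list(variant_ids)
    if len(ids) != D.shape[0]:
        raise ValueError(f"{D.shape[0]} dosage rows but {len(ids)} variant ids")
    index = {v: i for i, v in enumerate(weights.variant_ids)}
    unmatched = [v for v in ids if v not in index]
    if unmatched:
        raise KeyError(f"variant ids not in weight set: {unmatched}")
    order = [index[v] for v in ids]
    w = weights.weights[order]
    valid = np.isfinite(D)
    if not np.all((D[valid] >= 0) & (D[valid] <= 2)):
        raise ValueError("dosages must lie in [0, 2]")
    if valid.all():
        return w @ D
    filled = D.copy()
    if weights.eaf is not None:
        fill = (2.0 * weights.eaf[order])[:, None]
        filled = np.where(valid, filled, np.broadcast_to(fill, D.shape))
    else:
        filled = np.where(valid, filled, 0.0)  # drop variant for that participant
    return w @ filled
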