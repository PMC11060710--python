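"""Follow-up assembly and sex-stratified Cox proportional-hazards models.

Follow-up runs from baseline to the first of cancer diagnosis, death, loss
to follow-up, or administrative censoring.  Hazard ratios come from partial
likelihood with Efron tie handling; the PhenoAgeAccel exposure is fitted
continuously (per 5 years), as a younger/older binary, as quantile-based
low/intermediate/high groups (with a trend test over the ordered codes), and
by decile.  Proportionality is screened per term via the scaled Schoenfeld
residual test and reported, never auto-acted upon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL1_COVARIATES",
    "ModelSpec",
    "assemble_followup",
    "CoxFit",
    "fit_cox",
    "decile_analysis",
    "sensitivity_filters",
    "impute_covariates",
]

#: baseline adjustment: age, height, family history, deprivation, 10 ancestry PCs
MODEL1_COVARIATES = ("age", "height", "family_history", "townsend",
                     "pc1", "pc2", "pc3", "pc4", "pc5",
                     "pc6", "pc7", "pc8", "pc9", "pc10")

#: Model 2 additionally adjusts for genetic risk and lifestyle
MODEL2_EXTRA = ("cprs_z", "lifestyle_index")


@dataclass
class ModelSpec:
    """Exposure coding + covariate set for one Cox model.

    ``exposure``: name(s) of the exposure column(s) already present in the
    data (e.g. ``accel_per5``, a dummy, or ordered-group dummies).
    ``trend_col``: optional ordinal 0/1/2 column for a p-for-trend model.
    """

    exposure: tuple
    covariates: tuple = MODEL1_COVARIATES
    duration_col: str = "time_years"
    event_col: str = "cancer"
    sex: str | None = None
    trend_col: str | None = None

    def __post_init__(self):
        if isinstance(self.exposure, str):
            self.exposure = (self.exposure,)
        self.exposure = tuple(self.exposure)
        self.covariates = tuple(self.covariates)


def assemble_followup(cohort: pd.DataFrame, entry_col: str = "entry_time",
                      diagnosis_col: str = "diagnosis_time",
                      death_col: str = "death_time",
                      loss_col: str = "loss_time",
                      censor_col: str = "admin_censor_time") -> pd.DataFrame:
    """Build follow-up records: time to the first terminating event.

    Each terminating column may contain NaN (event never observed).  The
    event is cancer iff the diagnosis is the earliest terminus; death, loss
    and administrative censoring all censor the cancer outcome.  A
    terminating time at or before entry raises, listing the offending ids.
    """
    entry = cohort[entry_col].to_numpy(float)
    termini = np.column_stack([
        cohort[c].to_numpy(float) if c in cohort.columns else np.full(len(cohort), np.nan)
        for c in (diagnosis_col, death_col, loss_col, censor_col)
    ])
    if np.all(np.isnan(termini), axis=1).any():
        raise ValueError("every participant needs at least one terminating time")
    bad = np.nanmin(termini, axis=1) <= entry
    if bad.any():
        ids = cohort.index[bad].tolist() if "id" not in cohort.columns \
            else cohort.loc[bad, "id"].tolist()
        raise ValueError(f"terminating time at or before entry for participant(s) {ids[:10]}")
    first = np.nanmin(termini, axis=1)
    time = first - entry
    event = (~np.isnan(termini[:, 0])) & (termini[:, 0] <= first)
    out = pd.DataFrame({"time": time, "event": event.astype(int),
                        "person_years": time}, index=cohort.index)
    return out


@dataclass
class CoxFit:
    """Tidy summary of one proportional-hazards fit."""

    summary: pd.DataFrame       # term, loghr, se, hr, ci_lo, ci_hi, p
    n: int
    events: int
    ph_pvalues: dict = field(default_factory=dict)
    trend_p: float | None = None
    model: object = None        # fitted lifelines CoxPHFitter

    def hr(self, term: str) -> float:
        return float(self.summary.set_index("term").loc[term, "hr"])

    def loghr(self, term: str) -> float:
        return float(self.summary.set_index("term").loc[term, "loghr"])

    def se(self, term: str) -> float:
        return float(self.summary.set_index("term").loc[term, "se"])

    def ci(self, term: str) -> tuple:
        row = self.summary.set_index("term").loc[term]
        return float(row["ci_lo"]), float(row["ci_hi"])

    def to_tidy(self) -> pd.DataFrame:
        t = self.summary.copy()
        t["n"] = self.n
        t["events"] = self.events
        return t


def _tidy_from_lifelines(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    return pd.DataFrame({
        "term": s.index,
        "loghr": s["coef"].to_numpy(),
        "se": s["se(coef)"].to_numpy(),
        "hr": np.exp(s["coef"].to_numpy()),
        "ci_lo": np.exp(s["coef"].to_numpy() - 1.96 * s["se(coef)"].to_numpy()),
        "ci_hi": np.exp(s["coef"].to_numpy() + 1.96 * s["se(coef)"].to_numpy()),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)


def fit_cox(data: pd.DataFrame, spec: ModelSpec, check_proportionality: bool = True) -> CoxFit:
    """Partial-likelihood Cox fit (Efron ties) for one model specification.

    Warns (does not fail) when events fall below 10 per parameter.  A trend
    p-value is computed when ``spec.trend_col`` names an ordinal coding: the
    exposure dummies are replaced by the single ordered code and its Wald p
    reported.
    """
    cols = list(spec.exposure) + [c for c in spec.covariates if c in data.columns]
    missing = [c for c in list(spec.exposure) + list(spec.covariates)
               if c not in data.columns]
    if missing:
        raise KeyError(f"model columns absent from data: {missing}")
    df = data[cols + [spec.duration_col, spec.event_col]].dropna()
    events = int(df[spec.event_col].sum())
    n_params = len(cols)
    if events < 10 * n_params:
        warnings.warn(f"only {events} events for {n_params} parameters "
                      "(< 10 per parameter); estimates may be unstable",
                      stacklevel=2)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=spec.duration_col, event_col=spec.event_col)
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc

    ph_p = {}
    if check_proportionality:
        try:
            res = proportional_hazard_test(cph, df, time_transform="rank")
            ph_p = {t: float(p) for t, p in res.summary["p"].items()}
            flagged = [t for t, p in ph_p.items() if p < 0.05]
            if flagged:
                logger.info("proportionality flagged (p<0.05) for terms: %s", flagged)
        except Exception:  # diagnostic only; never blocks the fit
            ph_p = {}

    trend_p = None
    if spec.trend_col is not None:
        tcols = [spec.trend_col] + [c for c in spec.covariates if c in data.columns]
        tdf = data[tcols + [spec.duration_col, spec.event_col]].dropna()
        tfit = CoxPHFitter()
        tfit.fit(tdf, duration_col=spec.duration_col, event_col=spec.event_col)
        trend_p = float(tfit.summary.loc[spec.trend_col, "p"])

    return CoxFit(summary=_tidy_from_lifelines(cph), n=len(df), events=events,
                  ph_pvalues=ph_p, trend_p=trend_p, model=cph)


def decile_analysis(data: pd.DataFrame, accel_col: str = "phenoaccel",
                    covariates=MODEL1_COVARIATES,
                    duration_col: str = "time_years",
                    event_col: str = "cancer") -> tuple:
    """Hazard ratios by decile of aging acceleration, bottom decile reference.

    One model with nine dummy codes; returns (CoxFit, decile labels 1..10).
    Ties that collapse decile boundaries raise.
    """
    v = data[accel_col]
    try:
        decile = pd.qcut(v, 10, labels=False, duplicates="raise") + 1
    except ValueError as exc:
        raise ValueError(f"ties collapse decile boundaries of {accel_col}") from exc
    counts = decile.value_counts()
    if (counts < 10).any():
        raise ValueError(f"need >= 10 participants per decile; sizes {sorted(counts)}")
    work = data.copy()
    dummy_cols = []
    for d in range(2, 11):
        col = f"{accel_col}_d{d}"
        work[col] = (decile == d).astype(int)
        dummy_cols.append(col)
    spec = ModelSpec(exposure=tuple(dummy_cols), covariates=tuple(covariates),
                     duration_col=duration_col, event_col=event_col)
    fit = fit_cox(work, spec, check_proportionality=False)
    return fit, decile


def sensitivity_filters(cohort: pd.DataFrame, filter: str,
                        time_col: str = "time_years", event_col: str = "cancer",
                        covariates=None, flag_col: str = "unrelated_british") -> pd.DataFrame:
    """Apply one of the sensitivity-analysis cohort filters.

    - ``exclude_first_2y``: drop participants with a cancer event in the
      first two years of follow-up (censored participants are retained).
    - ``complete_case``: drop rows with any missing covariate.
    - ``unrelated_subset_flag``: keep rows where the flag column is truthy.
    """
    if filter == "exclude_first_2y":
        early = (cohort[event_col] == 1) & (cohort[time_col] <= 2.0)
        return cohort.loc[~early].copy()
    if filter == "complete_case":
        cols = list(covariates) if covariates is not None else \
            [c for c in cohort.columns if c not in (time_col, event_col)]
        return cohort.dropna(subset=[c for c in cols if c in cohort.columns]).copy()
    if filter == "unrelated_subset_flag":
        if flag_col not in cohort.columns:
            raise KeyError(f"flag column {flag_col!r} not present")
        return cohort.loc[cohort[flag_col].astype(bool)].copy()
    raise ValueError(f"unknown sensitivity filter {filter!r}")


def impute_covariates(cohort: pd.DataFrame, columns=None,
                      outcome_cols=("time_years", "cancer", "death_time_years", "death"),
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single median/mode imputation of covariates with an audit table.

    Numeric columns get their median, categorical/integer-coded columns
    their mode.  Outcome columns must already be complete.  Returns
    (imputed table, audit) where the audit lists per-column fill counts and
    the value used.  A fully-missing column raises.
    """
    cols = list(columns) if columns is not None else \
        [c for c in cohort.columns if c not in outcome_cols and cohort[c].isna().any()]
    for oc in outcome_cols:
        if oc in cohort.columns and cohort[oc].isna().any():
            raise ValueError(f"outcome column {oc!r} has missing values")
    out = cohort.copy()
    audit_rows = []
    for c in cols:
        s = out[c]
        n_miss = int(s.isna().sum())
        if n_miss == 0:
            continue
        if n_miss == len(s):
            raise ValueError(f"column {c!r} is fully missing; cannot impute")
        if pd.api.types.is_float_dtype(s) and s.dropna().nunique() > 2:
            value = float(s.median())
        else:
            value = s.mode(dropna=True).iloc[0]
        out[c] = s.fillna(value)
        audit_rows.append({"column": c, "n_imputed": n_miss, "value": value})
    audit = pd.DataFrame(audit_rows, columns=["column", "n_imputed", "value"])
    return out, audit
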