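"""Incidence rates, 5-year absolute risks, joint genetic x aging analysis,
additive interaction (RERI/AP), and screening-age threshold curves.

Absolute scales complement the hazard ratios: incidence rates per 100,000
person-years, 5-year absolute risks (optionally age-standardized to the
whole-cohort age distribution in 5-year bands), and bootstrap confidence
intervals for between-group risk differences.  Additive interaction between
genetic risk and accelerated aging is quantified by the relative excess risk
due to interaction, RERI = HR11 - HR10 - HR01 + 1, and the attributable
proportion AP = RERI/HR11, with percentile bootstrap intervals from joint
Cox refits.  Risk-by-age curves locate the chronological age at which a
group's 5-year risk crosses a screening threshold (default 2%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import ModelSpec, fit_cox, MODEL1_COVARIATES

__all__ = [
    "RateEstimate",
    "incidence_rate",
    "AbsoluteRisk5y",
    "absolute_risk_5y",
    "absolute_risk_increase",
    "joint_category_analysis",
    "reri_ap",
    "InteractionEstimate",
    "reri_ap_bootstrap",
    "RiskCurve",
    "risk_by_age_curve",
]


@dataclass
class RateEstimate:
    """Incidence rate per 100,000 person-years with a 95% CI."""

    cases: int
    person_years: float
    rate: float
    ci95: tuple
    degenerate: bool = False   # zero cases: no usable CI


def incidence_rate(cases: int, person_years: float, exact: bool = False) -> RateEstimate:
    """cases / person-years x 100,000.

    Default CI is the normal approximation rate +/- 1.96*rate/sqrt(cases);
    ``exact=True`` uses the Poisson (chi-square) interval instead.  Zero
    cases give rate 0 with a degenerate-flagged CI.
    """
    if person_years <= 0:
        raise ValueError("person_years must be > 0")
    if cases < 0:
        raise ValueError("cases must be >= 0")
    rate = cases / person_years * 1e5
    if cases == 0:
        return RateEstimate(0, person_years, 0.0, (0.0, 0.0), degenerate=True)
    if exact:
        lo = stats.chi2.ppf(0.025, 2 * cases) / 2 / person_years * 1e5
        hi = stats.chi2.ppf(0.975, 2 * (cases + 1)) / 2 / person_years * 1e5
    else:
        half = 1.96 * rate / np.sqrt(cases)
        lo, hi = rate - half, rate + half
    return RateEstimate(int(cases), float(person_years), float(rate),
                        (float(lo), float(hi)))


@dataclass
class AbsoluteRisk5y:
    """Percent of a group expected to have the event within 5 years."""

    risk_pct: float
    standardization: str       # "none" | "age-standardized"
    cases: int
    person_years: float


def _banded(ages: np.ndarray, band_width: float) -> np.ndarray:
    return np.floor(ages / band_width).astype(int)


def absolute_risk_5y(records: pd.DataFrame, standardization: str = "none",
                     standard_ages=None, time_col: str = "time_years",
                     event_col: str = "cancer", age_col: str = "age",
                     band_width: float = 5.0) -> AbsoluteRisk5y:
    """5-year absolute risk of a group from its incidence rate.

    Unstandardized: 5 x (cases / person-years) x 100.  Age-standardized:
    the same quantity per 5-year age band, weighted by the age distribution
    of ``standard_ages`` (typically the whole analysis cohort), so that
    groups with different age structures become comparable.
    """
    if len(records) == 0:
        raise ValueError("empty group")
    cases = int(records[event_col].sum())
    py = float(records[time_col].sum())
    if standardization == "none":
        return AbsoluteRisk5y(5.0 * cases / py * 100.0, "none", cases, py)
    if standardization != "age-standardized":
        raise ValueError(f"unknown standardization {standardization!r}")
    if standard_ages is None:
        standard_ages = records[age_col].to_numpy(float)
    std_bands = _banded(np.asarray(standard_ages, dtype=float), band_width)
    band_ids, band_counts = np.unique(std_bands, return_counts=True)
    w = band_counts / band_counts.sum()
    grp_bands = _banded(records[age_col].to_numpy(float), band_width)
    risk = 0.0
    for b, wt in zip(band_ids, w):
        m = grp_bands == b
        if not m.any():
            continue  # band absent from group: contributes the standard weight times 0
        py_b = float(records.loc[m, time_col].sum())
        cases_b = float(records.loc[m, event_col].sum())
        if py_b > 0:
            risk += wt * 5.0 * cases_b / py_b * 100.0
    return AbsoluteRisk5y(float(risk), "age-standardized", cases, py)


def absolute_risk_increase(records: pd.DataFrame, group_a, group_b,
                           standardization: str = "none", standard_ages=None,
                           bootstrap_n: int = 1000, seed: int = 0,
                           sex_col: str = "sex", **risk_kw) -> dict:
    """Risk difference (group_b minus group_a) with a percentile bootstrap CI.

    ``group_a``/``group_b`` are disjoint boolean masks over ``records``.
    Participants are resampled with replacement within group, stratified by
    sex; the same draws feed both groups' risks so the difference is
    coherent.
    """
    a = np.asarray(group_a, dtype=bool)
    b = np.asarray(group_b, dtype=bool)
    if (a & b).any():
        raise ValueError("groups must be disjoint")
    if bootstrap_n < 2:
        raise ValueError("bootstrap_n must be >= 2")
    risk_a = absolute_risk_5y(records.loc[a], standardization, standard_ages, **risk_kw)
    risk_b = absolute_risk_5y(records.loc[b], standardization, standard_ages, **risk_kw)
    point = risk_b.risk_pct - risk_a.risk_pct

    rng = np.random.default_rng(seed)
    strata = []
    for mask in (a, b):
        for sex in records.loc[mask, sex_col].unique() if sex_col in records.columns else [None]:
            idx = records.index[mask & ((records[sex_col] == sex).to_numpy()
                                        if sex is not None else mask)]
            strata.append((mask is b, np.asarray(idx)))
    diffs = np.empty(bootstrap_n)
    for r in range(bootstrap_n):
        parts_a, parts_b = [], []
        for is_b, idx in strata:
            take = idx[rng.integers(0, len(idx), size=len(idx))]
            (parts_b if is_b else parts_a).append(take)
        ra = absolute_risk_5y(records.loc[np.concatenate(parts_a)],
                              standardization, standard_ages, **risk_kw)
        rb = absolute_risk_5y(records.loc[np.concatenate(parts_b)],
                              standardization, standard_ages, **risk_kw)
        diffs[r] = rb.risk_pct - ra.risk_pct
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return {"increase_pct": float(point), "ci95": (float(lo), float(hi)),
            "risk_a": risk_a, "risk_b": risk_b, "bootstrap_n": bootstrap_n,
            "seed": seed}


def _joint_dummies(data: pd.DataFrame, genetic_col: str, aging_col: str,
                   reference: tuple) -> tuple[pd.DataFrame, list]:
    gvals = pd.Series(data[genetic_col]).astype(str)
    avals = pd.Series(data[aging_col]).astype(str)
    # full cross of observed levels: an absent combination is an empty cell
    cells = sorted((g, a) for g in gvals.unique() for a in avals.unique())
    ref = (str(reference[0]), str(reference[1]))
    if ref not in cells:
        raise ValueError(f"reference cell {ref} is empty")
    observed = set(zip(gvals, avals))
    empty = [c for c in cells if c not in observed]
    if empty:
        raise ValueError(f"empty joint cell(s): {empty}")
    work = data.copy()
    dummy_cols = []
    for g, a in cells:
        if (g, a) == ref:
            continue
        col = f"joint[{g}|{a}]"
        work[col] = ((gvals == g) & (avals == a)).astype(int).to_numpy()
        dummy_cols.append(col)
    return work, dummy_cols


def joint_category_analysis(data: pd.DataFrame, genetic_col: str = "genetic_group",
                            aging_col: str = "aging_group",
                            reference: tuple = ("low", "younger"),
                            covariates=MODEL1_COVARIATES,
                            duration_col: str = "time_years",
                            event_col: str = "cancer"):
    """Cox model over joint genetic x aging cells vs the (low, younger) cell.

    Returns a CoxFit whose terms are ``joint[<genetic>|<aging>]`` dummies;
    the reference cell has HR 1 by construction and is omitted.
    """
    work, dummy_cols = _joint_dummies(data, genetic_col, aging_col, reference)
    spec = ModelSpec(exposure=tuple(dummy_cols), covariates=tuple(covariates),
                     duration_col=duration_col, event_col=event_col)
    return fit_cox(work, spec, check_proportionality=False)


def reri_ap(hr10: float, hr01: float, hr11: float) -> tuple[float, float]:
    """Additive-interaction indices from the 2x2 joint hazard ratios.

    RERI = HR11 - HR10 - HR01 + 1 (zero when excess risks add);
    AP = RERI / HR11, the share of the doubly-exposed risk attributable to
    interaction.
    """
    for name, v in (("hr10", hr10), ("hr01", hr01), ("hr11", hr11)):
        if not (v > 0):
            raise ValueError(f"{name} must be > 0, got {v}")
    reri = hr11 - hr10 - hr01 + 1.0
    return float(reri), float(reri / hr11)


@dataclass
class InteractionEstimate:
    reri: float
    ap: float
    reri_ci95: tuple
    ap_ci95: tuple
    bootstrap_n: int
    seed: int
    n_redraws: int = 0
    samples: np.ndarray | None = None   # (bootstrap_n, 5): hr10, hr01, hr11, reri, ap


def _fit_2x2(data: pd.DataFrame, exposed_g: str, exposed_a: str,
             genetic_col: str, aging_col: str, covariates,
             duration_col: str, event_col: str) -> tuple[float, float, float]:
    work = data.copy()
    g1 = (work[genetic_col].astype(str) == exposed_g).astype(int)
    a1 = (work[aging_col].astype(str) == exposed_a).astype(int)
    work["_g1a0"] = (g1 & ~a1.astype(bool)).astype(int)
    work["_g0a1"] = (~g1.astype(bool) & a1.astype(bool)).astype(int)
    work["_g1a1"] = (g1.astype(bool) & a1.astype(bool)).astype(int)
    spec = ModelSpec(exposure=("_g1a0", "_g0a1", "_g1a1"), covariates=tuple(covariates),
                     duration_col=duration_col, event_col=event_col)
    fit = fit_cox(work, spec, check_proportionality=False)
    return fit.hr("_g1a0"), fit.hr("_g0a1"), fit.hr("_g1a1")


def reri_ap_bootstrap(data: pd.DataFrame, genetic_col: str = "genetic_group",
                      aging_col: str = "aging_group",
                      exposed_genetic: str = "high", reference_genetic: str = "low",
                      exposed_aging: str = "older", reference_aging: str = "younger",
                      covariates=MODEL1_COVARIATES,
                      duration_col: str = "time_years", event_col: str = "cancer",
                      bootstrap_n: int = 5000, seed: int = 0,
                      max_redraw_frac: float = 0.10,
                      return_samples: bool = False) -> InteractionEstimate:
    """RERI and AP with percentile bootstrap CIs from joint Cox refits.

    Three-level genetic risk is collapsed to its high-vs-low margin
    (intermediate rows dropped) so the interaction is a 2x2 contrast.  Each
    resample refits the joint model; resamples that empty a cell are redrawn
    (counted; more than ``max_redraw_frac`` of draws redrawn raises).
    """
    if bootstrap_n < 2:
        raise ValueError("bootstrap_n must be >= 2")
    keep = data[genetic_col].astype(str).isin([exposed_genetic, reference_genetic])
    df = data.loc[keep].reset_index(drop=True)
    cells = list(zip(df[genetic_col].astype(str), df[aging_col].astype(str)))
    required = {(g, a) for g in (exposed_genetic, reference_genetic)
                for a in (exposed_aging, reference_aging)}
    have = set(cells)
    if required - have:
        raise ValueError(f"empty joint cell(s): {sorted(required - have)}")

    hr10, hr01, hr11 = _fit_2x2(df, exposed_genetic, exposed_aging, genetic_col,
                                aging_col, covariates, duration_col, event_col)
    reri, ap = reri_ap(hr10, hr01, hr11)

    rng = np.random.default_rng(seed)
    reris = np.empty(bootstrap_n)
    aps = np.empty(bootstrap_n)
    hrs = np.empty((bootstrap_n, 3))
    n = len(df)
    redraws = 0
    for r in range(bootstrap_n):
        while True:
            idx = rng.integers(0, n, size=n)
            boot = df.iloc[idx]
            bcells = set(zip(boot[genetic_col].astype(str), boot[aging_col].astype(str)))
            if required <= bcells:
                break
            redraws += 1
            if redraws > max_redraw_frac * bootstrap_n:
                raise RuntimeError(
                    f"more than {max_redraw_frac:.0%} of bootstrap resamples "
                    "emptied a joint cell; cells too sparse")
        h10, h01, h11 = _fit_2x2(boot.reset_index(drop=True), exposed_genetic,
                                 exposed_aging, genetic_col, aging_col,
                                 covariates, duration_col, event_col)
        hrs[r] = (h10, h01, h11)
        reris[r], aps[r] = reri_ap(h10, h01, h11)
    return InteractionEstimate(
        reri=reri, ap=ap,
        reri_ci95=tuple(np.percentile(reris, [2.5, 97.5]).astype(float)),
        ap_ci95=tuple(np.percentile(aps, [2.5, 97.5]).astype(float)),
        bootstrap_n=bootstrap_n, seed=seed, n_redraws=redraws,
        samples=np.column_stack([hrs, reris, aps]) if return_samples else None,
    )


@dataclass
class RiskCurve:
    """5-year absolute risk across chronological age for one group."""

    group: str
    age_grid: np.ndarray
    risk_pct: np.ndarray
    threshold_pct: float
    crossing_age: float | None     # None when the threshold is never reached

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.group, "age": self.age_grid,
                             "risk_pct": self.risk_pct})


def risk_by_age_curve(records: pd.DataFrame, group_col: str = "aging_group",
                      age_col: str = "age", time_col: str = "time_years",
                      event_col: str = "cancer", age_grid=None,
                      threshold_pct: float = 2.0,
                      half_window: float = 2.5) -> dict[str, RiskCurve]:
    """5-year absolute risk in sliding age windows, per group.

    At each grid age a, risk is 5 x rate x 100 among participants whose
    baseline age falls in [a - half_window, a + half_window]; smoothing
    comes only from window overlap.  The crossing age is the first grid age
    where the risk meets ``threshold_pct``, linearly interpolated between
    the bracketing grid points; a curve that never reaches it is flagged by
    ``crossing_age=None``.
    """
    ages = records[age_col].to_numpy(float)
    if age_grid is None:
        age_grid = np.arange(np.ceil(ages.min() + half_window),
                             np.floor(ages.max() - half_window) + 1.0)
    age_grid = np.asarray(age_grid, dtype=float)
    if age_grid.size == 0 or age_grid.min() < ages.min() - half_window \
            or age_grid.max() > ages.max() + half_window:
        raise ValueError("age grid must lie within the observed age span")
    out = {}
    for g, grp in records.groupby(group_col, observed=True):
        gages = grp[age_col].to_numpy(float)
        risk = np.full(age_grid.size, np.nan)
        for i, a in enumerate(age_grid):
            m = (gages >= a - half_window) & (gages <= a + half_window)
            if not m.any():
                continue
            py = float(grp.loc[m, time_col].sum())
            cases = float(grp.loc[m, event_col].sum())
            if py > 0:
                risk[i] = 5.0 * cases / py * 100.0
        crossing = None
        valid = ~np.isnan(risk)
        above = valid & (risk >= threshold_pct)
        if above.any():
            j = int(np.argmax(above))
            if j == 0 or not valid[j - 1]:
                crossing = float(age_grid[j])
            else:
                a0, a1 = age_grid[j - 1], age_grid[j]
                r0, r1 = risk[j - 1], risk[j]
                crossing = float(a0 + (threshold_pct - r0) / (r1 - r0) * (a1 - a0))
        out[str(g)] = RiskCurve(group=str(g), age_grid=age_grid, risk_pct=risk,
                                threshold_pct=threshold_pct, crossing_age=crossing)
    return out
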