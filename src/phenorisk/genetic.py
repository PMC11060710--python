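"""Incidence-weighted overall-cancer polygenic risk score (CPRS).

A participant's CPRS is the weighted sum of their site-specific polygenic
risk scores, CPRS_i = sum_k h_k * PRS_{i,k}, where h_k is the
age-standardized incidence of cancer site k in the participant's sex.  Sites
with higher population burden therefore contribute more to the overall
genetic-risk ranking.  Because the cancer incidence spectrum differs sharply
between men and women (prostate vs breast, etc.), the score is constructed
within sex throughout.

The default weight table shipped with the package
(``data/cprs_weights_default.tsv``) holds approximate UK age-standardized
incidences per 100,000 by sex for the 20 sites; it is an editable input, not
a constant — pass your own table for any serious use.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_cprs_weights",
    "default_cprs_weights",
    "site_prs_columns",
    "standardize_site_prs",
    "compute_cprs",
    "RiskGroupAssignment",
    "assign_risk_groups",
    "assign_risk_groups_by_sex",
]

_SCHEMES = {
    "quintile": (0.2, 0.4, 0.6, 0.8),
    "quartile": (0.25, 0.5, 0.75),
    "tertile": (1 / 3, 2 / 3),
}


def _validate_weights(df: pd.DataFrame) -> pd.DataFrame:
    required = {"cancer_site", "sex", "incidence_per_100k"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if (df["incidence_per_100k"] < 0).any():
        raise ValueError("incidence weights must be non-negative")
    dup = df.duplicated(subset=["cancer_site", "sex"])
    if dup.any():
        raise ValueError(f"duplicate (site, sex) weight rows: "
                         f"{df.loc[dup, ['cancer_site', 'sex']].to_records(index=False)}")
    return df


def load_cprs_weights(path) -> pd.DataFrame:
    """Read a tab-delimited (cancer_site, sex, incidence_per_100k) table."""
    return _validate_weights(pd.read_csv(path, sep="\t"))


def default_cprs_weights() -> pd.DataFrame:
    """Approximate per-sex UK incidence weights for the 20 default sites."""
    with resources.files("phenorisk.data").joinpath("cprs_weights_default.tsv").open() as fh:
        return _validate_weights(pd.read_csv(fh, sep="\t"))


def site_prs_columns(table: pd.DataFrame, prefix: str = "prs_") -> list[str]:
    """Columns holding site-specific PRS values, by naming convention."""
    return [c for c in table.columns if c.startswith(prefix)]


def standardize_site_prs(scores: pd.DataFrame, site_cols=None, sex_col: str = "sex",
                         prefix: str = "prs_") -> pd.DataFrame:
    """Z-standardize each site PRS column within sex (population SD, ddof=0).

    Standardization puts the site scores on a common scale before incidence
    weighting; idempotent to numerical precision.
    """
    cols = list(site_cols) if site_cols is not None else site_prs_columns(scores, prefix)
    if not cols:
        raise ValueError("no site PRS columns found")
    out = scores.copy()
    for sex, idx in scores.groupby(sex_col, sort=False).groups.items():
        if len(idx) < 2:
            raise ValueError(f"need >= 2 participants per sex; {sex} has {len(idx)}")
        block = scores.loc[idx, cols].to_numpy(float)
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        if np.any(sd == 0):
            bad = [cols[j] for j in np.where(sd == 0)[0]]
            raise ValueError(f"zero-variance PRS column(s) within sex={sex}: {bad}")
        out.loc[idx, cols] = (block - mu) / sd
    return out


def compute_cprs(scores: pd.DataFrame, weights: pd.DataFrame, site_cols=None,
                 sex_col: str = "sex", prefix: str = "prs_") -> pd.Series:
    """CPRS_i = sum_k h_k * PRS_{i,k}, with sex-specific weights h_k.

    Every site PRS column must have a weight row for each sex present in the
    data; a missing weight raises rather than silently dropping the site.
    """
    _validate_weights(weights)
    cols = list(site_cols) if site_cols is not None else site_prs_columns(scores, prefix)
    if not cols:
        raise ValueError("no site PRS columns found")
    sites = [c.removeprefix(prefix) for c in cols]
    cprs = pd.Series(np.nan, index=scores.index, name="cprs", dtype=float)
    for sex, idx in scores.groupby(sex_col, sort=False).groups.items():
        wsex = weights[weights["sex"] == sex].set_index("cancer_site")["incidence_per_100k"]
        missing = [s for s in sites if s not in wsex.index]
        if missing:
            raise KeyError(f"no incidence weight for site(s) {missing} (sex={sex})")
        h = wsex.loc[sites].to_numpy(float)
        cprs.loc[idx] = scores.loc[idx, cols].to_numpy(float) @ h
    return cprs


@dataclass
class RiskGroupAssignment:
    """Low / intermediate / high strata from quantile cuts of a score."""

    group: pd.Series          # categorical: low < intermediate < high
    scheme: str
    cut_points: np.ndarray    # score values at the scheme's quantiles

    @property
    def counts(self) -> pd.Series:
        return self.group.value_counts().reindex(["low", "intermediate", "high"]).fillna(0).astype(int)


def assign_risk_groups(values, scheme: str = "quintile") -> RiskGroupAssignment:
    """Cut a score into low / intermediate / high by quantiles.

    Quintile: bottom fifth = low, fifths 2-4 = intermediate, top fifth =
    high; quartile and tertile analogues for sensitivity analyses.  Quantiles
    use type-7 linear interpolation; a value equal to a cut point goes to the
    lower stratum.  Heavy ties that empty a stratum raise, reporting the cut
    points.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(_SCHEMES)}")
    v = pd.Series(values).astype(float)
    qs = _SCHEMES[scheme]
    if v.size < len(qs) + 1:
        raise ValueError(f"need >= {len(qs) + 1} participants for {scheme} grouping")
    cuts = np.quantile(v.to_numpy(), qs)
    stratum = np.searchsorted(cuts, v.to_numpy(), side="left")  # boundary -> lower
    n_strata = len(qs) + 1
    sizes = np.bincount(stratum, minlength=n_strata)
    if np.any(sizes == 0):
        raise ValueError(f"tied values empty a {scheme} stratum; cut points: {cuts}")
    labels = np.where(stratum == 0, "low",
                      np.where(stratum == n_strata - 1, "high", "intermediate"))
    group = pd.Series(pd.Categorical(labels, categories=["low", "intermediate", "high"],
                                     ordered=True), index=v.index, name="risk_group")
    return RiskGroupAssignment(group=group, scheme=scheme, cut_points=cuts)


def assign_risk_groups_by_sex(table: pd.DataFrame, value_col: str,
                              scheme: str = "quintile", sex_col: str = "sex") -> pd.Series:
    """Apply :func:`assign_risk_groups` within each sex; returns the labels."""
    out = pd.Series(pd.Categorical([None] * len(table),
                                   categories=["low", "intermediate", "high"], ordered=True),
                    index=table.index)
    for _, idx in table.groupby(sex_col, sort=False).groups.items():
        out.loc[idx] = assign_risk_groups(table.loc[idx, value_col], scheme).group.values
    return out
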