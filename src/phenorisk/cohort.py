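"""Synthetic cohort generator with known ground truth.

Emulates the structure of a middle-aged population cohort: ages 40-70,
nine age-trending clinical-chemistry biomarkers drawn from a multivariate
normal (C-reactive protein log-normal), five lifestyle factors with a latent
effect on the biomarker profile, 20 site-specific polygenic scores, and
cancer / death event times drawn from Gompertz proportional-hazards models
whose log hazard is linear in the true PhenoAgeAccel, the incidence-weighted
genetic score, and age.  Administrative censoring truncates follow-up.

Because the event-time log-HRs are inputs, cohorts from this module support
parameter-recovery tests: a correctly implemented analysis should get the
configured values back, up to sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from . import genetic, phenoage
from .gompertz import sample_gompertz_ph

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort", "inject_missing"]

#: per-biomarker (intercept, slope-per-year-of-age); "crp" is on the ln scale
_DEFAULT_MEANS = {
    "albumin": (47.5, -0.040),
    "creatinine": (55.0, 0.150),
    "glucose": (4.30, 0.012),
    "crp": (-3.50, 0.028),
    "lymphocyte_pct": (36.0, -0.130),
    "mcv": (88.2, 0.050),
    "rdw": (12.6, 0.0125),
    "alp": (64.0, 0.300),
    "wbc": (6.50, 0.005),
}

_DEFAULT_SD = {
    "albumin": 2.4, "creatinine": 12.0, "glucose": 0.6, "crp": 1.0,
    "lymphocyte_pct": 6.0, "mcv": 4.0, "rdw": 0.9, "alp": 22.0, "wbc": 1.6,
}

#: additive male shifts on the biomarker mean (crp on ln scale)
_DEFAULT_MALE_SHIFT = {"albumin": 0.6, "creatinine": 16.0, "alp": -3.0}

#: physiologic floors applied after the normal draw
_FLOORS = {
    "albumin": 25.0, "creatinine": 25.0, "glucose": 2.5, "lymphocyte_pct": 2.0,
    "mcv": 60.0, "rdw": 10.0, "alp": 10.0, "wbc": 1.5,
}

_DEFAULT_LIFESTYLE_PREV = {
    "no_current_smoking": 0.56,
    "no_alcohol": 0.045,
    "regular_activity": 0.64,
    "normal_bmi": 0.75,
    "healthy_diet": 0.25,
}

#: outcome / identity columns that must never be masked
PROTECTED_COLUMNS = ("id", "sex", "time_years", "cancer", "death_time_years", "death")


def _default_cov() -> np.ndarray:
    names = list(phenoage.BIOMARKERS)
    sd = np.array([_DEFAULT_SD[b] for b in names])
    corr = np.eye(len(names))

    def set_corr(a, b, r):
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = r

    # inflammation cluster: CRP, WBC up together, lymphocyte fraction down
    set_corr("crp", "wbc", 0.30)
    set_corr("crp", "rdw", 0.15)
    set_corr("wbc", "lymphocyte_pct", -0.20)
    set_corr("albumin", "crp", -0.20)
    set_corr("mcv", "rdw", 0.10)
    return corr * np.outer(sd, sd)


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of a synthetic cohort.

    The hazard of the simulated cancer process is
    ``b * exp(g*t) * exp(lp)`` with
    ``lp = loghr_age*(age - mean age) + loghr_accel*(PhenoAgeAccel/5)
    + loghr_cprs * standardized CPRS``; death has its own Gompertz baseline
    with log hazard proportional to the mortality predictor xb, so the
    biomarkers that age a participant also kill them.
    """

    n_participants: int = 10_000
    seed: int = 0
    prop_male: float = 0.463            # men / total in the emulated cohort
    age_range: tuple = (40.0, 70.0)
    biomarker_means_by_age: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    biomarker_cov: np.ndarray = field(default_factory=_default_cov)
    male_mean_shift: dict = field(default_factory=lambda: dict(_DEFAULT_MALE_SHIFT))
    lifestyle_prevalence: dict = field(default_factory=lambda: dict(_DEFAULT_LIFESTYLE_PREV))
    lifestyle_effect_on_accel: float = -1.0   # PhenoAgeAccel years per healthy factor
    true_loghr_phenoaccel_per5y: float = float(np.log(1.15))
    true_loghr_cprs_per_sd: float = float(np.log(1.30))
    true_loghr_age_per_year: float = 0.085
    baseline_gompertz: tuple = (0.006, 0.08)       # cancer (rate/yr, shape/yr)
    death_baseline_gompertz: tuple = (0.004, 0.09)
    death_loghr_xb: float = 1.0
    admin_censor_years: float = 7.1
    missing_rate: float = 0.0
    cprs_weights: pd.DataFrame | None = None       # defaults to the shipped table

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name, frac in [("prop_male", self.prop_male),
                           ("missing_rate", self.missing_rate)]:
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.missing_rate >= 1.0:
            raise ValueError("missing_rate must be < 1")
        cov = np.asarray(self.biomarker_cov, dtype=float)
        if cov.shape != (9, 9) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("biomarker_cov must be a symmetric 9x9 matrix")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("biomarker_cov is not positive-definite") from exc
        if self.baseline_gompertz[0] <= 0 or self.death_baseline_gompertz[0] <= 0:
            raise ValueError("Gompertz baseline rate must be > 0")
        if self.admin_censor_years < 0:
            raise ValueError("admin_censor_years must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["biomarker_cov"] = np.asarray(self.biomarker_cov).tolist()
        d["age_range"] = list(self.age_range)
        d["baseline_gompertz"] = list(self.baseline_gompertz)
        d["death_baseline_gompertz"] = list(self.death_baseline_gompertz)
        d.pop("cprs_weights")
        return d


@dataclass
class SyntheticCohort:
    """Participant table plus the ground truth that generated it."""

    table: pd.DataFrame
    truth: pd.DataFrame         # per-participant latent quantities
    config: GeneratorConfig

    def write(self, outdir, stem: str = "cohort"):
        """Write the table as CSV and Parquet with a YAML truth sidecar."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / f"{stem}.csv", index=False)
        try:
            self.table.to_parquet(outdir / f"{stem}.parquet", index=False)
        except ImportError:  # pragma: no cover - pyarrow assumed present
            pass
        with open(outdir / f"{stem}.truth.yaml", "w") as fh:
            yaml.safe_dump({"generator_config": self.config.to_dict()}, fh)
        return outdir / f"{stem}.csv"


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a cohort; byte-identical for a fixed config (single seeded RNG)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    names = list(phenoage.BIOMARKERS)

    sex = np.where(rng.uniform(size=n) < config.prop_male, "male", "female")
    male = sex == "male"
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)

    # lifestyle factors: independent Bernoullis; the factor count then shifts
    # the biomarker profile so that PhenoAgeAccel moves by
    # lifestyle_effect_on_accel years per healthy factor
    prev = config.lifestyle_prevalence
    factors = {f: rng.uniform(size=n) < p for f, p in prev.items()}
    n_factors = np.sum([factors[f] for f in prev], axis=0).astype(float)
    expected_factors = float(sum(prev.values()))
    dxb = (n_factors - expected_factors) * config.lifestyle_effect_on_accel * 0.09165

    # biomarkers: MVN on the working scale (ln CRP), age-indexed means
    L = np.linalg.cholesky(np.asarray(config.biomarker_cov, dtype=float))
    draws = rng.standard_normal((n, 9)) @ L.T
    means = np.empty((n, 9))
    for j, b in enumerate(names):
        icpt, slope = config.biomarker_means_by_age[b]
        means[:, j] = icpt + slope * age
        shift = config.male_mean_shift.get(b, 0.0)
        if shift:
            means[:, j] += shift * male
    X = means + draws
    coef = phenoage.PHENOAGE_2018
    # spread the lifestyle xb shift over the inflammation markers
    X[:, names.index("crp")] += 0.5 * dxb / coef.beta_lncrp
    X[:, names.index("rdw")] += 0.3 * dxb / coef.beta_rdw
    X[:, names.index("wbc")] += 0.2 * dxb / coef.beta_wbc
    X[:, names.index("crp")] = np.exp(X[:, names.index("crp")])
    for j, b in enumerate(names):
        if b in _FLOORS:
            X[:, j] = np.maximum(X[:, j], _FLOORS[b])

    biomarkers = pd.DataFrame(X, columns=names)

    height = np.where(male, rng.normal(176.0, 6.8, size=n), rng.normal(162.3, 6.2, size=n))
    family_history = rng.uniform(size=n) < 0.345
    townsend = rng.normal(-1.6, 3.0, size=n)
    pcs = rng.standard_normal((n, 10))

    weights = config.cprs_weights if config.cprs_weights is not None \
        else genetic.default_cprs_weights()
    sites = weights["cancer_site"].unique().tolist()
    prs = rng.standard_normal((n, len(sites)))
    prs_df = pd.DataFrame(prs, columns=[f"prs_{s}" for s in sites])
    prs_df["sex"] = sex

    # ground-truth aging and genetic scores
    xb = phenoage.compute_xb(biomarkers, age, coef)
    pheno = phenoage.compute_phenoage(xb, coef)
    if n >= 3 and np.ptp(age) > 0:
        accel = phenoage.compute_phenoaccel(pheno, age)
    else:
        accel = pheno - pheno.mean()
    cprs_raw = genetic.compute_cprs(prs_df, weights)
    cprs_z = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        if m.sum() >= 2:
            v = cprs_raw[m].to_numpy()
            cprs_z[m] = (v - v.mean()) / v.std()
        elif m.any():
            cprs_z[m] = 0.0

    lp_cancer = (config.true_loghr_age_per_year * (age - age.mean())
                 + config.true_loghr_phenoaccel_per5y * (accel / 5.0)
                 + config.true_loghr_cprs_per_sd * cprs_z)
    b_c, g_c = config.baseline_gompertz
    t_cancer = sample_gompertz_ph(rng, b_c, g_c, lp_cancer)

    lp_death = config.death_loghr_xb * (xb - xb.mean())
    b_d, g_d = config.death_baseline_gompertz
    t_death = sample_gompertz_ph(rng, b_d, g_d, lp_death)

    cens = config.admin_censor_years
    time = np.minimum.reduce([t_cancer, t_death, np.full(n, cens)])
    cancer_event = (t_cancer <= np.minimum(t_death, cens)).astype(int)
    death_time = np.minimum(t_death, cens)
    death_event = (t_death < cens).astype(int)

    table = pd.DataFrame({"id": np.arange(n), "sex": sex, "age": age})
    table = pd.concat([table, biomarkers], axis=1)
    table["height"] = height
    table["family_history"] = family_history.astype(int)
    table["townsend"] = townsend
    for k in range(10):
        table[f"pc{k + 1}"] = pcs[:, k]
    for f in prev:
        table[f] = factors[f].astype(int)
    table["lifestyle_index"] = n_factors.astype(int)
    for j, s in enumerate(sites):
        table[f"prs_{s}"] = prs[:, j]
    table["time_years"] = time
    table["cancer"] = cancer_event
    table["death_time_years"] = death_time
    table["death"] = death_event
    # exclusion / sensitivity flag columns
    table["prior_cancer"] = (rng.uniform(size=n) < 0.023).astype(int)
    table["withdrawn"] = (rng.uniform(size=n) < 0.001).astype(int)
    table["sex_mismatch"] = (rng.uniform(size=n) < 0.001).astype(int)
    table["unrelated_british"] = (rng.uniform(size=n) < 0.85).astype(int)

    truth = pd.DataFrame({
        "id": table["id"], "xb_true": xb, "phenoage_true": pheno,
        "phenoaccel_true": accel, "cprs_z_true": cprs_z,
        "lp_cancer_true": lp_cancer, "t_cancer_latent": t_cancer,
        "t_death_latent": t_death,
    })

    cohort = SyntheticCohort(table=table, truth=truth, config=config)
    if config.missing_rate > 0:
        # derive a sub-seed so the masking stream is decoupled from the draws
        cohort = inject_missing(cohort, config.missing_rate,
                                seed=int(np.random.SeedSequence(config.seed).generate_state(2)[1] % (2**31)))
    return cohort


def covariate_columns(table: pd.DataFrame) -> list[str]:
    """Columns eligible for MCAR masking (everything but outcomes/identity
    and the simulation flags)."""
    skip = set(PROTECTED_COLUMNS) | {"prior_cancer", "withdrawn", "sex_mismatch",
                                     "unrelated_british", "lifestyle_index"}
    skip |= {c for c in table.columns if c.startswith("prs_")}
    return [c for c in table.columns if c not in skip]


def inject_missing(cohort: SyntheticCohort | pd.DataFrame, rate: float, seed: int,
                   columns=None):
    """Mask covariate cells missing-completely-at-random at the given rate.

    Outcome and identity columns are protected; requesting one raises.
    Returns the same type as the input.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"missing rate must lie in [0, 1), got {rate}")
    table = cohort.table if isinstance(cohort, SyntheticCohort) else cohort
    cols = list(columns) if columns is not None else covariate_columns(table)
    banned = [c for c in cols if c in PROTECTED_COLUMNS]
    if banned:
        raise ValueError(f"refusing to mask outcome/identity column(s): {banned}")
    out = table.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        for c in cols:
            mask = rng.uniform(size=len(out)) < rate
            col = out[c].astype(float) if out[c].dtype.kind in "ib" else out[c].copy()
            col[mask] = np.nan
            out[c] = col
    if isinstance(cohort, SyntheticCohort):
        return SyntheticCohort(table=out, truth=cohort.truth, config=cohort.config)
    return out
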