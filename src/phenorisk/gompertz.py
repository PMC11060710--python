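"""Gompertz proportional-hazards model: sampling, maximum likelihood, retraining.

The hazard is h(t | x) = b * exp(g*t) * exp(beta . x) with scale b > 0 and
shape g; the cumulative hazard has the closed form H(t|x) =
(b/g)(e^{g t} - 1) e^{beta.x}, which gives exact inverse-transform sampling
and an explicit log-likelihood.  This is the model family behind the
PhenoAge mortality score, so a cohort with death follow-up can be used to
refit ("retrain") the full clock: a multivariable fit on the biomarkers
defines the mortality score, and a univariate age-only fit supplies the
mapping from score back to years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .phenoage import BIOMARKERS, PhenoAgeCoefficients

__all__ = [
    "sample_gompertz_ph",
    "GompertzPHFit",
    "fit_gompertz_ph",
    "retrain_phenoage",
]


def sample_gompertz_ph(rng: np.random.Generator, baseline_rate: float, shape: float,
                       log_relative_hazard):
    """Draw event times from the Gompertz-PH survival function.

    Inverse-transform: with U ~ Uniform(0,1) and m = exp(log relative hazard),
    t = (1/g) * ln(1 - g*ln(U) / (b*m)); the g -> 0 limit is exponential.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline rate b must be > 0")
    lp = np.asarray(log_relative_hazard, dtype=float)
    u = rng.uniform(size=lp.shape)
    bm = baseline_rate * np.exp(lp)
    if abs(shape) < 1e-12:
        return -np.log(u) / bm
    arg = 1.0 - shape * np.log(u) / bm
    # for g < 0 a fraction of subjects never fail; arg <= 0 encodes t = +inf
    t = np.full_like(lp, np.inf)
    ok = arg > 0
    t[ok] = np.log(arg[ok]) / shape
    return t


@dataclass
class GompertzPHFit:
    """MLE of (log b, g, beta) with covariance from the observed information."""

    log_b: float
    shape: float
    beta: dict
    se: dict            # keyed like beta, plus "log_b" and "shape"
    cov: np.ndarray     # in the order (log_b, shape, *features)
    feature_names: list
    loglik: float
    n: int
    events: int
    grad_norm: float

    @property
    def baseline_rate(self) -> float:
        return math.exp(self.log_b)


def _ngll_and_grad(theta, t, d, X):
    """Negative log-likelihood and gradient; theta = (log b, g, beta)."""
    logb, g = theta[0], theta[1]
    beta = theta[2:]
    eta = X @ beta
    b = np.exp(logb)
    gt = g * t
    if abs(g) < 1e-10:
        cumfac = t * (1.0 + gt / 2.0 + gt * gt / 6.0)
        dcum_dg = t * t / 2.0
    else:
        egt = np.exp(gt)
        cumfac = (egt - 1.0) / g
        dcum_dg = (t * egt * g - (egt - 1.0)) / (g * g)
    H = b * cumfac * np.exp(eta)
    ll = np.sum(d * (logb + gt + eta)) - np.sum(H)
    grad = np.empty_like(theta)
    grad[0] = np.sum(d) - np.sum(H)
    grad[1] = np.sum(d * t) - np.sum(b * np.exp(eta) * dcum_dg)
    grad[2:] = X.T @ (d - H)
    return -ll, -grad


def fit_gompertz_ph(time, event, covariates: pd.DataFrame | np.ndarray | None = None,
                    feature_names=None, max_iter: int = 500,
                    grad_tol: float = 1e-6) -> GompertzPHFit:
    """Maximum-likelihood Gompertz-PH fit with analytic gradient.

    Covariates are standardized internally for conditioning and the estimates
    mapped back to the raw scale (an exact reparameterization).  Convergence
    requires the (standardized-scale) gradient norm to fall below
    ``grad_tol``; failure raises with the final norm attached.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    if np.any(t <= 0):
        raise ValueError("event/censoring times must be positive")
    events = int(d.sum())
    if events == 0:
        raise ValueError("no deaths in cohort: Gompertz likelihood is degenerate")
    if covariates is None:
        X = np.empty((t.size, 0))
        names = []
    elif isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(float)
    else:
        X = np.asarray(covariates, dtype=float)
        names = list(feature_names) if feature_names else [f"x{j}" for j in range(X.shape[1])]

    mu = X.mean(axis=0) if X.size else np.zeros(0)
    sd = X.std(axis=0) if X.size else np.zeros(0)
    if X.size and np.any(sd == 0):
        bad = [names[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"constant covariate columns: {bad}")
    Z = (X - mu) / sd if X.size else X

    theta0 = np.zeros(2 + Z.shape[1])
    theta0[0] = math.log(events / t.sum())  # crude exponential rate
    theta0[1] = 0.05
    res = optimize.minimize(_ngll_and_grad, theta0, args=(t, d, Z), jac=True,
                            method="BFGS", options={"gtol": grad_tol / 10, "maxiter": max_iter})
    theta = res.x

    def observed_information(th):
        # central differences of the analytic gradient
        k = th.size
        hess = np.empty((k, k))
        eps = 1e-5 * np.maximum(1.0, np.abs(th))
        for j in range(k):
            hi, lo = th.copy(), th.copy()
            hi[j] += eps[j]
            lo[j] -= eps[j]
            _, ghi = _ngll_and_grad(hi, t, d, Z)
            _, glo = _ngll_and_grad(lo, t, d, Z)
            hess[:, j] = (ghi - glo) / (2 * eps[j])
        return 0.5 * (hess + hess.T)

    # Newton polish: BFGS stops near the optimum; a few exact steps push the
    # gradient norm below the convergence requirement
    gnorm = float(np.linalg.norm(_ngll_and_grad(theta, t, d, Z)[1]))
    for _ in range(20):
        if gnorm <= grad_tol:
            break
        _, grad = _ngll_and_grad(theta, t, d, Z)
        hess = observed_information(theta)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        candidate = theta - step
        cnorm = float(np.linalg.norm(_ngll_and_grad(candidate, t, d, Z)[1]))
        if not np.isfinite(cnorm) or cnorm >= gnorm:
            break
        theta, gnorm = candidate, cnorm
    if gnorm > grad_tol:
        raise RuntimeError(
            f"Gompertz-PH fit did not converge after {res.nit} iterations "
            f"(gradient norm {gnorm:.3e} > {grad_tol:.0e})")

    cov_z = np.linalg.inv(observed_information(theta))

    # map (log b, g, beta_z) back to raw covariates: beta = beta_z/sd,
    # log b -= sum(beta_z * mu / sd)
    beta_z = theta[2:]
    beta = beta_z / sd if beta_z.size else beta_z
    log_b = theta[0] - float(beta_z @ (mu / sd)) if beta_z.size else theta[0]
    k = theta.size
    J = np.eye(k)
    if beta_z.size:
        J[0, 2:] = -mu / sd
        J[2:, 2:] = np.diag(1.0 / sd)
    cov = J @ cov_z @ J.T
    se_all = np.sqrt(np.diag(cov))
    se = {"log_b": se_all[0], "shape": se_all[1]}
    se.update({nm: se_all[2 + j] for j, nm in enumerate(names)})
    return GompertzPHFit(
        log_b=float(log_b), shape=float(theta[1]),
        beta={nm: float(b) for nm, b in zip(names, beta)},
        se=se, cov=cov, feature_names=names,
        loglik=float(-res.fun), n=t.size, events=events, grad_norm=gnorm,
    )


def retrain_phenoage(cohort: pd.DataFrame, time_col: str = "death_time_years",
                     event_col: str = "death", age_col: str = "age",
                     horizon_years: float = 10.0,
                     min_n: int = 200, min_deaths: int = 20) -> PhenoAgeCoefficients:
    """Refit the whole clock on a cohort with mortality follow-up.

    Two-stage construction mirroring the published clock: (1) a
    multivariable Gompertz-PH fit of death on the nine biomarkers (ln CRP)
    plus chronological age defines the mortality linear predictor xb (the
    fitted log baseline rate becomes the xb intercept); (2) a univariate
    age-only Gompertz-PH fit supplies the score-to-years mapping
    (c2 = the age slope, c1 and the outer offset from its scale and shape).
    The returned set has the shape/horizon expressed per year over a
    ``horizon_years`` window and is a drop-in replacement for the published
    constants.
    """
    need = list(BIOMARKERS) + [age_col, time_col, event_col]
    missing = [c for c in need if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing columns: {missing}")
    df = cohort.dropna(subset=need)
    deaths = int(df[event_col].sum())
    if len(df) < min_n or deaths < min_deaths:
        raise ValueError(
            f"retraining needs >= {min_n} participants with >= {min_deaths} deaths; "
            f"got n={len(df)}, deaths={deaths}")

    X = df[list(BIOMARKERS)].copy()
    X["crp"] = np.log(X["crp"].to_numpy(float))
    X = X.rename(columns={"crp": "lncrp"})
    X[age_col] = df[age_col].to_numpy(float)
    multi = fit_gompertz_ph(df[time_col], df[event_col], X)
    uni = fit_gompertz_ph(df[time_col], df[event_col], df[[age_col]])

    a1 = uni.beta[age_col]
    if a1 <= 0:
        raise RuntimeError("age-only Gompertz fit has non-positive age slope; "
                           "score-to-age mapping undefined")
    g2 = uni.shape
    cumfac2 = horizon_years if abs(g2) < 1e-12 else (math.exp(g2 * horizon_years) - 1.0) / g2
    return PhenoAgeCoefficients(
        intercept_xb=multi.log_b,
        beta_albumin=multi.beta["albumin"],
        beta_creatinine=multi.beta["creatinine"],
        beta_glucose=multi.beta["glucose"],
        beta_lncrp=multi.beta["lncrp"],
        beta_lymphocyte_pct=multi.beta["lymphocyte_pct"],
        beta_mcv=multi.beta["mcv"],
        beta_rdw=multi.beta["rdw"],
        beta_alp=multi.beta["alp"],
        beta_wbc=multi.beta["wbc"],
        beta_age=multi.beta[age_col],
        outer_offset=-uni.log_b / a1,
        c1=1.0 / cumfac2,
        c2=a1,
        gompertz_gamma=multi.shape,
        horizon=horizon_years,
        provenance="retrained",
    )
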