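"""End-to-end orchestration: simulate/ingest, score, analyze, report.

One :class:`RunConfig` drives the whole analysis: cohort generation (or a
CSV on disk), participant-flow exclusions, biomarker winsorization and
PhenoAge/PhenoAgeAccel scoring, CPRS construction and risk grouping,
lifestyle indexing, the sex-stratified Cox suite, absolute risks and
bootstrap risk differences, additive interaction, and screening-age curves.
All randomness flows from one root seed through named substreams, so a rerun
with the same config reproduces every stochastic output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genetic, phenoage, risk as risk_mod, survival
from .cohort import GeneratorConfig, SyntheticCohort, generate_cohort
from .lifestyle import regress_accel_on_lifestyle
from .survival import MODEL1_COVARIATES, MODEL2_EXTRA, ModelSpec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "apply_exclusions", "run_pipeline"]

EXCLUSION_RULES = ("withdrawn", "prior_cancer", "sex_mismatch", "missing_phenoage")


@dataclass
class RunConfig:
    """Inputs, stage toggles and seeds for one reproducible run."""

    generator: GeneratorConfig | None = None
    cohort_path: str | None = None           # CSV alternative to the generator
    cprs_weights_path: str | None = None     # defaults to the shipped table
    scheme: str = "quintile"                 # risk-group scheme for CPRS and accel
    ari_bootstrap_n: int = 1000
    reri_bootstrap_n: int = 5000
    seed: int = 0
    run_genetic: bool = True
    run_lifestyle: bool = True
    run_interaction: bool = True
    run_curves: bool = True
    output_dir: str | None = None

    def validate(self):
        if (self.generator is None) == (self.cohort_path is None):
            raise ValueError("exactly one of generator config or cohort_path is required")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise FileNotFoundError(self.cohort_path)
        if self.cprs_weights_path is not None and not Path(self.cprs_weights_path).exists():
            raise FileNotFoundError(self.cprs_weights_path)
        if self.run_genetic and self.cprs_weights_path is None and self.cohort_path is not None:
            # generated cohorts carry default-weight PRS columns; external
            # cohorts must state their weights explicitly
            raise ValueError("genetic stage enabled for an external cohort but "
                             "no CPRS weights file given")
        if self.scheme not in ("quintile", "quartile", "tertile"):
            raise ValueError(f"unknown grouping scheme {self.scheme!r}")

    def config_hash(self) -> str:
        gen = self.generator.to_dict() if self.generator is not None else None
        payload = {k: v for k, v in self.__dict__.items() if k != "generator"}
        payload["generator"] = gen
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Provenance and participant flow of one pipeline run."""

    config_hash: str
    seed: int
    substream_seeds: dict
    flow: list = field(default_factory=list)   # [{"step", "excluded", "remaining"}]
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def check_flow_conservation(self) -> bool:
        for prev, step in zip(self.flow, self.flow[1:]):
            if step["remaining"] != prev["remaining"] - step["excluded"]:
                return False
        return True


def apply_exclusions(cohort: pd.DataFrame, rules=EXCLUSION_RULES
                     ) -> tuple[pd.DataFrame, list]:
    """Sequential participant-flow exclusions with per-rule counts.

    A participant hit by several rules is counted once, at the first
    applicable rule.  ``missing_phenoage`` means any missing value among the
    nine biomarkers or age.  Returns (retained cohort, flow records).
    """
    flow = [{"step": "input", "excluded": 0, "remaining": len(cohort)}]
    work = cohort
    for rule in rules:
        if rule == "missing_phenoage":
            cols = [c for c in phenoage.BIOMARKERS if c in work.columns] + ["age"]
            hit = work[cols].isna().any(axis=1)
        elif rule in work.columns:
            hit = work[rule].fillna(0).astype(bool)
        else:
            raise ValueError(f"unknown exclusion rule {rule!r} (no such column)")
        flow.append({"step": rule, "excluded": int(hit.sum()),
                     "remaining": int((~hit).sum())})
        work = work.loc[~hit]
    return work.copy(), flow


def _cox_suite(df: pd.DataFrame, scheme: str, model2: bool) -> dict:
    """Per-sex PhenoAgeAccel Cox fits: continuous, binary, grouped, decile."""
    results = {}
    work = df.copy()
    work["accel_per5"] = work["phenoaccel"] / 5.0
    work["older"] = (work["phenoaccel"] >= 0).astype(int)
    groups = genetic.assign_risk_groups(work["phenoaccel"], scheme).group
    work["accel_group"] = groups
    work["accel_group_ord"] = groups.cat.codes.astype(float)
    work["accel_int"] = (groups == "intermediate").astype(int)
    work["accel_high"] = (groups == "high").astype(int)

    covs1 = tuple(c for c in MODEL1_COVARIATES if c in work.columns)
    results["per5_m1"] = survival.fit_cox(work, ModelSpec(("accel_per5",), covs1))
    if model2:
        covs2 = covs1 + tuple(c for c in MODEL2_EXTRA if c in work.columns)
        results["per5_m2"] = survival.fit_cox(work, ModelSpec(("accel_per5",), covs2))
    results["binary_m1"] = survival.fit_cox(work, ModelSpec(("older",), covs1))
    results["groups_m1"] = survival.fit_cox(
        work, ModelSpec(("accel_int", "accel_high"), covs1, trend_col="accel_group_ord"))
    try:
        decile_fit, _ = survival.decile_analysis(work, covariates=covs1)
        results["decile_m1"] = decile_fit
    except ValueError as exc:
        logger.warning("decile analysis skipped: %s", exc)
    results["_frame"] = work
    return results


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every enabled stage; see the module docstring for the order.

    Stage failures abort with the stage name; artifacts already written are
    left in place.  Returns the run report (flow counts, output tables,
    seeds); tables are also written to ``config.output_dir`` when set.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    sub = {name: int(s.generate_state(1)[0] % (2**31))
           for name, s in zip(("generator", "bootstrap_ari", "bootstrap_reri"),
                              root.spawn(3))}
    report = RunReport(config_hash=config.config_hash(), seed=config.seed,
                       substream_seeds=sub)
    outputs: dict = {}
    stage = "ingest"
    t0 = _time.perf_counter()
    try:
        # --- ingest / generate -------------------------------------------
        if config.generator is not None:
            gen_cfg = config.generator
            if gen_cfg.seed != sub["generator"]:
                gen_cfg = GeneratorConfig(**{**gen_cfg.__dict__, "seed": sub["generator"]})
            cohort = generate_cohort(gen_cfg)
            table = cohort.table
        else:
            table = pd.read_csv(config.cohort_path)
        report.timings[stage] = _time.perf_counter() - t0

        # --- participant flow --------------------------------------------
        stage = "exclusions"
        rules = [r for r in EXCLUSION_RULES
                 if r == "missing_phenoage" or r in table.columns]
        table, flow = apply_exclusions(table, rules)
        report.flow = flow

        # --- imputation, PhenoAge scoring --------------------------------
        stage = "phenoage"
        if table[list(phenoage.BIOMARKERS) + ["age"]].isna().any().any():
            table, audit = survival.impute_covariates(table)
            outputs["imputation_audit"] = audit
        table = phenoage.phenoage_from_table(table)
        table["aging_group"] = np.where(table["phenoaccel"] >= 0, "older", "younger")

        # --- genetic risk -------------------------------------------------
        stage = "genetic"
        if config.run_genetic:
            weights = (genetic.load_cprs_weights(config.cprs_weights_path)
                       if config.cprs_weights_path else genetic.default_cprs_weights())
            scored = genetic.standardize_site_prs(table)
            table["cprs"] = genetic.compute_cprs(scored, weights)
            z = table.groupby("sex")["cprs"].transform(
                lambda v: (v - v.mean()) / v.std())
            table["cprs_z"] = z
            table["genetic_group"] = genetic.assign_risk_groups_by_sex(
                table, "cprs", config.scheme)

        # --- lifestyle ----------------------------------------------------
        stage = "lifestyle"
        if config.run_lifestyle and "lifestyle_index" in table.columns:
            rows = []
            for sex, grp in table.groupby("sex"):
                covs = [c for c in MODEL1_COVARIATES if c in grp.columns and c != "height"]
                covs = ["age", "height", "family_history", "townsend"] + \
                       [f"pc{k}" for k in range(1, 11)]
                covs = [c for c in covs if c in grp.columns]
                reg = regress_accel_on_lifestyle(grp["phenoaccel"],
                                                 grp["lifestyle_index"], grp[covs])
                rows.append({"sex": sex, "beta": reg.slope, "se": reg.se,
                             "p": reg.p_value, "n": reg.n})
            outputs["lifestyle_regression"] = pd.DataFrame(rows)

        # --- Cox suite ----------------------------------------------------
        stage = "cox"
        tidy_rows = []
        frames = {}
        for sex, grp in table.groupby("sex"):
            suite = _cox_suite(grp, config.scheme, model2=config.run_genetic)
            frames[sex] = suite.pop("_frame")
            for model_name, fit in suite.items():
                t = fit.to_tidy()
                t.insert(0, "model", model_name)
                t.insert(0, "sex", sex)
                if fit.trend_p is not None:
                    t["trend_p"] = fit.trend_p
                tidy_rows.append(t)
        outputs["cox_models"] = pd.concat(tidy_rows, ignore_index=True)

        # --- joint categories, rates, absolute risk ------------------------
        stage = "joint_risk"
        if config.run_genetic:
            joint_rows, strat_rows = [], []
            for sex, grp in frames.items():
                grp = grp.assign(aging_group=table.loc[grp.index, "aging_group"],
                                 genetic_group=table.loc[grp.index, "genetic_group"])
                covs1 = tuple(c for c in MODEL1_COVARIATES if c in grp.columns)
                jfit = risk_mod.joint_category_analysis(grp, covariates=covs1)
                t = jfit.to_tidy()
                t.insert(0, "sex", sex)
                joint_rows.append(t)
                std_ages = grp["age"].to_numpy()
                for g in ("low", "intermediate", "high"):
                    for a in ("younger", "older"):
                        cell = grp[(grp["genetic_group"] == g) & (grp["aging_group"] == a)]
                        rate = risk_mod.incidence_rate(int(cell["cancer"].sum()),
                                                       float(cell["time_years"].sum()))
                        ar = risk_mod.absolute_risk_5y(cell, "age-standardized", std_ages)
                        strat_rows.append({
                            "sex": sex, "genetic_group": g, "aging_group": a,
                            "cases": rate.cases, "person_years": rate.person_years,
                            "rate_per_100k": rate.rate, "rate_lo": rate.ci95[0],
                            "rate_hi": rate.ci95[1], "abs_risk_5y_pct": ar.risk_pct,
                        })
                for g in ("low", "intermediate", "high"):
                    mask_y = ((grp["genetic_group"] == g) &
                              (grp["aging_group"] == "younger")).to_numpy()
                    mask_o = ((grp["genetic_group"] == g) &
                              (grp["aging_group"] == "older")).to_numpy()
                    ari = risk_mod.absolute_risk_increase(
                        grp, mask_y, mask_o, standardization="age-standardized",
                        standard_ages=std_ages, bootstrap_n=config.ari_bootstrap_n,
                        seed=sub["bootstrap_ari"])
                    strat_rows.append({
                        "sex": sex, "genetic_group": g, "aging_group": "older-vs-younger",
                        "abs_risk_increase_pct": ari["increase_pct"],
                        "ari_lo": ari["ci95"][0], "ari_hi": ari["ci95"][1],
                    })
            outputs["joint_cox"] = pd.concat(joint_rows, ignore_index=True)
            outputs["stratified_risk"] = pd.DataFrame(strat_rows)

        # --- additive interaction ------------------------------------------
        stage = "interaction"
        if config.run_genetic and config.run_interaction:
            inter_rows = []
            for sex, grp in frames.items():
                grp = grp.assign(aging_group=table.loc[grp.index, "aging_group"],
                                 genetic_group=table.loc[grp.index, "genetic_group"])
                covs1 = tuple(c for c in MODEL1_COVARIATES if c in grp.columns)
                est = risk_mod.reri_ap_bootstrap(
                    grp, covariates=covs1, bootstrap_n=config.reri_bootstrap_n,
                    seed=sub["bootstrap_reri"])
                inter_rows.append({"sex": sex, "reri": est.reri, "ap": est.ap,
                                   "reri_lo": est.reri_ci95[0], "reri_hi": est.reri_ci95[1],
                                   "ap_lo": est.ap_ci95[0], "ap_hi": est.ap_ci95[1],
                                   "bootstrap_n": est.bootstrap_n})
            outputs["interaction"] = pd.DataFrame(inter_rows)

        # --- screening-age curves ------------------------------------------
        stage = "curves"
        if config.run_curves:
            curve_rows, crossing_rows = [], []
            for sex, grp in table.groupby("sex"):
                curves = risk_mod.risk_by_age_curve(grp)
                for name, curve in curves.items():
                    cf = curve.to_frame()
                    cf.insert(0, "sex", sex)
                    curve_rows.append(cf)
                    crossing_rows.append({"sex": sex, "group": name,
                                          "threshold_pct": curve.threshold_pct,
                                          "crossing_age": curve.crossing_age})
            outputs["risk_curves"] = pd.concat(curve_rows, ignore_index=True)
            outputs["screening_ages"] = pd.DataFrame(crossing_rows)

        outputs["analysis_table"] = table
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.outputs = outputs
    report.timings["total"] = _time.perf_counter() - t0
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, obj in outputs.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "run_report.yaml", "w") as fh:
            yaml.safe_dump({"config_hash": report.config_hash, "seed": report.seed,
                            "substream_seeds": report.substream_seeds,
                            "flow": report.flow,
                            "outputs": sorted(outputs)}, fh)
    return report
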