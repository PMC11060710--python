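"""Follow-up assembly, Cox fits vs an independent Newton solver, deciles,
sensitivity filters, imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenorisk import (
    GeneratorConfig,
    ModelSpec,
    assemble_followup,
    decile_analysis,
    fit_cox,
    generate_cohort,
    impute_covariates,
    sensitivity_filters,
)
from oracles import cox_newton


class TestAssembleFollowup:
    def test_diagnosis_before_censor_is_event(self):
        df = pd.DataFrame({"entry_time": [0.0], "diagnosis_time": [3.0],
                           "death_time": [np.nan], "loss_time": [np.nan],
                           "admin_censor_time": [7.0]})
        rec = assemble_followup(df)
        assert rec.loc[0, "time"] == 3.0 and rec.loc[0, "event"] == 1

    def test_death_censors_cancer_outcome(self):
        df = pd.DataFrame({"entry_time": [0.0], "diagnosis_time": [np.nan],
                           "death_time": [2.0], "loss_time": [np.nan],
                           "admin_censor_time": [7.0]})
        rec = assemble_followup(df)
        assert rec.loc[0, "time"] == 2.0 and rec.loc[0, "event"] == 0

    def test_person_years_equal_elementwise_min_oracle(self, rng):
        n = 1000
        entry = rng.uniform(0, 1, n)
        df = pd.DataFrame({
            "entry_time": entry,
            "diagnosis_time": entry + rng.exponential(5, n),
            "death_time": entry + rng.exponential(8, n),
            "loss_time": np.where(rng.uniform(size=n) < 0.1,
                                  entry + rng.uniform(0, 7, n), np.nan),
            "admin_censor_time": entry + 7.0,
        })
        rec = assemble_followup(df)
        oracle = np.nanmin(df[["diagnosis_time", "death_time", "loss_time",
                               "admin_censor_time"]].to_numpy(), axis=1) - entry
        assert rec["person_years"].sum() == pytest.approx(oracle.sum())
        assert (rec["person_years"] == rec["time"]).all()

    def test_terminus_before_entry_rejected(self):
        df = pd.DataFrame({"id": [42], "entry_time": [5.0], "diagnosis_time": [4.0],
                           "admin_censor_time": [12.0]})
        with pytest.raises(ValueError, match="42"):
            assemble_followup(df)


class TestFitCox:
    def test_matches_newton_oracle_to_1e6(self, cox_fixture_50):
        spec = ModelSpec(exposure=("x1", "x2"), covariates=())
        fit = fit_cox(cox_fixture_50, spec, check_proportionality=False)
        beta_o, cov_o = cox_newton(cox_fixture_50["time_years"],
                                   cox_fixture_50["cancer"],
                                   cox_fixture_50[["x1", "x2"]])
        assert fit.loghr("x1") == pytest.approx(beta_o[0], abs=1e-6)
        assert fit.loghr("x2") == pytest.approx(beta_o[1], abs=1e-6)
        assert fit.se("x1") == pytest.approx(np.sqrt(cov_o[0, 0]), abs=1e-6)

    def test_time_unit_change_leaves_hr_unchanged(self, cox_fixture_50):
        spec = ModelSpec(exposure=("x1",), covariates=("x2",))
        fit1 = fit_cox(cox_fixture_50, spec, check_proportionality=False)
        doubled = cox_fixture_50.assign(time_years=2 * cox_fixture_50["time_years"])
        fit2 = fit_cox(doubled, spec, check_proportionality=False)
        assert fit1.hr("x1") == pytest.approx(fit2.hr("x1"), abs=1e-9)

    def test_recovers_true_hr_on_generated_cohort(self):
        cfg = GeneratorConfig(n_participants=30_000, seed=21)
        t = generate_cohort(cfg).table
        from phenorisk import phenoage_from_table
        t = phenoage_from_table(t)
        t["accel_per5"] = t["phenoaccel"] / 5
        spec = ModelSpec(exposure=("accel_per5",), covariates=("age",))
        fit = fit_cox(t, spec, check_proportionality=False)
        assert abs(fit.loghr("accel_per5") - cfg.true_loghr_phenoaccel_per5y) \
            < 3 * fit.se("accel_per5")

    def test_missing_column_rejected(self, cox_fixture_50):
        with pytest.raises(KeyError):
            fit_cox(cox_fixture_50, ModelSpec(exposure=("nope",), covariates=()))

    def test_directional_consistency_of_codings(self):
        """Binary, grouped and per-5-year codings of the same positive
        simulated effect all point the same way."""
        hits = 0
        seeds = range(10)
        for seed in seeds:
            t = generate_cohort(GeneratorConfig(
                n_participants=3000, seed=100 + seed,
                true_loghr_phenoaccel_per5y=0.4)).table
            from phenorisk import phenoage_from_table
            t = phenoage_from_table(t)
            t["accel_per5"] = t["phenoaccel"] / 5
            t["older"] = (t["phenoaccel"] >= 0).astype(int)
            hr_cont = fit_cox(t, ModelSpec(("accel_per5",), ("age",)),
                              check_proportionality=False).hr("accel_per5")
            hr_bin = fit_cox(t, ModelSpec(("older",), ("age",)),
                             check_proportionality=False).hr("older")
            hits += (hr_cont > 1) and (hr_bin > 1)
        assert hits >= 9  # >= 90% of seeds

    def test_trend_p_reported_for_ordered_groups(self, small_table):
        from phenorisk import phenoage_from_table, assign_risk_groups
        t = phenoage_from_table(small_table)
        groups = assign_risk_groups(t["phenoaccel"]).group
        t["g_int"] = (groups == "intermediate").astype(int)
        t["g_high"] = (groups == "high").astype(int)
        t["g_ord"] = groups.cat.codes.astype(float)
        fit = fit_cox(t, ModelSpec(("g_int", "g_high"), ("age",),
                                   trend_col="g_ord"), check_proportionality=False)
        assert fit.trend_p is not None and 0 <= fit.trend_p <= 1


class TestDecile:
    def test_exact_group_sizes(self, rng):
        n = 400
        df = pd.DataFrame({
            "phenoaccel": rng.standard_normal(n),
            "age": rng.uniform(40, 70, n),
            "time_years": rng.exponential(5, n),
            "cancer": (rng.uniform(size=n) < 0.3).astype(int),
        })
        fit, decile = decile_analysis(df, covariates=("age",))
        assert decile.value_counts().eq(40).all()
        assert len(fit.summary[fit.summary.term.str.startswith("phenoaccel_d")]) == 9

    def test_monotone_effect_gives_increasing_hrs(self):
        rhos = []
        for seed in range(5):
            r = np.random.default_rng(300 + seed)
            n = 4000
            accel = r.normal(0, 4.5, n)
            lp = 0.12 * accel
            time = r.exponential(scale=np.exp(-lp) / 0.08)
            df = pd.DataFrame({
                "phenoaccel": accel, "age": r.uniform(40, 70, n),
                "time_years": np.minimum(time, 7.0),
                "cancer": (time < 7.0).astype(int),
            })
            fit, _ = decile_analysis(df, covariates=("age",))
            hrs = fit.summary.set_index("term").loc[
                [f"phenoaccel_d{d}" for d in range(2, 11)], "hr"].to_numpy()
            rhos.append(stats.spearmanr(np.arange(9), hrs).statistic)
        assert np.mean(rhos) > 0.8

    def test_tied_values_rejected(self, rng):
        df = pd.DataFrame({"phenoaccel": np.zeros(200),
                           "age": rng.uniform(40, 70, 200),
                           "time_years": rng.exponential(5, 200),
                           "cancer": np.ones(200, dtype=int)})
        with pytest.raises(ValueError, match="decile"):
            decile_analysis(df, covariates=("age",))


class TestSensitivityFilters:
    def test_two_year_boundary(self):
        df = pd.DataFrame({"time_years": [1.9, 2.1, 1.5],
                           "cancer": [1, 1, 0]})
        out = sensitivity_filters(df, "exclude_first_2y")
        # early case removed, later case and early censoring retained
        assert out["time_years"].tolist() == [2.1, 1.5]

    def test_complete_case_identity_without_missing(self, small_table):
        out = sensitivity_filters(small_table, "complete_case")
        assert len(out) == len(small_table)

    def test_removed_count_matches_predicate_oracle(self, rng):
        n = 500
        df = pd.DataFrame({"time_years": rng.uniform(0, 7, n),
                           "cancer": (rng.uniform(size=n) < 0.5).astype(int)})
        out = sensitivity_filters(df, "exclude_first_2y")
        expected_removed = int(((df.cancer == 1) & (df.time_years <= 2)).sum())
        assert len(df) - len(out) == expected_removed

    def test_unrelated_flag_subset(self, small_table):
        out = sensitivity_filters(small_table, "unrelated_subset_flag")
        assert len(out) == int(small_table["unrelated_british"].sum())

    def test_unknown_filter_rejected(self, small_table):
        with pytest.raises(ValueError, match="unknown"):
            sensitivity_filters(small_table, "bogus")


class TestImpute:
    def test_identity_without_missing(self, small_table):
        out, audit = impute_covariates(small_table)
        pd.testing.assert_frame_equal(out, small_table)
        assert audit.empty

    def test_median_fill(self):
        df = pd.DataFrame({"height": [160.0, 170.0, 180.0, np.nan],
                           "time_years": [1, 2, 3, 4.0],
                           "cancer": [0, 0, 1, 0]})
        out, audit = impute_covariates(df)
        assert out.loc[3, "height"] == 170.0
        assert audit.loc[0, "n_imputed"] == 1

    def test_mcar_masking_error_below_column_sd(self):
        from phenorisk import inject_missing
        coh = generate_cohort(GeneratorConfig(n_participants=3000, seed=13))
        truth = coh.table["townsend"].copy()
        masked = inject_missing(coh.table, 0.1, seed=14, columns=["townsend"])
        out, _ = impute_covariates(masked, columns=["townsend"])
        miss = masked["townsend"].isna()
        mae = (out.loc[miss, "townsend"] - truth[miss]).abs().mean()
        assert mae < truth.std()

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"x": [np.nan, np.nan], "time_years": [1.0, 2.0],
                           "cancer": [0, 1]})
        with pytest.raises(ValueError, match="fully missing"):
            impute_covariates(df, columns=["x"])

    def test_incomplete_outcome_rejected(self):
        df = pd.DataFrame({"x": [1.0, np.nan], "time_years": [1.0, np.nan],
                           "cancer": [0, 1]})
        with pytest.raises(ValueError, match="time_years"):
            impute_covariates(df, columns=["x"])
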