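"""Rates, absolute risks, joint categories, RERI/AP, screening curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenorisk import (
    GeneratorConfig,
    absolute_risk_5y,
    absolute_risk_increase,
    generate_cohort,
    incidence_rate,
    joint_category_analysis,
    phenoage_from_table,
    reri_ap,
    reri_ap_bootstrap,
    risk_by_age_curve,
)


class TestIncidenceRate:
    @pytest.mark.parametrize("cases,py,expected", [
        (1840, 124502, 1477.89),
        (668, 114962, 581.06),
        (1144, 106303, 1076.17),
        (1030, 173195, 594.71),
    ])
    def test_worked_examples(self, cases, py, expected):
        assert incidence_rate(cases, py).rate == pytest.approx(expected, abs=0.005)

    def test_zero_cases_degenerate(self):
        est = incidence_rate(0, 1000.0)
        assert est.rate == 0.0 and est.degenerate

    def test_exact_poisson_interval_contains_normal_point(self):
        est = incidence_rate(100, 50_000.0, exact=True)
        assert est.ci95[0] < est.rate < est.ci95[1]

    def test_nonpositive_person_years_rejected(self):
        with pytest.raises(ValueError):
            incidence_rate(1, 0.0)


class TestAbsoluteRisk:
    def _records(self, cases, n, py_each=5.0, age=50.0):
        return pd.DataFrame({
            "time_years": np.full(n, py_each),
            "cancer": np.r_[np.ones(cases), np.zeros(n - cases)].astype(int),
            "age": np.full(n, age),
        })

    def test_zero_rate_gives_zero_risk(self):
        assert absolute_risk_5y(self._records(0, 100)).risk_pct == 0.0

    def test_single_band_standardized_equals_unstandardized(self):
        rec = self._records(10, 100)
        plain = absolute_risk_5y(rec)
        std = absolute_risk_5y(rec, "age-standardized", rec["age"])
        assert std.risk_pct == pytest.approx(plain.risk_pct)

    def test_two_band_hand_computed_weighted_sum(self):
        young = self._records(5, 100, age=47.0)
        old = self._records(20, 100, age=62.0)
        rec = pd.concat([young, old], ignore_index=True)
        # standard: 150 young, 50 old -> weights 0.75 / 0.25
        standard = np.r_[np.full(150, 47.0), np.full(50, 62.0)]
        got = absolute_risk_5y(rec, "age-standardized", standard)
        rate_y = 5 * 5 / 500 * 100
        rate_o = 5 * 20 / 500 * 100
        assert got.risk_pct == pytest.approx(0.75 * rate_y + 0.25 * rate_o)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            absolute_risk_5y(self._records(0, 100).iloc[:0])


class TestAbsoluteRiskIncrease:
    @pytest.mark.parametrize("risk_b,risk_a,expected", [
        (3.87, 2.71, 1.16),   # men, low genetic risk
        (3.39, 2.83, 0.56),   # women, low genetic risk
        (5.17, 4.58, 0.59),   # women, high genetic risk
    ])
    def test_printed_risk_differences(self, risk_b, risk_a, expected):
        assert risk_b - risk_a == pytest.approx(expected, abs=1e-9)

    def _cohort(self, seed=1, n=2000):
        r = np.random.default_rng(seed)
        return pd.DataFrame({
            "time_years": r.uniform(1, 7, n),
            "cancer": (r.uniform(size=n) < 0.05).astype(int),
            "age": r.uniform(40, 70, n),
            "sex": np.where(r.uniform(size=n) < 0.5, "male", "female"),
        })

    def test_identical_distributions_give_increase_near_zero(self):
        rec = self._cohort()
        half = np.zeros(len(rec), dtype=bool)
        half[: len(rec) // 2] = True
        out = absolute_risk_increase(rec, half, ~half, bootstrap_n=200, seed=3)
        assert out["ci95"][0] <= 0.0 <= out["ci95"][1]

    def test_seeded_bootstrap_deterministic(self):
        rec = self._cohort(2)
        a = np.zeros(len(rec), dtype=bool)
        a[:800] = True
        r1 = absolute_risk_increase(rec, a, ~a, bootstrap_n=200, seed=9)
        r2 = absolute_risk_increase(rec, a, ~a, bootstrap_n=200, seed=9)
        assert r1["ci95"] == r2["ci95"]

    def test_overlapping_groups_rejected(self):
        rec = self._cohort(3)
        m = np.ones(len(rec), dtype=bool)
        with pytest.raises(ValueError, match="disjoint"):
            absolute_risk_increase(rec, m, m)


class TestReriAp:
    def test_null_case(self):
        assert reri_ap(1, 1, 1) == (0.0, 0.0)

    def test_exact_additivity_of_excess_risks(self):
        reri, ap = reri_ap(2.0, 3.0, 4.0)
        assert reri == 0.0 and ap == 0.0

    def test_direct_formula_arithmetic(self):
        reri, ap = reri_ap(1.5, 2.0, 4.0)
        assert reri == pytest.approx(1.5)
        assert ap == pytest.approx(0.375)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="hr01"):
            reri_ap(1.0, 0.0, 2.0)

    @given(st.floats(0.1, 10), st.floats(0.1, 10))
    @settings(deadline=None, max_examples=50)
    def test_additive_construction_always_gives_zero_reri(self, hr10, hr01):
        hr11 = hr10 + hr01 - 1.0
        if hr11 <= 0:
            return
        reri, _ = reri_ap(hr10, hr01, hr11)
        assert reri == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def joint_cohort():
    """Generated cohort with aging and (2-level margin collapses from
    3-level) genetic groups attached."""
    from phenorisk import assign_risk_groups_by_sex

    t = generate_cohort(GeneratorConfig(n_participants=8000, seed=41)).table
    t = phenoage_from_table(t)
    from phenorisk import standardize_site_prs, compute_cprs, default_cprs_weights
    scored = standardize_site_prs(t)
    t["cprs"] = compute_cprs(scored, default_cprs_weights())
    t["genetic_group"] = assign_risk_groups_by_sex(t, "cprs")
    t["aging_group"] = np.where(t["phenoaccel"] >= 0, "older", "younger")
    return t


class TestJointCategories:
    def test_reference_cell_omitted_five_terms(self, joint_cohort):
        fit = joint_category_analysis(joint_cohort, covariates=("age",))
        joint_terms = [t for t in fit.summary["term"] if t.startswith("joint[")]
        assert len(joint_terms) == 5
        assert not any("low|younger" in t for t in joint_terms)

    def test_empty_cell_named(self, joint_cohort):
        broken = joint_cohort[~((joint_cohort.genetic_group == "high")
                                & (joint_cohort.aging_group == "older"))]
        with pytest.raises(ValueError, match="high"):
            joint_category_analysis(broken, covariates=("age",))

    def test_multiplicative_effects_compose_in_joint_cell(self):
        """With multiplicative genetic and aging effects exp(a) and exp(b),
        the doubly-exposed cell fits ~ exp(a+b)."""
        r = np.random.default_rng(55)
        n = 50_000
        g1 = r.uniform(size=n) < 0.5
        a1 = r.uniform(size=n) < 0.5
        a, b = 0.35, 0.50
        lp = a * g1 + b * a1
        time = r.exponential(scale=np.exp(-lp) / 0.02)
        df = pd.DataFrame({
            "time_years": np.minimum(time, 7.0),
            "cancer": (time < 7.0).astype(int),
            "genetic_group": np.where(g1, "high", "low"),
            "aging_group": np.where(a1, "older", "younger"),
            "age": r.uniform(40, 70, n),
        })
        fit = joint_category_analysis(df, covariates=("age",))
        term = "joint[high|older]"
        assert abs(fit.loghr(term) - (a + b)) < 3 * fit.se(term)


class TestReriBootstrap:
    def test_point_estimate_matches_direct_formula(self, joint_cohort):
        men = joint_cohort[joint_cohort.sex == "male"]
        est = reri_ap_bootstrap(men, covariates=("age",), bootstrap_n=20, seed=2)
        from phenorisk.risk import _fit_2x2
        keep = men[men.genetic_group.astype(str).isin(["high", "low"])].reset_index(drop=True)
        h10, h01, h11 = _fit_2x2(keep, "high", "older", "genetic_group",
                                 "aging_group", ("age",), "time_years", "cancer")
        reri_direct, ap_direct = reri_ap(h10, h01, h11)
        assert est.reri == pytest.approx(reri_direct, abs=1e-10)
        assert est.ap == pytest.approx(ap_direct, abs=1e-10)

    def test_seeded_bootstrap_deterministic(self, joint_cohort):
        men = joint_cohort[joint_cohort.sex == "male"]
        a = reri_ap_bootstrap(men, covariates=("age",), bootstrap_n=25, seed=5)
        b = reri_ap_bootstrap(men, covariates=("age",), bootstrap_n=25, seed=5)
        assert a.reri_ci95 == b.reri_ci95 and a.ap_ci95 == b.ap_ci95

    def test_empty_cell_errors(self, joint_cohort):
        broken = joint_cohort[~((joint_cohort.genetic_group == "high")
                                & (joint_cohort.aging_group == "older"))]
        with pytest.raises(ValueError, match="empty joint cell"):
            reri_ap_bootstrap(broken, covariates=("age",), bootstrap_n=10, seed=1)


class TestRiskByAgeCurve:
    def _records(self, spec):
        """spec: list of (age, n, cases, py_each)."""
        frames = []
        for age, n, cases, py_each in spec:
            frames.append(pd.DataFrame({
                "age": np.full(n, float(age)),
                "time_years": np.full(n, py_each),
                "cancer": np.r_[np.ones(cases), np.zeros(n - cases)].astype(int),
                "group": "g",
            }))
        return pd.concat(frames, ignore_index=True)

    def test_linear_interpolation_of_crossing(self):
        # risk 1.8% at age 50, 2.2% at age 52 -> crossing at 51.0
        rec = self._records([(50, 500, 9, 5.0), (52, 500, 11, 5.0)])
        curves = risk_by_age_curve(rec, group_col="group",
                                   age_grid=[50.0, 52.0], half_window=0.5)
        assert curves["g"].risk_pct == pytest.approx([1.8, 2.2])
        assert curves["g"].crossing_age == pytest.approx(51.0)

    def test_constant_risk_crosses_at_grid_start(self):
        rec = self._records([(50, 500, 15, 5.0), (52, 500, 15, 5.0)])
        curves = risk_by_age_curve(rec, group_col="group",
                                   age_grid=[50.0, 52.0], half_window=0.5)
        assert curves["g"].crossing_age == 50.0

    def test_threshold_never_reached_is_flagged(self):
        rec = self._records([(50, 500, 1, 5.0), (52, 500, 1, 5.0)])
        curves = risk_by_age_curve(rec, group_col="group",
                                   age_grid=[50.0, 52.0], half_window=0.5)
        assert curves["g"].crossing_age is None

    def test_grid_outside_span_rejected(self):
        rec = self._records([(50, 100, 5, 5.0)])
        with pytest.raises(ValueError, match="span"):
            risk_by_age_curve(rec, group_col="group", age_grid=[80.0])

    def test_older_group_crosses_before_younger_on_generated_cohort(self):
        t = generate_cohort(GeneratorConfig(n_participants=40_000, seed=61)).table
        t = phenoage_from_table(t)
        t["aging_group"] = np.where(t["phenoaccel"] >= 0, "older", "younger")
        curves = risk_by_age_curve(t, threshold_pct=2.0)
        older, younger = curves["older"], curves["younger"]
        assert older.crossing_age is not None and younger.crossing_age is not None
        assert older.crossing_age < younger.crossing_age
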