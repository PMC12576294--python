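"""Cox engine against independent oracles, diagnostics, splines, scans."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import ediirisk as er
from ediirisk import survival as sv
from ediirisk.errors import CollinearityError, ConvergenceError, SplineUnavailableError
from ediirisk.synth_cohort import GeneratorConfig, generate_cohort

from conftest import lean_spec


def _toy_cohort(n=30, seed=0, beta=0.8):
    """Continuous times (no ties), one binary covariate with true log-HR beta."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    c = rng.exponential(20.0, n)
    return pd.DataFrame(
        {
            "x": x,
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
        }
    )


def _newton_oracle(df, tol=1e-12):
    """Textbook partial-likelihood Newton solve for a single covariate."""
    x = df["x"].to_numpy()
    t = df["time"].to_numpy()
    e = df["event"].to_numpy()
    order = np.argsort(t)
    x, t, e = x[order], t[order], e[order]

    def derivs(beta):
        grad = hess = 0.0
        for i in np.flatnonzero(e == 1):
            risk = t >= t[i]
            w = np.exp(beta * x[risk])
            xbar = np.sum(w * x[risk]) / np.sum(w)
            x2bar = np.sum(w * x[risk] ** 2) / np.sum(w)
            grad += x[i] - xbar
            hess -= x2bar - xbar**2
        return grad, hess

    beta = 0.0
    for _ in range(100):
        g, h = derivs(beta)
        step = -g / h
        beta += step
        if abs(step) < tol:
            break
    return beta


class TestCoxOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_covariate_matches_newton_solve(self, seed):
        df = _toy_cohort(n=30, seed=seed)
        spec = sv.ModelSpec(exposure="x", covariates=[])
        fit = sv.fit_cox(df, spec)
        oracle = _newton_oracle(df)
        assert fit.params["x"] == pytest.approx(oracle, abs=1e-6)

    def test_duplicating_rows_preserves_coefficient(self):
        df = _toy_cohort(n=40, seed=3)
        spec = sv.ModelSpec(exposure="x", covariates=[])
        single = sv.fit_cox(df, spec)
        double = sv.fit_cox(
            pd.concat([df, df], ignore_index=True), spec
        )
        assert double.params["x"] == pytest.approx(single.params["x"], abs=1e-4)
        se_1 = np.sqrt(single.covariance.loc["x", "x"])
        se_2 = np.sqrt(double.covariance.loc["x", "x"])
        assert se_2 < se_1

    def test_matches_r_coxph(self, tmp_path):
        """Coefficients and C-index against survival::coxph (no ties)."""
        rng = np.random.default_rng(5)
        n = 300
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.integers(0, 2, n).astype(float),
            }
        )
        t = rng.exponential(1.0 / (0.1 * np.exp(0.5 * df.x1 - 0.3 * df.x2)))
        c = rng.exponential(15.0, n)
        df["time"] = np.minimum(t, c)
        df["event"] = (t <= c).astype(int)
        csv = tmp_path / "cohort.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(survival))
            d <- read.csv("{csv}")
            f <- coxph(Surv(time, event) ~ x1 + x2, data = d)
            cat(coef(f), sqrt(diag(vcov(f))), concordance(f)$concordance, sep="\\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.split()]
        fit = sv.fit_cox(df, sv.ModelSpec(exposure=["x1", "x2"], covariates=[]))
        assert fit.params["x1"] == pytest.approx(vals[0], abs=1e-5)
        assert fit.params["x2"] == pytest.approx(vals[1], abs=1e-5)
        assert np.sqrt(fit.covariance.loc["x1", "x1"]) == pytest.approx(vals[2], abs=1e-5)
        assert np.sqrt(fit.covariance.loc["x2", "x2"]) == pytest.approx(vals[3], abs=1e-5)
        assert fit.c_index == pytest.approx(vals[4], abs=1e-6)

    def test_bic_uses_event_count(self):
        df = _toy_cohort(n=60, seed=6)
        fit = sv.fit_cox(df, sv.ModelSpec(exposure="x", covariates=[]))
        expected = -2 * fit.log_likelihood + 1 * np.log(fit.events)
        assert fit.bic == pytest.approx(expected, rel=1e-12)

    def test_ci_is_wald_exponentiated(self):
        df = _toy_cohort(n=80, seed=7)
        fit = sv.fit_cox(df, sv.ModelSpec(exposure="x", covariates=[]))
        se = np.sqrt(fit.covariance.loc["x", "x"])
        lo = np.exp(fit.params["x"] - 1.959963984540054 * se)
        assert fit.hr_table.loc["x", "ci_lower"] == pytest.approx(lo, rel=1e-9)

    def test_collinear_design_rejected(self):
        df = _toy_cohort(n=50, seed=8)
        df["x_copy"] = df["x"]
        with pytest.raises(CollinearityError):
            sv.fit_cox(df, sv.ModelSpec(exposure=["x", "x_copy"], covariates=[]))

    def test_too_few_events_rejected(self):
        df = _toy_cohort(n=20, seed=9)
        df["event"] = 0
        df.loc[0, "event"] = 1
        with pytest.raises(ConvergenceError):
            sv.fit_cox(df, sv.ModelSpec(exposure="x", covariates=[]))

    def test_efron_ties_option_agrees_without_ties(self):
        """With continuous times the Breslow and Efron paths coincide."""
        df = _toy_cohort(n=60, seed=11)
        b = sv.fit_cox(df, sv.ModelSpec(exposure="x", covariates=[]))
        e = sv.fit_cox(
            df, sv.ModelSpec(exposure="x", covariates=[], ties="efron")
        )
        assert e.params["x"] == pytest.approx(b.params["x"], abs=1e-6)

    def test_efron_ties_differ_under_heavy_ties(self):
        rng = np.random.default_rng(12)
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        # coarsely discretized times force many tied events
        t = np.ceil(rng.exponential(3.0 / np.exp(0.7 * x)))
        df = pd.DataFrame({"x": x, "time": t + 1, "event": 1})
        b = sv.fit_cox(df, sv.ModelSpec(exposure="x", covariates=[]))
        e = sv.fit_cox(
            df, sv.ModelSpec(exposure="x", covariates=[], ties="efron")
        )
        assert b.params["x"] != pytest.approx(e.params["x"], abs=1e-8)

    def test_tier_covariate_nesting(self):
        t1, t2, t3 = (set(sv.tier_covariates(k)) for k in (1, 2, 3))
        assert t1 < t2 < t3


class TestSchoenfeld:
    def test_ph_violation_detected(self):
        cfg = GeneratorConfig(
            n_participants=6000, seed=12, baseline_rate=4e-3,
            covariate_log_hr={}, log_hr_edii_sd=0.3,
            ph_violation_log_hr=1.0, ph_violation_years=4.0,
            p_refused_followup=0.0, p_baseline_aaa=0.0, p_pregnant=0.0,
            p_missing_marker=0.0, p_missing_covariate=0.0,
        )
        raw = generate_cohort(cfg, include_recalls=False)
        part = raw.participants.rename(columns={"true_edii_sd": "edii_sd"})
        fit = sv.fit_cox(part, lean_spec())
        ph = sv.schoenfeld_test(fit)
        assert ph.loc["edii_sd", "p"] < 0.01
        assert ph.loc["GLOBAL", "p"] < 0.05

    def test_null_model_not_flagged(self, null_cohort):
        fit = sv.fit_cox(null_cohort, lean_spec())
        ph = sv.schoenfeld_test(fit)
        # one draw from a uniform null; just reject gross miscalibration
        assert ph.loc["GLOBAL", "p"] > 1e-4
        assert set(ph.columns) == {"chi2", "df", "p"}


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {
                "time": rng.exponential(5, 200),
                "event": 1,
                "grp": "a",
            }
        )
        curves, _ = sv.km_curve(df, "grp")
        t = np.sort(df["time"].to_numpy())
        for _, row in curves.iloc[1:].iterrows():
            emp = np.mean(t > row["time"])
            assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_all_censored_curve_stays_at_one(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": 0, "grp": "a"})
        curves, _ = sv.km_curve(df, "grp")
        assert (curves["survival"] == 1.0).all()

    def test_identical_groups_logrank_near_one(self):
        rng = np.random.default_rng(14)
        half = pd.DataFrame(
            {"time": rng.exponential(5, 100), "event": 1}
        )
        df = pd.concat(
            [half.assign(grp="a"), half.assign(grp="b")], ignore_index=True
        )
        _, p = sv.km_curve(df, "grp")
        assert p == pytest.approx(1.0, abs=1e-9)


class TestSplines:
    def test_reference_hazard_ratio_is_one(self, small_cohort):
        cohort, _, _ = small_cohort
        spl = sv.rcs_dose_response(cohort, "edii", lean_spec())
        at_ref = np.interp(spl.reference, spl.curve["x"], spl.curve["hr"])
        assert at_ref == pytest.approx(1.0, abs=5e-3)
        assert len(spl.knots) == 4

    def test_quadratic_hazard_triggers_nonlinearity(self):
        cfg = GeneratorConfig(
            n_participants=8000, seed=15, baseline_rate=4e-3,
            covariate_log_hr={}, quadratic_log_hr=0.4,
            p_refused_followup=0.0, p_baseline_aaa=0.0, p_pregnant=0.0,
            p_missing_marker=0.0, p_missing_covariate=0.0,
        )
        raw = generate_cohort(cfg, include_recalls=False)
        part = raw.participants.rename(columns={"true_edii_sd": "edii_sd"})
        spl = sv.rcs_dose_response(part, "edii_sd", lean_spec())
        assert spl.nonlinearity_p < 0.01

    def test_too_few_distinct_values(self):
        df = pd.DataFrame(
            {"x": [1.0, 1.0, 2.0, 2.0] * 10,
             "time": np.arange(1, 41, dtype=float), "event": 1}
        )
        with pytest.raises(SplineUnavailableError):
            sv.rcs_dose_response(
                df, "x", sv.ModelSpec(exposure="x", covariates=[])
            )

    def test_linear_in_linear_region_matches_cox_slope(self):
        rng = np.random.default_rng(16)
        n = 3000
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.4 * x)))
        df = pd.DataFrame(
            {"x": x, "time": np.minimum(t, 13.8),
             "event": (t <= 13.8).astype(int)}
        )
        spl = sv.rcs_dose_response(
            df, "x", sv.ModelSpec(exposure="x", covariates=[])
        )
        assert spl.nonlinearity_p > 0.001  # truly log-linear effect


class TestScans:
    def test_component_scan_one_row_per_component(self, small_cohort):
        cohort, _, densities = small_cohort
        few = densities.iloc[:, :5]
        out = sv.component_scan(cohort, few, lean_spec())
        assert list(out["component"]) == list(few.columns)
        assert out[["HR", "ci_lower", "ci_upper", "p"]].notna().all().all()

    def test_protective_component_detected(self):
        """A density that lowers the hazard shows HR < 1."""
        rng = np.random.default_rng(17)
        n = 6000
        d = rng.normal(10, 2, n)
        t = rng.exponential(1.0 / (0.04 * np.exp(-0.35 * (d - 10) / 2)))
        cohort = pd.DataFrame(
            {"time": np.minimum(t, 13.8), "event": (t <= 13.8).astype(int)}
        )
        dens = pd.DataFrame({"fiber": d})
        out = sv.component_scan(
            cohort, dens, sv.ModelSpec(exposure="edii_sd", covariates=[])
        )
        row = out.set_index("component").loc["fiber"]
        assert row["HR"] < 1 and row["ci_upper"] < 1

    def test_subgroup_scan_reports_strata_and_interaction(self, small_cohort):
        cohort, _, _ = small_cohort
        out = sv.subgroup_scan(
            cohort, lean_spec(), stratifiers={
                "sex": sv.DEFAULT_STRATIFIERS["sex"],
                "age": sv.DEFAULT_STRATIFIERS["age"],
            }
        )
        assert set(out["stratifier"]) == {"sex", "age"}
        assert out["p_interaction"].between(0, 1).all()

    def test_sex_specific_effect_detected(self):
        cfg = GeneratorConfig(
            n_participants=12000, seed=18, baseline_rate=4e-3,
            covariate_log_hr={}, log_hr_edii_sd=0.0,
            log_hr_edii_sd_male_extra=float(np.log(2.0)),
            p_refused_followup=0.0, p_baseline_aaa=0.0, p_pregnant=0.0,
            p_missing_marker=0.0, p_missing_covariate=0.0,
        )
        raw = generate_cohort(cfg, include_recalls=False)
        part = raw.participants.rename(columns={"true_edii_sd": "edii_sd"})
        out = sv.subgroup_scan(
            part, lean_spec(),
            stratifiers={"sex": sv.DEFAULT_STRATIFIERS["sex"]},
        )
        assert (out["p_interaction"] < 0.01).all()
        hrs = out.set_index("stratum")["HR"]
        assert hrs["male"] > hrs["female"]

    def test_sensitivity_reruns_preserve_strong_effect(self, small_cohort):
        cohort, _, _ = small_cohort
        out = sv.sensitivity_scan(cohort, lean_spec())
        assert {"landmark", "no_comorbidity"} <= set(out["analysis"])
        assert (out["HR"] > 1).all()  # true per-SD HR 1.12 keeps its sign
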