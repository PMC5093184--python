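"""Cox engine: oracle equivalence, closed forms, and lifelines cross-check."""

import numpy as np
import pandas as pd
import pytest

from crshape.cox import (
    CohortTable,
    DegenerateCovariateError,
    PartialLikelihood,
    fit_transformed_cox,
    partial_loglik,
)
from crshape.transforms import ExposureTransform, make_special

LINEAR01 = make_special("linear", 0.0, 1.0)  # nu(x) ~ x for a 0/1 covariate


def brute_force_breslow(times, events, x, betas):
    """Vectorised grid evaluation of the single-covariate partial loglik."""
    order = np.argsort(-np.asarray(times, float))
    x = np.asarray(x, float)[order]
    events = np.asarray(events, int)[order]
    betas = np.asarray(betas, float)
    ex = np.exp(np.outer(betas, x))  # (B, n)
    csum = np.cumsum(ex, axis=1)
    ll = np.zeros(len(betas))
    for i in range(len(x)):
        if events[i]:
            ll += betas * x[i] - np.log(csum[:, i])
    return ll


class TestOracleEquivalence:
    def test_four_subject_grid_oracle(self, four_subject_cohort):
        co = four_subject_cohort
        betas = np.arange(-5.0, 5.0, 1e-4)
        ll = brute_force_breslow(co.times(), co.events(), co.df["x"], betas)
        beta_star = betas[np.argmax(ll)]
        fit = fit_transformed_cox(co, LINEAR01)
        assert fit.beta_hat == pytest.approx(beta_star, abs=1e-3)
        assert fit.loglik == pytest.approx(ll.max(), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_small_cohorts_match_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        df = pd.DataFrame(
            {
                "time": rng.exponential(5.0, n),
                "event": np.r_[np.ones(5, int), rng.integers(0, 2, n - 5)],
                "x": rng.normal(size=n),
            }
        )
        co = CohortTable(df, "time", "event", "x")
        t = make_special("linear", df["x"].min() - 1, df["x"].max() + 1)
        betas = np.arange(-5.0, 5.0, 1e-4)
        ll = brute_force_breslow(co.times(), co.events(), df["x"], betas)
        fit = fit_transformed_cox(co, t)
        assert abs(fit.beta_hat - betas[np.argmax(ll)]) < 1e-3


class TestPartialLoglik:
    def test_null_closed_form(self, four_subject_cohort):
        # beta=0: each event contributes -log(risk set size)
        expected = -(np.log(4) + np.log(3) + np.log(2) + np.log(1))
        val = partial_loglik(four_subject_cohort, LINEAR01, beta=0.0)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_equals_fit_loglik_at_optimum(self, small_cohort, true_curve):
        fit = fit_transformed_cox(small_cohort, true_curve.transform)
        val = partial_loglik(
            small_cohort, true_curve.transform, fit.beta_hat, fit.gamma_hat
        )
        assert val == pytest.approx(fit.loglik, rel=1e-12)

    def test_breslow_equals_efron_without_ties(self, small_cohort, true_curve):
        fe = fit_transformed_cox(small_cohort, true_curve.transform, "efron")
        fb = fit_transformed_cox(small_cohort, true_curve.transform, "breslow")
        assert fe.beta_hat == pytest.approx(fb.beta_hat, rel=1e-9)
        assert fe.loglik == pytest.approx(fb.loglik, rel=1e-12)

    def test_gamma_length_checked(self, small_cohort, true_curve):
        with pytest.raises(ValueError):
            partial_loglik(small_cohort, true_curve.transform, 0.1, (0.1,))


class TestStrataAndInvariances:
    def test_duplicated_stratum_doubles_loglik(self, four_subject_cohort):
        df = four_subject_cohort.df
        df2 = pd.concat(
            [df.assign(s=0), df.assign(s=1)], ignore_index=True
        )
        co2 = CohortTable(df2, "time", "event", "x", strata_cols=["s"])
        f1 = fit_transformed_cox(four_subject_cohort, LINEAR01)
        f2 = fit_transformed_cox(co2, LINEAR01)
        assert f2.beta_hat == pytest.approx(f1.beta_hat, rel=1e-8)
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-10)

    def test_covariate_shift_absorbed_by_baseline(self, small_cohort):
        x = small_cohort.exposures()
        pl1 = PartialLikelihood(
            small_cohort.times(), small_cohort.events(), x[:, None]
        )
        pl2 = PartialLikelihood(
            small_cohort.times(), small_cohort.events(), (x + 100.0)[:, None]
        )
        b1, _, _ = pl1.fit()
        b2, _, _ = pl2.fit()
        assert b1[0] == pytest.approx(b2[0], rel=1e-7)

    def test_zero_event_stratum_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(5)
        n = 200
        df = pd.DataFrame(
            {
                "time": rng.exponential(5, n),
                "event": rng.integers(0, 2, n),
                "x": rng.normal(size=n),
                "s": 0,
            }
        )
        dead = pd.DataFrame(
            {"time": [1.0, 2.0], "event": [0, 0], "x": [0.1, -0.1], "s": [1, 1]}
        )
        co = CohortTable(
            pd.concat([df, dead], ignore_index=True), "time", "event", "x", strata_cols=["s"]
        )
        t = make_special("linear", -5, 5)
        with caplog.at_level("WARNING"):
            fit_transformed_cox(co, t)
        assert any("zero events" in r.message for r in caplog.records)

    def test_constant_exposure_raises(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [1, 1, 1], "x": [2.0, 2.0, 2.0]}
        )
        co = CohortTable(df, "time", "event", "x")
        with pytest.raises(DegenerateCovariateError):
            fit_transformed_cox(co, make_special("linear", 0, 5))


class TestAgainstLifelines:
    """lifelines CoxPHFitter as the independent reference implementation."""

    def _cohort(self, seed=11, n=600, tie=False):
        rng = np.random.default_rng(seed)
        z = rng.gamma(4, 3, n) + 1.4
        df = pd.DataFrame(
            {
                "z": z,
                "x1": rng.normal(size=n),
                "s": rng.integers(0, 2, n),
            }
        )
        lam = 0.05 * np.exp(0.1 * np.log(z) + 0.3 * df["x1"])
        T = rng.exponential(1 / lam)
        df["time"] = np.ceil(T) if tie else np.minimum(T, 15.0)
        df["event"] = 1 if tie else (T <= 15.0).astype(int)
        return df

    @pytest.mark.parametrize("tie", [False, True])
    def test_matches_lifelines_efron(self, tie):
        lifelines = pytest.importorskip("lifelines")
        df = self._cohort(tie=tie)
        t = ExposureTransform("log", mu=float(np.median(df["z"])), tau=0.1,
                              range_r=float(np.ptp(df["z"])))
        co = CohortTable(df, "time", "event", "z", ["x1"], ["s"])
        fit = fit_transformed_cox(co, t, ties="efron")

        from crshape.transforms import transform_value

        df2 = df.copy()
        df2["nu"] = transform_value(df["z"].to_numpy(), t)
        cph = lifelines.CoxPHFitter()
        cph.fit(
            df2[["time", "event", "nu", "x1", "s"]],
            duration_col="time",
            event_col="event",
            strata=["s"],
        )
        assert fit.beta_hat == pytest.approx(cph.params_["nu"], rel=1e-5)
        assert fit.se_beta == pytest.approx(cph.standard_errors_["nu"], rel=1e-5)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, rel=1e-9)


class TestNullBehaviour:
    def test_permuted_exposure_gives_null_beta(self, medium_cohort, true_curve):
        rng = np.random.default_rng(123)
        df = medium_cohort.df.copy()
        df["pm25"] = rng.permutation(df["pm25"].to_numpy())
        co = CohortTable(df, "time", "event", "pm25", ["x1", "x2"], ["stratum"])
        fit = fit_transformed_cox(co, true_curve.transform)
        assert abs(fit.beta_hat) < 3 * fit.se_beta


class TestCohortValidation:
    def test_negative_time_names_row(self):
        df = pd.DataFrame(
            {"time": [1.0, -2.0, 3.0], "event": [1, 0, 1], "x": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="row 1"):
            CohortTable(df, "time", "event", "x")

    def test_missing_column(self):
        df = pd.DataFrame({"time": [1.0], "x": [1.0]})
        with pytest.raises(ValueError, match="event"):
            CohortTable(df, "time", "event", "x")

    def test_non_binary_events(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 2], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="0/1"):
            CohortTable(df, "time", "event", "x")

    def test_no_events(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="no events"):
            CohortTable(df, "time", "event", "x")
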