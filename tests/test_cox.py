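"""Cox engine: partial-likelihood oracle, lifelines cross-check, KM, R^2."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import petsurv as ps
from petsurv.cox import cox_ph, km_curve
from petsurv.errors import (
    CollinearDesignError,
    DegenerateCovariateError,
    MonotoneLikelihoodError,
    NoEventsError,
    PetsurvError,
)

from conftest import make_survival_arrays


def efron_loglik_reference(beta, x, time, event):
    """Independent, explicit Efron log partial likelihood (plain loops).

    Written directly from the definition over risk sets; shares no code
    with the package implementation.
    """
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        deaths = np.flatnonzero((time == t) & (event == 1))
        risk = np.flatnonzero(time >= t)
        d = len(deaths)
        sum_risk = np.exp(beta * x[risk]).sum()
        sum_tied = np.exp(beta * x[deaths]).sum()
        ll += beta * x[deaths].sum()
        for l in range(d):
            ll -= np.log(sum_risk - l / d * sum_tied)
    return ll


def oracle_beta(x, time, event, bound=12.0):
    res = minimize_scalar(
        lambda b: -efron_loglik_reference(b, x, time, event),
        bounds=(-bound, bound), method="bounded",
        options={"xatol": 1e-10},
    )
    return res.x


class TestCoxPartialLikelihood:
    def test_six_patient_binary_matches_grid_oracle(self):
        """No ties, one binary covariate: Newton equals the 1-D maximizer of

        the explicit partial likelihood to |dbeta| < 1e-6."""
        x = np.array([1, 0, 1, 0, 1, 0], float)
        time = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        fit = cox_ph(x.reshape(-1, 1), time, event)
        assert abs(fit.coef[0] - oracle_beta(x, time, event)) < 1e-6

    def test_tied_data_matches_oracle(self):
        x = np.array([1, 1, 0, 0, 1, 0, 1, 0], float)
        time = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        fit = cox_ph(x.reshape(-1, 1), time, event)
        assert abs(fit.coef[0] - oracle_beta(x, time, event)) < 1e-6

    def test_random_small_datasets_match_oracle(self):
        """Random datasets of up to 8 patients, exact oracle agreement."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 30:
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 2, n).astype(float)
            time = rng.permutation(np.arange(1.0, n + 1))
            event = rng.integers(0, 2, n)
            if event.sum() == 0 or np.ptp(x) == 0:
                continue
            try:
                fit = cox_ph(x.reshape(-1, 1), time, event)
            except MonotoneLikelihoodError:
                b = oracle_beta(x, time, event)
                assert abs(b) > 9  # oracle also runs to its bound
                checked += 1
                continue
            except CollinearDesignError:
                # covariate constant within every event risk set: the
                # partial likelihood is flat and carries no information
                lls = [efron_loglik_reference(b, x, time, event)
                       for b in (-2.0, 0.0, 2.0)]
                assert max(lls) - min(lls) < 1e-12
                checked += 1
                continue
            assert abs(fit.coef[0] - oracle_beta(x, time, event)) < 1e-6
            checked += 1

    def test_matches_lifelines_with_ties(self):
        """Independent implementation cross-check at n = 300 with ties."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        x, time, event = make_survival_arrays(rng, 300)
        time = np.round(time, 1) + 0.05  # induce ties
        x2 = rng.binomial(1, 0.4, 300).astype(float)
        fit = cox_ph(np.c_[x, x2], time, event, names=["x", "x2"])
        df = pd.DataFrame({"t": time, "e": event, "x": x, "x2": x2})
        ref = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert fit.coef == pytest.approx(ref.params_.values, abs=2e-5)
        assert fit.se == pytest.approx(ref.standard_errors_.values, abs=2e-5)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(4)
        x, time, event = make_survival_arrays(rng, 150)
        assert len(np.unique(time)) == len(time)
        fe = cox_ph(x.reshape(-1, 1), time, event, ties="efron")
        fb = cox_ph(x.reshape(-1, 1), time, event, ties="breslow")
        assert abs(fe.coef[0] - fb.coef[0]) < 1e-10

    def test_covariate_scaling_invariance(self):
        """Scaling x by c scales beta by 1/c and leaves the Wald p fixed."""
        rng = np.random.default_rng(5)
        x, time, event = make_survival_arrays(rng, 200)
        f1 = cox_ph(x.reshape(-1, 1), time, event)
        f2 = cox_ph((100.0 * x).reshape(-1, 1), time, event)
        assert f2.coef[0] == pytest.approx(f1.coef[0] / 100.0, rel=1e-8)
        assert f2.p[0] == pytest.approx(f1.p[0], abs=1e-8)

    def test_no_events_raises(self):
        x = np.array([0.0, 1.0, 0.5])
        with pytest.raises(NoEventsError):
            cox_ph(x.reshape(-1, 1), np.array([1.0, 2, 3]), np.zeros(3, int))

    def test_constant_covariate_raises(self):
        x = np.ones(5)
        t = np.arange(1.0, 6)
        with pytest.raises(DegenerateCovariateError):
            cox_ph(x.reshape(-1, 1), t, np.ones(5, int))

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_fast_binary_path_equals_general_engine(self, ties):
        """The count-based binary-covariate fit reproduces the general

        Newton engine to near machine precision, ties included."""
        from petsurv.cox import binary_cox

        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(20, 80))
            g = rng.integers(0, 2, n).astype(float)
            t = np.round(rng.exponential(5.0, n), 1) + 0.1
            e = rng.integers(0, 2, n)
            if e.sum() == 0 or np.ptp(g) == 0:
                continue
            if e[g > 0.5].sum() == 0 or e[g < 0.5].sum() == 0:
                continue
            try:
                ref = cox_ph(g.reshape(-1, 1), t, e, ties=ties)
            except MonotoneLikelihoodError:
                with pytest.raises(MonotoneLikelihoodError):
                    binary_cox(t, e, g, ties=ties)
                continue
            coef, se = binary_cox(t, e, g, ties=ties)
            assert coef == pytest.approx(ref.coef[0], abs=1e-9)
            assert se == pytest.approx(ref.se[0], abs=1e-9)

    def test_monotone_likelihood_raises_with_direction(self):
        """All events in the high group: infinite HR, direction +1."""
        x = np.array([1, 1, 1, 0, 0, 0], float)
        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(MonotoneLikelihoodError) as exc:
            cox_ph(x.reshape(-1, 1), t, e)
        assert exc.value.direction == 1


class TestRecordInterface:
    def test_metric_fit_from_records(self, small_cohort):
        fit = ps.cox_fit(small_cohort, ["tlg_all"])
        assert fit.n == 60 and fit.n_events >= 1
        assert fit.hr[0] == pytest.approx(np.exp(fit.coef[0]))
        assert fit.ci_lower[0] < fit.hr[0] < fit.ci_upper[0]

    def test_multivariate_reduces_to_univariate(self, small_cohort):
        f1 = ps.cox_fit(small_cohort, ["tlg_all"])
        f2 = ps.cox_fit_multivariate(small_cohort, "tlg_all", [])
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-12)

    def test_orthogonal_confounder_leaves_hr(self, default_cohort):
        """A covariate independent of TLG barely moves the adjusted HR."""
        f1 = ps.cox_fit(default_cohort, ["tlg_all>290"])
        f2 = ps.cox_fit_multivariate(default_cohort, "tlg_all>290",
                                     ["sex=male"])
        assert f2.hr[0] == pytest.approx(f1.hr[0], rel=0.10)

    def test_aliased_covariate_collinear(self, small_cohort):
        with pytest.raises(CollinearDesignError):
            ps.cox_fit_multivariate(small_cohort, "tlg_all", ["tlg_all"])

    def test_stage_ordinal_encoding(self, default_cohort):
        fit = ps.cox_fit(default_cohort, ["t_stage>2"])
        df = ps.cohort_frame(default_cohort)
        known = df["t_stage"].isin(["T1", "T2", "T3", "T4"])
        assert fit.n == int(known.sum())  # Tx rows are complete-case dropped


class TestKaplanMeier:
    def test_three_event_empirical_survival(self):
        c = km_curve(np.array([1.0, 2, 3]), np.array([1, 1, 1]))
        assert c.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert list(c.at_risk) == [3, 2, 1]

    def test_hand_product_limit_with_censoring(self):
        """Events at 1 and 3, censor at 2: S = (1-1/3), then (1-1/1)x2/3."""
        c = km_curve(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        assert c.times == pytest.approx([1.0, 3.0])
        assert c.survival == pytest.approx([2 / 3, 0.0])

    def test_all_censored_survival_stays_one(self):
        c = km_curve(np.array([1.0, 2, 3]), np.zeros(3, int))
        assert len(c.times) == 0 and c.n == 3

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(1.0, 200)
        c = km_curve(t, np.ones(200, int))
        ecdf = np.searchsorted(np.sort(t), c.times, side="right") / 200
        assert c.survival == pytest.approx(1.0 - ecdf)

    def test_censored_at_event_time_counted_at_risk(self):
        c = km_curve(np.array([1.0, 1.0, 2.0]), np.array([1, 0, 1]))
        assert c.at_risk[0] == 3  # the patient censored at t=1 is at risk
        assert c.survival == pytest.approx([2 / 3, 0.0])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(10)
        t = np.round(rng.exponential(5.0, 100), 1) + 0.1
        e = rng.integers(0, 2, 100)
        if e.sum() == 0:
            e[0] = 1
        c = km_curve(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(c.times).to_numpy()
        assert c.survival == pytest.approx(ref, abs=1e-12)


class TestCollinearityScreen:
    def test_self_r2_is_one(self, small_cohort):
        r2 = ps.collinearity_screen(small_cohort, ["tlg_all", "mtv_all"])
        assert r2.loc["tlg_all", "tlg_all"] == pytest.approx(1.0)

    def test_constructed_linear_pair(self):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.uniform(1, 10, n)
        df = pd.DataFrame({"a": x, "b": 2 * x + rng.normal(0, 0.01, n)})
        df["patient_id"] = "p"
        for col in ["ffdm_time", "os_time"]:
            df[col] = 1.0
        for col in ["ffdm_event", "os_event"]:
            df[col] = 0
        r2 = ps.collinearity_screen(df, ["a", "b"])
        assert r2.loc["a", "b"] > 0.99

    def test_independent_params_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=1000),
                           "b": rng.normal(size=1000)})
        r2 = ps.collinearity_screen(df, ["a", "b"])
        assert r2.loc["a", "b"] < 0.05

    def test_zero_variance_flagged_nan(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        r2 = ps.collinearity_screen(df, ["a", "b"])
        assert np.isnan(r2.loc["a", "b"]) and np.isnan(r2.loc["a", "a"])

    def test_too_few_records_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(PetsurvError):
            ps.collinearity_screen(df, ["a", "b"])
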