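import numpy as np
import pandas as pd
import pytest

from damicox import (adjusted_survival_curves, fit_cox_td, kaplan_meier,
                     nelson_aalen, schoenfeld_residuals, schoenfeld_test,
                     to_counting_process)
from damicox.survival import CollinearityError


class TestKaplanMeierNelsonAalen:
    def test_hand_computed_three_subject_curves(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 0])
        assert km.survival == pytest.approx([2 / 3, 1 / 3])
        na = nelson_aalen([1, 2, 3], [1, 1, 0])
        assert na.hazard == pytest.approx([1 / 3, 1 / 3 + 1 / 2])

    def test_all_censored_gives_flat_estimates(self):
        km = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert len(km.times) == 0 and km.at([0.5, 5]).tolist() == [1.0, 1.0]
        na = nelson_aalen([1, 2, 3], [0, 0, 0])
        assert na.at([2.0])[0] == 0.0

    def test_duplicating_every_subject_leaves_km_unchanged(self):
        t = [1.0, 2.0, 2.5, 4.0]
        e = [1, 0, 1, 1]
        single = kaplan_meier(t, e)
        double = kaplan_meier(t * 2, e * 2)
        np.testing.assert_allclose(single.survival, double.survival)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])

    def test_na_nondecreasing_property(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 200)
        e = rng.integers(0, 2, 200)
        e[0] = 1
        na = nelson_aalen(t, e)
        assert (np.diff(na.hazard) >= 0).all()

    def test_agreement_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(42)
        t = rng.exponential(1, 500)
        c = rng.exponential(1.5, 500)
        dur, ev = np.minimum(t, c), (t <= c).astype(int)
        km = kaplan_meier(dur, ev)
        kmf = lifelines.KaplanMeierFitter().fit(dur, ev)
        np.testing.assert_allclose(
            km.survival,
            kmf.survival_function_at_times(km.times).to_numpy(), atol=1e-12)
        na = nelson_aalen(dur, ev)
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(dur, ev)
        np.testing.assert_allclose(
            na.hazard,
            naf.cumulative_hazard_at_times(na.times).to_numpy(), atol=1e-12)


class TestCoxFit:
    def test_two_event_toy_recovers_closed_form(self, cox_toy_cp):
        # partial likelihood e^b/(2e^b+2) * 1/(e^b+2) maximised at b=ln(2)/2
        fit = fit_cox_td(cox_toy_cp, ["x"])
        assert fit.converged
        assert fit.beta[0] == pytest.approx(0.5 * np.log(2), abs=1e-6)
        assert fit.hazard_ratios[0] == pytest.approx(np.exp(fit.beta[0]))

    def test_null_design_baseline_equals_nelson_aalen(self, cox_toy_cp):
        fit = fit_cox_td(cox_toy_cp, [])
        na = nelson_aalen(cox_toy_cp["stop"], cox_toy_cp["event"])
        np.testing.assert_allclose(fit.baseline_cumhaz, na.hazard)
        np.testing.assert_allclose(fit.baseline_times, na.times)

    def test_location_invariance_of_coefficients(self, cox_toy_cp):
        shifted = cox_toy_cp.assign(x=cox_toy_cp["x"] + 100.0)
        f0 = fit_cox_td(cox_toy_cp, ["x"])
        f1 = fit_cox_td(shifted, ["x"])
        assert f1.beta[0] == pytest.approx(f0.beta[0], abs=1e-8)

    def test_loglik_at_mle_beats_null(self, small_cohort):
        cp = to_counting_process(small_cohort, ["psa", "alk_phos"])
        fit = fit_cox_td(cp, ["psa", "alk_phos"])
        assert fit.loglik >= fit.loglik_null

    def test_efron_equals_breslow_without_ties(self, small_cohort):
        cp = to_counting_process(small_cohort, ["alk_phos"])
        assert cp.loc[cp["event"] == 1, "stop"].is_unique
        fe = fit_cox_td(cp, ["alk_phos"], ties="efron")
        fb = fit_cox_td(cp, ["alk_phos"], ties="breslow")
        np.testing.assert_allclose(fe.beta, fb.beta, atol=1e-9)
        np.testing.assert_allclose(fe.loglik, fb.loglik, atol=1e-9)

    def test_agreement_with_lifelines_time_varying(self, small_cohort):
        lifelines = pytest.importorskip("lifelines")
        cp = to_counting_process(small_cohort, ["psa", "alk_phos"])
        fit = fit_cox_td(cp, ["psa", "alk_phos"])
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(cp, id_col="id", start_col="start", stop_col="stop",
                event_col="event")
        np.testing.assert_allclose(
            fit.beta, ctv.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(
            fit.se, ctv.standard_errors_.to_numpy(), rtol=1e-3)

    def test_collinear_design_names_columns(self, cox_toy_cp):
        dup = cox_toy_cp.assign(x2=cox_toy_cp["x"] * 2.0)
        with pytest.raises(CollinearityError, match="x2"):
            fit_cox_td(dup, ["x", "x2"])

    def test_monotone_likelihood_is_flagged(self):
        # perfectly separating covariate: all events in the x=1 group first
        cp = pd.DataFrame({
            "id": range(6), "start": 0.0,
            "stop": [1, 2, 3, 10, 11, 12],
            "event": [1, 1, 1, 0, 0, 0],
            "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        })
        fit = fit_cox_td(cp, ["x"])
        assert not fit.converged
        assert any("monotone" in w for w in fit.warnings)

    def test_recovers_known_coefficient_within_mc_error(self):
        # simulated proportional-hazards data with beta = 0.5
        rng = np.random.default_rng(99)
        reps, n, beta = 200, 500, 0.5
        est = []
        for _ in range(reps):
            x = rng.standard_normal(n)
            t = rng.exponential(np.exp(-beta * x))
            c = rng.exponential(1.5, n)
            cp = pd.DataFrame({
                "id": np.arange(n), "start": 0.0,
                "stop": np.minimum(t, c), "event": (t <= c).astype(int),
                "x": x})
            est.append(fit_cox_td(cp, ["x"]).beta[0])
        est = np.asarray(est)
        assert abs(est.mean() - beta) < 2 * est.std(ddof=1) / np.sqrt(reps)


class TestSchoenfeld:
    def test_single_event_residual_is_covariate_minus_riskset_mean(self):
        cp = pd.DataFrame({
            "id": [1, 2, 3], "start": 0.0, "stop": [2.0, 3.0, 4.0],
            "event": [1, 0, 0], "x": [1.0, 2.0, 6.0],
        })
        fit = fit_cox_td(cp, ["x"])
        times, resid = schoenfeld_residuals(fit, cp)
        w = np.exp(fit.beta[0] * cp["x"].to_numpy())
        mean = (w * cp["x"]).sum() / w.sum()
        assert resid[0, 0] == pytest.approx(1.0 - mean)

    def test_pvalues_invariant_to_covariate_rescaling(self, small_cohort):
        cp = to_counting_process(small_cohort, ["alk_phos"])
        f1 = fit_cox_td(cp, ["alk_phos"])
        p1 = schoenfeld_test(f1, cp).table["p"].iloc[0]
        cp2 = cp.assign(alk_phos=cp["alk_phos"] * 1000.0)
        f2 = fit_cox_td(cp2, ["alk_phos"])
        p2 = schoenfeld_test(f2, cp2).table["p"].iloc[0]
        assert p2 == pytest.approx(p1, abs=1e-8)

    def test_matches_lifelines_score_test(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import proportional_hazard_test
        rng = np.random.default_rng(3)
        n = 200
        x = rng.standard_normal(n)
        t = rng.exponential(1.0 / np.exp(0.4 * x))
        c = rng.exponential(1.2, n)
        dur, ev = np.minimum(t, c), (t <= c).astype(int)
        cp = pd.DataFrame({"id": np.arange(n), "start": 0.0, "stop": dur,
                           "event": ev, "x": x})
        fit = fit_cox_td(cp, ["x"])
        mine = schoenfeld_test(fit, cp, transform="rank")
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"T": dur, "E": ev, "x": x}), "T", "E")
        ref = proportional_hazard_test(
            cph, pd.DataFrame({"T": dur, "E": ev, "x": x}),
            time_transform="rank")
        assert mine.table["p"].iloc[0] == pytest.approx(
            float(ref.summary["p"].iloc[0]), abs=1e-4)

    def test_no_covariates_raises(self, cox_toy_cp):
        fit = fit_cox_td(cox_toy_cp, [])
        with pytest.raises(ValueError):
            schoenfeld_test(fit, cox_toy_cp)


class TestAdjustedCurves:
    def test_reference_profile_is_baseline_survival(self, cox_toy_cp):
        fit = fit_cox_td(cox_toy_cp, ["x"])
        curves = adjusted_survival_curves(fit, {"ref": {"x": 0.0}})
        np.testing.assert_allclose(curves["ref"].survival,
                                   np.exp(-fit.baseline_cumhaz))

    def test_larger_linear_predictor_lowers_survival(self, cox_toy_cp):
        fit = fit_cox_td(cox_toy_cp, ["x"])
        curves = adjusted_survival_curves(
            fit, {"lo": {"x": 0.0}, "hi": {"x": 2.0}})
        assert (curves["hi"].survival <= curves["lo"].survival).all()

    def test_unknown_covariate_in_profile_raises(self, cox_toy_cp):
        fit = fit_cox_td(cox_toy_cp, ["x"])
        with pytest.raises(KeyError):
            adjusted_survival_curves(fit, {"bad": {"x": 0.0, "z": 1.0}})
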