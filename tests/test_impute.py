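import numpy as np
import pandas as pd
import pytest

from damicox import (ImputationModelSpec, MissingnessMechanism, PanelDataset,
                     PanelSchema, augment_survival_predictors,
                     impose_missingness, impute_mar, trace_diagnostics)
from damicox.impute import EVENT_IND, INT_CUMHAZ, INT_EVENT, LOG_TIME, \
    NA_CUMHAZ, _NormalEngine, _design_matrix


class TestAugmentation:
    def test_three_subject_cumhaz_step_values(self):
        # events at T=1,2; censored at 3 -> H = (1/3, 5/6, 5/6)
        frame = pd.DataFrame({
            "id": [1, 2, 3], "time": [0.0, 0.0, 0.0],
            "event_time": [1.0, 2.0, 3.0], "event": [1, 1, 0],
        })
        schema = PanelSchema(baseline=(), time_varying=(), categorical=())
        aug = augment_survival_predictors(PanelDataset(frame, schema))
        np.testing.assert_allclose(aug.frame[NA_CUMHAZ],
                                   [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2])
        np.testing.assert_allclose(aug.frame[EVENT_IND], [1, 1, 0])
        np.testing.assert_allclose(aug.frame[LOG_TIME],
                                   np.log([1.0, 2.0, 3.0]))

    def test_all_censored_cohort_gives_zero_columns(self):
        frame = pd.DataFrame({
            "id": [1, 2], "time": [0.0, 0.0],
            "event_time": [2.0, 3.0], "event": [0, 0],
        })
        schema = PanelSchema(baseline=(), time_varying=(), categorical=())
        aug = augment_survival_predictors(PanelDataset(frame, schema))
        assert (aug.frame[NA_CUMHAZ] == 0).all()
        assert (aug.frame[EVENT_IND] == 0).all()
        assert (aug.frame[INT_EVENT] == 0).all()

    def test_idempotent_reaugmentation(self, masked_cohort):
        once = augment_survival_predictors(masked_cohort)
        twice = augment_survival_predictors(once)
        assert list(once.frame.columns) == list(twice.frame.columns)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_interval_predictors_partition_subject_cumhaz(self, small_cohort):
        # per-subject interval increments sum to H(T) - H(first visit)
        aug = augment_survival_predictors(small_cohort)
        f = aug.frame
        s = small_cohort.schema
        total = f.groupby(s.id)[INT_CUMHAZ].sum()
        # first visits are at t=0 where the cumulative hazard is zero
        expected = f.groupby(s.id)[NA_CUMHAZ].first()
        np.testing.assert_allclose(total, expected, atol=1e-10)

    def test_zero_event_time_rejected(self):
        frame = pd.DataFrame({
            "id": [1], "time": [0.0], "event_time": [0.0], "event": [1],
        })
        schema = PanelSchema(baseline=(), time_varying=(), categorical=())
        with pytest.raises(ValueError, match="positive"):
            augment_survival_predictors(PanelDataset(frame, schema))


class TestImputeMar:
    def test_observed_entries_are_immutable(self, masked_cohort):
        spec = ImputationModelSpec(predictors=("age", "psa"), m=3,
                                   iterations=3)
        stack = impute_mar(masked_cohort, spec, seed=1)
        observed = masked_cohort.miss_mask("alk_phos")
        src = masked_cohort.frame.loc[observed, "alk_phos"]
        for ds in stack.datasets:
            pd.testing.assert_series_equal(
                ds.frame.loc[observed, "alk_phos"], src)
            assert ds.frame["alk_phos"].notna().all()
            assert (ds.frame["alk_phos"] > 0).all()

    def test_identical_seed_is_bitwise_reproducible(self, masked_cohort):
        spec = ImputationModelSpec(predictors=("age", "psa"), m=3,
                                   iterations=3)
        a = impute_mar(masked_cohort, spec, seed=42)
        b = impute_mar(masked_cohort, spec, seed=42)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da.frame, db.frame)
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_no_missingness_returns_identical_copies(self, small_cohort):
        spec = ImputationModelSpec(predictors=("age",), m=2, iterations=2)
        stack = impute_mar(small_cohort, spec, seed=0)
        assert len(stack.trace) == 0
        for ds in stack.datasets:
            pd.testing.assert_frame_equal(ds.frame, small_cohort.frame)

    def test_too_few_observed_values_raise(self):
        frame = pd.DataFrame({
            "id": np.arange(12), "time": 0.0,
            "age": 60.0,
            "y": [1.0] * 5 + [np.nan] * 7,
            "event_time": 2.0, "event": 1,
        })
        schema = PanelSchema(baseline=("age",), time_varying=("y",),
                             categorical=())
        spec = ImputationModelSpec(target="y", predictors=("age",))
        with pytest.raises(ValueError, match="observed"):
            impute_mar(PanelDataset(frame, schema), spec, seed=0)

    def test_between_imputation_variance_is_positive(self, masked_cohort):
        spec = ImputationModelSpec(predictors=("age", "psa"), m=5,
                                   iterations=2)
        stack = impute_mar(masked_cohort, spec, seed=3)
        idx = stack.missing_index
        imputed = np.array([ds.frame["alk_phos"].to_numpy()[idx]
                            for ds in stack.datasets])
        between = imputed.var(axis=0, ddof=1)
        assert (between > 0).all()

    def test_imputation_regression_recovers_known_slope(self):
        # y = 1 + 0.5 x + e, sigma = 0.3; 30% MCAR; pooled OLS slope over
        # completed datasets stays within 2 MC-SE of 0.5
        rng = np.random.default_rng(12)
        reps, n = 100, 500
        slopes = []
        for r in range(reps):
            x = rng.normal(0, 1, n)
            y = np.exp(1.0 + 0.5 * x + rng.normal(0, 0.3, n))
            frame = pd.DataFrame({
                "id": np.arange(n), "time": 0.0, "x": x, "y": y,
                "event_time": 1.0, "event": 0,
            })
            schema = PanelSchema(baseline=("x",), time_varying=("y",),
                                 categorical=())
            data = PanelDataset(frame, schema)
            masked, _ = impose_missingness(
                data, MissingnessMechanism(kind="MCAR", prob=0.3),
                seed=1000 + r, target="y")
            spec = ImputationModelSpec(
                target="y", predictors=("x",), m=5, iterations=2,
                use_event_indicator=False, use_cumhaz=False,
                use_interval_event=False, use_interval_cumhaz=False)
            stack = impute_mar(masked, spec, seed=2000 + r)
            bs = []
            for ds in stack.datasets:
                ly = np.log(ds.frame["y"].to_numpy())
                bs.append(np.polyfit(x, ly, 1)[0])
            slopes.append(np.mean(bs))
        slopes = np.asarray(slopes)
        assert abs(slopes.mean() - 0.5) < 2 * slopes.std(ddof=1) / np.sqrt(reps)

    def test_random_intercept_engine_runs_and_respects_mask(self,
                                                            masked_cohort):
        spec = ImputationModelSpec(predictors=("age", "psa"), m=2,
                                   iterations=2,
                                   random_intercept="subject")
        stack = impute_mar(masked_cohort, spec, seed=5)
        observed = masked_cohort.miss_mask("alk_phos")
        for ds in stack.datasets:
            assert ds.frame["alk_phos"].notna().all()
            pd.testing.assert_series_equal(
                ds.frame.loc[observed, "alk_phos"],
                masked_cohort.frame.loc[observed, "alk_phos"])

    def test_serialization_round_trip(self, masked_cohort, tmp_path):
        spec = ImputationModelSpec(predictors=("age",), m=2, iterations=2)
        stack = impute_mar(masked_cohort, spec, seed=9)
        stack.to_csv_dir(tmp_path / "stack")
        assert (tmp_path / "stack" / "manifest.json").exists()
        back = pd.read_csv(tmp_path / "stack" / "imputed_1.csv")
        pd.testing.assert_frame_equal(
            back[["alk_phos"]], stack.datasets[0].frame[["alk_phos"]])


class TestTraceDiagnostics:
    def test_trace_shape_is_chains_by_iterations(self, masked_cohort):
        spec = ImputationModelSpec(predictors=("age",), m=4, iterations=6)
        stack = impute_mar(masked_cohort, spec, seed=2)
        assert len(stack.trace) == 4 * 6
        diag = trace_diagnostics(stack)
        assert {"chain", "iteration", "mean", "sd"} <= set(diag.trace.columns)

    def test_well_specified_chains_mix(self, masked_cohort):
        flags = []
        for seed in range(20):
            spec = ImputationModelSpec(predictors=("age", "psa"), m=3,
                                       iterations=8)
            stack = impute_mar(masked_cohort, spec, seed=seed)
            flags.append(trace_diagnostics(stack).non_mixing)
        assert np.mean(flags) <= 0.25


def test_design_matrix_dummy_codes_categoricals():
    frame = pd.DataFrame({"g": ["a", "b", "c", "a"], "x": [1.0, 2, 3, 4]})
    X, names = _design_matrix(frame, ["g", "x"], ("g",))
    assert names[0] == "(intercept)"
    assert "g=b" in names and "g=c" in names and "g=a" not in names
    assert X.shape == (4, 4)
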