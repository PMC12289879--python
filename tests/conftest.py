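import numpy as np
import pandas as pd
import pytest

from damicox import (AnalysisConfig, ImputationModelSpec, MissingnessMechanism,
                     PanelDataset, PanelSchema, simulate_cohort)
from damicox.studies import recovery_cohort_spec


@pytest.fixture
def toy_panel() -> PanelDataset:
    """Two subjects, two visits each, one missing biomarker cell."""
    frame = pd.DataFrame({
        "id": [1, 1, 2, 2],
        "time": [0.0, 3.0, 0.0, 4.0],
        "age": [60.0, 60.0, 55.0, 55.0],
        "bmi": [20.0, 20.0, 22.0, 22.0],
        "gleason": ["9", "9", "3+3", "3+3"],
        "drug": ["EBRT", "EBRT", "ADT", "ADT"],
        "psa": [10.0, 8.0, 5.0, 4.0],
        "alk_phos": [100.0, np.nan, 80.0, 90.0],
        "event_time": [8.0, 8.0, 5.0, 5.0],
        "event": [1, 1, 0, 0],
    })
    return PanelDataset(frame, PanelSchema())


@pytest.fixture
def cox_toy_cp() -> pd.DataFrame:
    """Four subjects, binary covariate; closed-form MLE beta = ln(2)/2."""
    return pd.DataFrame({
        "id": [1, 2, 3, 4],
        "start": [0.0, 0.0, 0.0, 0.0],
        "stop": [1.0, 3.0, 2.0, 3.0],
        "event": [1, 0, 1, 0],
        "x": [1.0, 1.0, 0.0, 0.0],
    })


@pytest.fixture(scope="session")
def small_cohort() -> PanelDataset:
    """Fully observed simulated cohort with a known biomarker effect."""
    return simulate_cohort(recovery_cohort_spec(), seed=20260920)


@pytest.fixture(scope="session")
def masked_cohort(small_cohort) -> PanelDataset:
    from damicox import impose_missingness
    mech = MissingnessMechanism(kind="MCAR", prob=0.3)
    masked, _ = impose_missingness(small_cohort, mech, seed=11)
    return masked


@pytest.fixture
def simple_config() -> AnalysisConfig:
    return AnalysisConfig(
        imputation=ImputationModelSpec(predictors=("age", "psa"),
                                       iterations=4, m=3),
        fixed_covariates=("age",),
        time_varying=("psa", "alk_phos"),
        categorical_refs={},
        seed=7,
    )
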