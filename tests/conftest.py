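import numpy as np
import pandas as pd
import pytest

import ediirisk as er
from ediirisk.survival import ModelSpec


@pytest.fixture(scope="session")
def reference():
    return er.default_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """One calibrated per-SD cohort, shared by read-only tests."""
    cfg = er.calibration.recovery_config("per_sd", n=4000, seed=42)
    cohort, log, densities = er.simulate_analysis_cohort(cfg)
    return cohort, log, densities


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no exposure effects (only covariate hazards)."""
    cfg = er.calibration.recovery_config("null", n=4000, seed=43)
    cohort, _, _ = er.simulate_analysis_cohort(cfg)
    return cohort


@pytest.fixture
def tier1_spec():
    return ModelSpec(tier=1, exposure="edii_sd")


def lean_spec(exposure="edii_sd"):
    """Minimal adjustment set for speed in replicate loops."""
    return ModelSpec(tier=1, exposure=exposure, covariates=["age", "male", "smoker"])
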