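import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from crshape.cox import CohortTable
from crshape.simulate import (
    ExposureSpec,
    SimulationDesign,
    default_true_curve,
    generate_cohort,
)


@pytest.fixture(scope="session")
def exposure_spec():
    return ExposureSpec()


@pytest.fixture(scope="session")
def true_curve(exposure_spec):
    """The default log-type sigmoidal truth with mu at the median."""
    return default_true_curve(exposure_spec)


@pytest.fixture(scope="session")
def medium_cohort(true_curve):
    """One seeded n=20,000 cohort generated under the default truth."""
    design = SimulationDesign(true_curve=true_curve, seed=42)
    return generate_cohort(design)


@pytest.fixture(scope="session")
def small_cohort(true_curve):
    """A quick n=2,000 cohort for smoke-level fitting tests."""
    design = SimulationDesign(n_subjects=2_000, true_curve=true_curve, seed=7)
    return generate_cohort(design)


@pytest.fixture
def four_subject_cohort():
    """Four subjects, all events at distinct times, one binary covariate."""
    df = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 1],
            "x": [1.0, 0.0, 1.0, 0.0],
        }
    )
    return CohortTable(df, "time", "event", "x")
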