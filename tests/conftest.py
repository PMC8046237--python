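import numpy as np
import pandas as pd
import pytest

from epicmap.instruments import ExtraTerm, ValueSet
from epicmap.simulate import CohortSimulator, generate_cohort


@pytest.fixture(scope="session")
def simulator():
    """Default-calibrated cohort simulator (calibration paid once)."""
    return CohortSimulator()


@pytest.fixture(scope="session")
def cohort_565(simulator):
    """One default synthetic estimation cohort."""
    return simulator.sample(n=565, seed=42)


@pytest.fixture(scope="session")
def cohort_10k(simulator):
    """Large cohort for calibration checks."""
    return simulator.sample(n=10_000, seed=7)


@pytest.fixture
def synthetic_value_set():
    """All-nonpositive synthetic tariff used wherever exact US numbers do not matter."""
    decs = {
        "mobility": {2: -0.05, 3: -0.30},
        "self_care": {2: -0.07, 3: -0.25},
        "usual_activities": {2: -0.04, 3: -0.20},
        "pain_discomfort": {2: -0.09, 3: -0.35},
        "anxiety_depression": {2: -0.06, 3: -0.28},
    }
    return ValueSet(
        name="synthetic_test",
        decrements=decs,
        extra_terms=(ExtraTerm("D1", "any_dysfunction", -0.08),),
    )
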