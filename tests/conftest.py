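import pytest

from theradose import (
    CU64,
    NormalizedActivityPoint,
    normalized_activity,
    OrganMeasurement,
    to_physical_units,
)
from theradose.simulate import StudyDesign, generate_study

# liver %IA/g series (mean, SD) at the three sampling times, organ mass 1.01 g;
# the worked reference data set used throughout the tests
LIVER_SERIES = [(4.3, 16.3, 0.6), (26.0, 12.7, 1.4), (50.2, 12.8, 2.8)]
LIVER_MASS = 1.01


@pytest.fixture
def liver_points() -> list[NormalizedActivityPoint]:
    """Decay-corrected liver normalized activities from the %IA/g series."""
    return [
        normalized_activity(
            OrganMeasurement("liver", t, mean, sd, n=3), LIVER_MASS
        )
        for t, mean, sd in LIVER_SERIES
    ]


@pytest.fixture
def liver_uncorrected(liver_points) -> list[NormalizedActivityPoint]:
    """Liver activities with physical decay re-applied (Cu-64)."""
    return to_physical_units(liver_points, CU64)


@pytest.fixture(scope="session")
def noiseless_study():
    """Synthetic study with zero measurement noise, with its truth record."""
    design = StudyDesign(seed=20260927, noise_cv=0.0)
    return generate_study(design)
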