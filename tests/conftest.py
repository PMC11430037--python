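import numpy as np
import pytest

from dysglyc import (
    GeneratorConfig,
    GlucoseTrace,
    PatientRecord,
    generate_cohort,
    make_fixture_trace,
)


def random_trace(rng, n_min=2, n_max=40, t_max=300.0, patient_id="rand") -> GlucoseTrace:
    """An arbitrary valid trace: unique sorted times, physiological values."""
    n = int(rng.integers(n_min, n_max + 1))
    times = np.sort(rng.uniform(0, t_max, size=n))
    while np.any(np.diff(times) <= 1e-6):
        times = np.sort(rng.uniform(0, t_max, size=n))
    values = rng.uniform(45.0, 350.0, size=n)
    return GlucoseTrace(patient_id, times, values)


@pytest.fixture
def rng():
    return np.random.default_rng(20240849)


@pytest.fixture
def two_patient_cohort():
    """One no-DCI and one DCI patient (onset 100 h) with handcrafted traces."""
    records = [
        PatientRecord("A", "noDCI", None, 61.0, "female", 2, 2, 34),
        PatientRecord("B", "DCI", 100.0, 48.5, "male", 4, 3, 41),
    ]
    traces = [
        make_fixture_trace([(0.0, 110.0), (4.0, 130.0), (8.5, 120.0)], "A"),
        make_fixture_trace(
            [(0.0, 125.0), (50.0, 150.0), (99.0, 132.0), (100.0, 160.0), (150.0, 145.0)],
            "B",
        ),
    ]
    return records, traces


@pytest.fixture(scope="session")
def small_cohort():
    """A generated default-condition cohort, small enough for fast tests."""
    return generate_cohort(GeneratorConfig(n_patients=60, seed=11))
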