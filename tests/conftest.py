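import numpy as np
import pytest

from massresponse import (
    MassRecord,
    ParticleClass,
    Role,
    SimulationSpec,
    sample_masses,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture(scope="session")
def baseline_spec():
    """Default baseline population: lognormal, mean 60 pg, CV 0.35."""
    return SimulationSpec()


@pytest.fixture(scope="session")
def baseline_population(baseline_spec):
    """A 10k-cell draw from the baseline, shared across read-only tests."""
    return sample_masses(baseline_spec, 10_000, rng=101)


@pytest.fixture
def contaminated_spec():
    """20% aggregates+debris, 10% permeable, as in a messy primary sample."""
    return SimulationSpec.contaminated(0.2)


def make_experiment_records(n_per=50, n_tests=2, seed=7):
    """Small well-formed session: reference, control, and test conditions."""
    gen = np.random.default_rng(seed)
    records = []

    def add(cid, role, t):
        masses = gen.lognormal(4.0, 0.3, n_per)
        records.extend(
            MassRecord(float(m), ParticleClass.INTACT, cid, role, t)
            for m in masses
        )

    add("REF", Role.REFERENCE, 0.0)
    for k in range(n_tests):
        add(f"DRUG_{k}", Role.TEST, 600.0 * (k + 1))
    add("CTRL", Role.CONTROL, 10_000.0)
    return records


@pytest.fixture
def experiment_records():
    return make_experiment_records()
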