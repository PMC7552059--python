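import numpy as np
import pytest
from hypothesis import settings

from vdomics.assignment import AssignmentRules, assign_spectrum, get_database
from vdomics.qc import run_qc
from vdomics.synthetic import (
    SimulationConfig,
    generate_formula_library,
    simulate_experiment,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rules():
    return AssignmentRules()


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study conditions for fast end-to-end tests."""
    return SimulationConfig(seed=7, n_library=600, n_vdom=150, n_noise_peaks=50)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_formula_library(small_config)


@pytest.fixture(scope="session")
def small_experiment(small_truth):
    return simulate_experiment(small_truth)


@pytest.fixture(scope="session")
def small_db(small_config, rules):
    return get_database(rules, small_config.mass_range[0] - 2.0,
                        small_config.mass_range[1] + 25.0)


@pytest.fixture(scope="session")
def small_assignments(small_experiment, small_db, rules):
    spectra, _ = small_experiment
    return {sp.sample_id: assign_spectrum(sp, rules, db=small_db) for sp in spectra}


@pytest.fixture(scope="session")
def small_table(small_assignments, small_experiment, rules):
    _, metas = small_experiment
    return run_qc(small_assignments, metas, rules)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
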