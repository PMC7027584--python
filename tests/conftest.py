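import pytest

from runinmeta import SimConfig, load_table1, simulate_trial_set


@pytest.fixture(scope="session")
def table1():
    """Packaged design-characteristics fixture (35 trials, no outcomes)."""
    return load_table1()


@pytest.fixture(scope="session")
def synthetic_set():
    """A complete synthetic trial set with all outcome fields populated."""
    return simulate_trial_set(
        SimConfig(n_trials=20, patients_per_trial=150, seed=42))


@pytest.fixture(scope="session")
def small_set():
    return simulate_trial_set(
        SimConfig(n_trials=8, patients_per_trial=80, seed=11))
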