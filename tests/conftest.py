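import pytest

from ffrcea.config import load_model_params, load_trial_config, load_unit_costs
from ffrcea.synthetic import generate_trial


@pytest.fixture(scope="session")
def unit_costs():
    return load_unit_costs()


@pytest.fixture(scope="session")
def model_params():
    return load_model_params()


@pytest.fixture(scope="session")
def small_trial(unit_costs):
    """A modest default-calibration trial with missingness, for unit tests."""
    cfg = load_trial_config(n_per_arm=2000, seed=1234)
    return generate_trial(cfg, unit_costs)


@pytest.fixture(scope="session")
def complete_trial(unit_costs):
    """A complete-case (no missingness) trial used by model-fitting tests."""
    cfg = load_trial_config(n_per_arm=2000, seed=77, missingness_rates=(0.0, 0.0))
    return generate_trial(cfg, unit_costs)
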