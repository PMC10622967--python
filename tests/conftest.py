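import warnings

import pytest

from vlcpufa.chem import load_reference_panel
from vlcpufa.simulate import ScenarioConfig, simulate_experiment


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture
def quiet_simulate():
    """simulate_experiment with the expected isomer co-elution warning silenced."""

    def _run(configs, **kwargs):
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="isomers .* unresolvable")
            return simulate_experiment(configs, **kwargs)

    return _run


@pytest.fixture
def challenge_config():
    return ScenarioConfig(scenario="pos_challenge", pos_per_cell=20.0, noise_cv=0.0)
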