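import warnings

import pytest

from neurocognet.battery import compute_contrasts, default_battery, orient_scores
from neurocognet.simulate import SimConfig, generate_norms, generate_trial


@pytest.fixture(scope="session")
def spec():
    return default_battery()


@pytest.fixture(scope="session")
def sim_outputs(spec):
    """One fixed small trial shared across tests (seed 5, defaults)."""
    cfg = SimConfig(seed=5)
    data, truth = generate_trial(cfg, spec)
    norms = generate_norms(cfg, spec)
    return cfg, data, truth, norms


@pytest.fixture()
def trial(sim_outputs):
    return sim_outputs[1]


@pytest.fixture()
def truth(sim_outputs):
    return sim_outputs[2]


@pytest.fixture()
def norms(sim_outputs):
    return sim_outputs[3]


@pytest.fixture()
def oriented(trial, spec):
    return orient_scores(trial, spec)


@pytest.fixture()
def full(oriented, spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_contrasts(oriented, spec)
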