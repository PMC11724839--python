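import numpy as np
import pytest
from hypothesis import settings

import stumblekit as sk

settings.register_profile("ci", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_cfg():
    return sk.SimulationConfig(
        marker_noise_sd=0.0, force_noise_sd=0.0, metric_noise_sd={},
        n_perturbations_per_side=3, seed=5)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_cfg):
    """One noiseless simulated perturbation trial shared across tests."""
    trial, truth = sk.simulate_trial(noiseless_cfg)
    return trial, truth


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_cfg, noiseless_trial):
    trial, truth = noiseless_trial
    static = sk.generate_static_trial(noiseless_cfg)
    return sk.analyze_trial(trial, static)


@pytest.fixture(scope="session")
def corrupted_batch():
    """Trials with grabs, dropout, and mid-line crossings plus their truth."""
    out = []
    for seed in (9, 10):
        cfg = sk.SimulationConfig(
            n_perturbations_per_side=5, seed=seed,
            snp_condition="active" if seed % 2 else "inactive",
            handrail_grab_probability=0.4, dropout_probability=0.4,
            midline_cross_probability=0.4)
        trial, truth = sk.simulate_trial(cfg)
        ana = sk.analyze_trial(trial, sk.generate_static_trial(cfg))
        out.append((cfg, trial, truth, ana))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
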