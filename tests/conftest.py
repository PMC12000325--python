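import numpy as np
import pytest

import phaseopp as pp


@pytest.fixture(scope="session")
def planted_trials():
    """Strong planted opposition at (8 Hz, -256 ms), 50 trials/condition."""
    cfg = pp.SynthTrialConfig(n_trials_per_condition=50, kappa=8.0, seed=11)
    trials, labels = pp.make_phase_coded_trials(cfg)
    return cfg, trials, labels


@pytest.fixture(scope="session")
def planted_analytic(planted_trials):
    _, trials, _ = planted_trials
    return pp.morlet_analytic(trials)


@pytest.fixture(scope="session")
def null_trials():
    """kappa = 0: no planted effect."""
    cfg = pp.SynthTrialConfig(n_trials_per_condition=30, kappa=0.0, seed=5)
    trials, labels = pp.make_phase_coded_trials(cfg)
    return cfg, trials, labels


@pytest.fixture(scope="session")
def coupled_pair():
    cfg = pp.CoupledPairConfig(seed=4)
    trials, thetas = pp.make_coupled_source_pair(cfg, 100)
    gated = np.array(trials.meta["gated"])
    return cfg, trials, thetas, gated
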