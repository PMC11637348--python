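import numpy as np
import pytest

from thalamoflow import synth, task


@pytest.fixture(scope="session")
def mapping():
    return task.TaskMapping()


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    """Noiseless 8-run dataset whose cortical patterns are W* O* exactly."""
    brain = synth.make_brain(n_seed=60, n_targets=30, seed=11)
    events = task.generate_trial_sequence(n_runs=8, trials_per_run=20, seed=11)
    return synth.simulate_timeseries(
        brain, events, noise_sd=0.0, seed=11, fd_spike_rate=0.0
    )


@pytest.fixture(scope="session")
def small_noisy_dataset():
    brain = synth.make_brain(n_seed=60, n_targets=30, seed=7)
    events = task.generate_trial_sequence(n_runs=4, trials_per_run=16, seed=7)
    return synth.simulate_timeseries(brain, events, noise_sd=1.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
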