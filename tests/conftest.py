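import numpy as np
import pytest

from steplen import SubjectSpec, preprocess, simulate_bout


@pytest.fixture(scope="session")
def noiseless_subject():
    return SubjectSpec(
        "noiseless", mean_step_length=60.0, step_length_sd=0.0, noise_sd=0.0
    )


@pytest.fixture(scope="session")
def noiseless_bout(noiseless_subject):
    """60 cm, sd-0, noise-free 20-step bout plus its ground-truth table."""
    return simulate_bout(noiseless_subject, n_steps=20, seed=1)


@pytest.fixture(scope="session")
def noiseless_conditioned(noiseless_bout):
    rec, table = noiseless_bout
    return preprocess(rec), table


@pytest.fixture(scope="session")
def noisy_bout():
    """Realistic 12-step bout: step-to-step variability + 0.3 m/s^2 noise."""
    subject = SubjectSpec(
        "noisy", mean_step_length=60.0, step_length_sd=2.5, noise_sd=0.3
    )
    return simulate_bout(subject, n_steps=12, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
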