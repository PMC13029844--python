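import numpy as np
import pytest
from hypothesis import settings

from gaitrank.grf import GRFCycle, pad_to_uniform
from gaitrank.synthetic import GeneratorConfig, build_study, generate_cycle, sample_population

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cycle(n=800, stance=(40, 600), subject="S1", amp=700.0, seed=0,
               condition="unloaded", trial=0):
    """Hand-built valid cycle: half-sine stances on both limbs."""
    rng = np.random.default_rng(seed)
    sig = np.zeros((6, n))
    s, e = stance
    t = np.linspace(0, np.pi, e - s)
    bump = np.sin(t)
    for base in (0, 3):
        sig[base + 1, s:e] = amp * bump
        sig[base + 0, s:e] = 0.2 * amp * np.sin(2 * t)
        sig[base + 2, s:e] = 0.05 * amp * bump
    return GRFCycle(subject_id=subject, condition=condition, trial_id=trial,
                    signal=sig, body_mass_kg=75.0)


@pytest.fixture
def simple_cycle():
    return make_cycle()


@pytest.fixture(scope="session")
def noiseless_config():
    return GeneratorConfig(
        n_subjects=3, trials_min=5, trials_max=5, seed=11
    ).noiseless()


@pytest.fixture(scope="session")
def noiseless_study(noiseless_config):
    return build_study(noiseless_config)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_subjects=8, trials_min=6, trials_max=6, seed=5)


@pytest.fixture(scope="session")
def small_study(small_config):
    return build_study(small_config)


@pytest.fixture(scope="session")
def small_profiles(small_config):
    return sample_population(small_config)
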