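import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_trials_clean():
    """Full three-experiment trial table, zero noise and zero omissions."""
    from phonconv.design import full_study_designs
    from phonconv.simulate import full_study_profiles, simulate_experiment

    designs = full_study_designs()
    profiles = full_study_profiles(designs, seed=11, noise_sd=(0.0, 0.0), error_rate=0.0)
    res = simulate_experiment(designs, profiles, seed=11)
    return res


@pytest.fixture(scope="session")
def s1_i_vowel():
    """Synthesized S1 /i/ vowel (F0 210 Hz, F1 285 Hz) padded with silence."""
    from phonconv.synth import make_target_stimuli
    from phonconv.targets import TARGET_BANK

    stim = make_target_stimuli(TARGET_BANK)
    w = stim[("S1", "i")]
    pad = np.zeros(22050)
    return np.concatenate([pad, w, pad]), 44100
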