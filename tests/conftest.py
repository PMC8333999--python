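import numpy as np
import pytest

from cmaad.io import DecisionWindow, ProcessedTrial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_processed_trial(rng, M=4, S=700, fs=70.0, attended="A",
                         trial_id="T0"):
    eeg = rng.standard_normal((M, S))
    eeg = (eeg - eeg.mean(axis=1, keepdims=True)) / eeg.std(axis=1,
                                                            keepdims=True)
    env_a = np.abs(rng.standard_normal(S)) + 0.1
    env_b = np.abs(rng.standard_normal(S)) + 0.1
    env_a = env_a / np.sqrt(np.mean(env_a ** 2))
    env_b = env_b / np.sqrt(np.mean(env_b ** 2))
    return ProcessedTrial(eeg_feat=eeg, env_a=env_a, env_b=env_b,
                          attended=attended, trial_id=trial_id, fs=fs)


def make_window(rng, M=4, T=20, attended="A"):
    return DecisionWindow(
        eeg=rng.standard_normal((M, T)), env_a=rng.standard_normal(T),
        env_b=rng.standard_normal(T), attended=attended)


@pytest.fixture
def processed_trial(rng):
    return make_processed_trial(rng)
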