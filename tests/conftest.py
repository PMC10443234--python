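import numpy as np
import pytest

from crossgen.datasets import TrialSet


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_trialset():
    """Fixed 6-trial, 3-channel instance used by the brute-force oracles."""
    data = np.array(
        [
            [1.2, -0.3, 0.5],
            [0.8, 0.1, -0.2],
            [-0.9, 0.4, 0.3],
            [1.5, -0.8, 0.9],
            [0.2, 0.6, -1.1],
            [-1.3, 0.2, 0.7],
        ]
    )
    labels = np.array([1, 2, 2, 1, 1, 2])
    return TrialSet(data=data, labels=labels, context_id="A", replicate_id="r0")


def make_gaussian_trialset(
    rng, delta, n_trials=40, context_id="A", replicate_id="r0", noise_sd=1.0
):
    """Balanced two-class Gaussian trials with true mean difference `delta`."""
    delta = np.asarray(delta, dtype=float)
    half = n_trials // 2
    labels = np.r_[np.ones(half, dtype=int), np.full(half, 2, dtype=int)]
    signs = np.where(labels == 1, 0.5, -0.5)
    data = signs[:, None] * delta[None, :] + noise_sd * rng.standard_normal(
        (n_trials, len(delta))
    )
    return TrialSet(data=data, labels=labels, context_id=context_id,
                    replicate_id=replicate_id)
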