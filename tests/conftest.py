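import numpy as np
import pytest

from eegemotion.synthetic import SyntheticSpec, generate_eeg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticSpec(
        n_subjects=2,
        n_trials_per_subject=8,
        trial_duration=8.0,
        baseline_duration=2.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_eeg(tiny_spec)


def numeric_grad(f, xs, i, eps=1e-6):
    """Central finite differences of scalar f(list-of-arrays) wrt xs[i]."""
    g = np.zeros_like(xs[i])
    it = np.nditer(xs[i], flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = [x.copy() for x in xs]
        xm = [x.copy() for x in xs]
        xp[i][idx] += eps
        xm[i][idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g
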