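import numpy as np
import pytest

from psvae.synthgen import SceneSpec, generate_session
from psvae.training import TrialDataset


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene for fast unit tests (defaults otherwise)."""
    return SceneSpec()


@pytest.fixture(scope="session")
def small_session(small_scene):
    trials, traces = generate_session(small_scene, n_trials=10, trial_len=40,
                                      seed=123)
    return trials, traces


@pytest.fixture(scope="session")
def small_dataset(small_session):
    trials, _ = small_session
    return TrialDataset(trials)


def finite_difference(f, x, eps=1e-6):
    """Central finite differences of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
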