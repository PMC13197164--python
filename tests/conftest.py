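import hypothesis
import numpy as np
import pytest

from dyadreach import ModelParams

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Default study-condition model parameters."""
    return ModelParams()


@pytest.fixture(scope="session")
def fast_params():
    """Shorter horizon for tests that only need closed-loop mechanics."""
    return ModelParams(horizon_steps=60)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_game(rng, n=4, m=2):
    """A random small two-player LQ game (dense, well-conditioned)."""
    A = rng.normal(0, 0.5, (n, n)) + 0.5 * np.eye(n)
    B1 = rng.normal(0, 1, (n, m))
    B2 = rng.normal(0, 1, (n, m))
    def psd():
        M = rng.normal(0, 1, (n, n))
        return M @ M.T / n
    Q1T, Q2T = psd(), psd()
    R1 = np.eye(m) * rng.uniform(0.5, 2.0)
    R2 = np.eye(m) * rng.uniform(0.5, 2.0)
    a1, a2 = rng.uniform(0, 1, 2)
    return A, B1, B2, Q1T, Q2T, R1, R2, a1, a2
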