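import numpy as np
import pytest

from spiderfs.core import ExpressionDataset
from spiderfs.synthetic import SyntheticSpec, generate_synthetic_dataset


@pytest.fixture()
def tiny_dataset():
    """4 samples x 2 features, labels A,A,B,B (tie broken to A=+1)."""
    return ExpressionDataset(
        matrix=np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0], [4.0, 40.0]]),
        labels=np.array([1, 1, -1, -1]),
        feature_names=("f1", "f2"),
        sample_ids=("s1", "s2", "s3", "s4"),
        label_names={1: "A", -1: "B"},
    )


@pytest.fixture(scope="session")
def small_planted():
    """Fast planted-signal dataset for wrapper/classifier tests."""
    spec = SyntheticSpec(
        n_samples=80,
        n_informative=5,
        n_redundant_per_informative=1,
        n_noise=50,
        effect_size=2.0,
        redundancy_rho=0.8,
        imbalance=1.5,
        seed=7,
    )
    return generate_synthetic_dataset(spec)


@pytest.fixture(scope="session")
def default_fixture():
    """The package's default study-condition fixture (n=100, d=500)."""
    return generate_synthetic_dataset(SyntheticSpec(seed=0))


class StubRng:
    """Deterministic stand-in for a Generator: replays queued draws."""

    def __init__(self, draws):
        self.draws = list(draws)

    def random(self, shape=None):
        if shape is None:
            return self.draws.pop(0)
        out = np.empty(shape if isinstance(shape, tuple) else (shape,))
        flat = out.reshape(-1)
        for i in range(flat.size):
            v = self.draws.pop(0)
            flat[i] = v
        return out


class ConstRng:
    """Returns a constant for every uniform draw."""

    def __init__(self, value):
        self.value = value

    def random(self, shape=None):
        if shape is None:
            return self.value
        return np.full(shape, self.value)


@pytest.fixture()
def stub_rng():
    return StubRng


@pytest.fixture()
def const_rng():
    return ConstRng
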