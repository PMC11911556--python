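import numpy as np
import pytest

import m5censemble as m


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """60 balanced windows with moderate positional signal."""
    return m.generate(30, 30, m.default_logo(0.4, seed=101))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    X, names = m.assemble_dataset(small_dataset)
    return X, small_dataset.labels, names


def _extracted(effect, seed, n_per_class):
    ds = m.generate(n_per_class, n_per_class, m.default_logo(effect, seed=seed))
    X, names = m.assemble_dataset(ds)
    return X, ds.labels, names


@pytest.fixture(scope="session")
def features_strong_signal():
    """n = 1000/class at effect 0.4 — the strong-signal study condition."""
    return _extracted(0.4, 11, 1000)


@pytest.fixture(scope="session")
def features_null_signal():
    """n = 1000/class at effect 0 — positives and negatives identical."""
    return _extracted(0.0, 12, 1000)


@pytest.fixture
def random_windows():
    """200 random valid windows (center C), as plain strings."""
    local = np.random.default_rng(4242)
    alphabet = np.array(list("ACGU"))
    out = []
    for _ in range(200):
        chars = alphabet[local.integers(0, 4, size=41)]
        chars[20] = "C"
        out.append("".join(chars))
    return out
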