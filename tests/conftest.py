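import numpy as np
import pytest

from latentpls.data_prep import standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


def random_pls_instance(seed, n=None, p=None, m=None):
    """Seeded standardized (X, U) pair with random dimensions."""
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(10, 41))
    p = p or int(rng.integers(2, 9))
    m = m or int(rng.integers(1, 5))
    X = rng.standard_normal((n, p))
    U = X @ rng.standard_normal((p, m)) + 0.5 * rng.standard_normal((n, m))
    return standardize(X).values, standardize(U).values


def align_signs(reference, other):
    """Flip columns of `other` to match the column signs of `reference`."""
    signs = np.sign(np.sum(reference * other, axis=0))
    signs[signs == 0] = 1.0
    return other * signs


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """On-disk CSV fixtures for all three outcome kinds."""
    from latentpls.synthetic_data import make_fixture

    root = tmp_path_factory.mktemp("fixtures")
    return {kind: make_fixture(kind, root)
            for kind in ("tiny", "binary", "survival")}
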