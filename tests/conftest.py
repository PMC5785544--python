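import numpy as np
import pytest

from phylomorph import Phylogeny, SyntheticScenario, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tree():
    """5-tip rooted tree with mixed branch lengths."""
    return Phylogeny.from_newick(
        "((A:1.0,B:2.0):0.5,((C:0.7,D:0.7):0.9,E:1.6):0.4);", is_path=False)


@pytest.fixture(scope="session")
def study96():
    """One moderate synthetic study shared across read-only tests."""
    return simulate_study(SyntheticScenario(seed=7, n_tips=96))


def random_configuration(rng, k=20, d=2, scale=1.0):
    return rng.standard_normal((k, d)) * scale


def random_rotation(rng, d):
    A = rng.standard_normal((d, d))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
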