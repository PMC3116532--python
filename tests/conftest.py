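import numpy as np
import pytest

from mdmdfit.model_io import Structure
from mdmdfit.synthetic import PseudoTrnaSpec, make_pseudo_trna


@pytest.fixture(scope="session")
def trna90():
    """Default pseudo-tRNA with a 90-degree interarm angle."""
    return make_pseudo_trna(PseudoTrnaSpec(hinge_angle=90.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_structure(coords, names=None, resids=None, resnames=None,
                  chains=None, elements=None):
    """Minimal Structure around a coordinate array (test helper)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    names = names or ["P"] * n
    resids = resids if resids is not None else list(range(1, n + 1))
    resnames = resnames or ["G"] * n
    chains = chains or ["A"] * n
    return Structure(range(1, n + 1), names, resnames, chains, resids,
                     coords, elements)
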