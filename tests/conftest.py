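import numpy as np
import pytest

from dynalysis.io import Ensemble, Selection, Topology


def make_topology(n_atoms, names=None, resnames=None, resids=None,
                  elements=None, chains=None):
    return Topology(
        names=np.array(names or ["CA"] * n_atoms, dtype=object),
        elements=np.array(elements or ["C"] * n_atoms, dtype=object),
        resnames=np.array(resnames or ["ALA"] * n_atoms, dtype=object),
        resids=np.array(resids if resids is not None
                        else np.arange(1, n_atoms + 1)),
        chainids=np.array(chains or ["A"] * n_atoms, dtype=object),
    )


def make_ensemble(coords, topology=None, label="test"):
    coords = np.asarray(coords, dtype=float)
    top = topology or make_topology(coords.shape[1])
    times = 0.1 * np.arange(1, coords.shape[0] + 1)
    return Ensemble(coords, times, top, label)


@pytest.fixture
def toy_ensemble():
    """3 atoms, 5 random frames."""
    rng = np.random.default_rng(42)
    return make_ensemble(rng.normal(scale=1.0, size=(5, 3, 3)) + 5.0)


@pytest.fixture
def all_atoms():
    return lambda ens: Selection(tuple(range(ens.n_atoms)))
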