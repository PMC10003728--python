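import numpy as np
import pytest

from vhhdyn.io_formats import Ensemble
from vhhdyn.pb import load_prototypes
from vhhdyn.synthetic import default_family_spec, gen_family


@pytest.fixture(scope="session")
def prototypes():
    return load_prototypes()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_ensemble(coords, residues=None, domain_id="dom", bfactors=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return Ensemble(domain_id=domain_id, coords=coords,
                    residues=residues or "A" * n, bfactors=bfactors)


@pytest.fixture
def straight_chain():
    """A 6-residue chain with trivially regular backbone geometry."""
    n = 6
    coords = np.zeros((1, n, 3, 3))
    for i in range(n):
        coords[0, i, 0] = (3.8 * i, 0.0, 0.0)
        coords[0, i, 1] = (3.8 * i + 1.2, 0.9, 0.0)
        coords[0, i, 2] = (3.8 * i + 2.4, 0.0, 0.3)
    return make_ensemble(coords)


@pytest.fixture(scope="session")
def family_two_class():
    """Two well-separated classes, long sampling (shared across tests)."""
    spec = default_family_spec(n_classes=2, domains_per_class=2,
                               n_frames=2000, seed=7)
    return gen_family(spec)


@pytest.fixture(scope="session")
def family_four_class():
    spec = default_family_spec(n_classes=4, domains_per_class=5,
                               n_frames=200, seed=1)
    return gen_family(spec)
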