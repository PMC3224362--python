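import numpy as np
import pytest

from sashape.model import default_model
from sashape.sasa import build_reference
from sashape.synthetic import HelixSpec, make_complex


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def reference():
    """ALA-X-ALA reference accessibilities (built once per session)."""
    return build_reference()


@pytest.fixture(scope="session")
def two_helix_complex():
    """Two parallel 12-residue helices 9 Å apart: a genuine buried interface."""
    return make_complex(HelixSpec(n_residues=12), HelixSpec(n_residues=12),
                        separation=9.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
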