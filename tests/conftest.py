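import logging

import numpy as np
import pytest

from scplpa.core_io import AssociationMatrix, DiseaseDAGSet, SCPLPAConfig
from scplpa.synthetic_data import FixtureSpec, generate_fixture

logging.getLogger("scplpa").setLevel(logging.ERROR)


@pytest.fixture
def two_block_assoc() -> AssociationMatrix:
    """Two planted blocks: {m1,m2}x{d1,d2} fully linked plus {m3}x{d3}."""
    md = np.array([[1.0, 1, 0], [1, 1, 0], [0, 0, 1]])
    return AssociationMatrix(md, ("m1", "m2", "m3"), ("d1", "d2", "d3"))


@pytest.fixture
def two_block_dags() -> DiseaseDAGSet:
    """d1 and d2 share an ancestor, d3 sits in its own subtree."""
    return DiseaseDAGSet.from_edges(
        [("d1", "P"), ("d2", "P"), ("d3", "Q")], diseases=["d1", "d2", "d3"]
    )


@pytest.fixture
def default_config() -> SCPLPAConfig:
    return SCPLPAConfig()


@pytest.fixture
def small_fixture():
    """A small but nontrivial generated instance (8 miRNAs x 6 diseases)."""
    spec = FixtureSpec(
        nm=8, nd=6, n_blocks=2, within_block_prob=0.8, cross_block_prob=0.05, seed=7
    )
    return generate_fixture(spec)
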