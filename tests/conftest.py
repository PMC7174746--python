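import numpy as np
import pytest

from hetelink import AssociationMatrix, PipelineConfig, SimilarityMatrix
from hetelink.synthetic import default_fixture


@pytest.fixture(scope="session")
def fixture_data():
    """The default synthetic block-structured instance (60 lncRNAs x 20 EFs)."""
    return default_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_stack(fixture_data):
    from hetelink import build_feature_stack

    return build_feature_stack(
        fixture_data.associations, fixture_data.chemical, PipelineConfig(seed=1)
    )


@pytest.fixture()
def tiny_assoc():
    """2x2 identity association matrix: each lncRNA paired with one EF."""
    return AssociationMatrix(np.eye(2), ("L1", "L2"), ("E1", "E2"))


def make_similarity(values, ids, kind="chemical"):
    return SimilarityMatrix(np.asarray(values, float), tuple(ids), kind)


@pytest.fixture()
def make_sim():
    return make_similarity
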