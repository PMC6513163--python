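import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

from regionfp.feature_space import FeatureSpace
from regionfp.gicf_model import GICFModel, LabelSet, add_intercept
from regionfp.synthetic_fixtures import SyntheticSpec, generate_corpus

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """A small planted corpus shared across tests (cheap to regenerate)."""
    return generate_corpus(SyntheticSpec(n_proteins=40, seed=7))


def make_toy_model(theta, w1=0.0, w2=0.0, lam=0.0):
    return GICFModel(
        go_id="GO:0003677", space=FeatureSpace.KEY,
        theta=np.asarray(theta, dtype=float), w1=w1, w2=w2, lam=lam,
    )


@pytest.fixture
def two_region_instance():
    """One protein, two regions with scores 0.2 and 0.8 under theta=[ln4, 0].

    X carries one feature (-1 for region 0, +1 for region 1) plus the
    intercept column; kappa couples the two regions with similarity 1.
    """
    X = add_intercept(sp.csr_matrix(np.array([[-1.0], [1.0]])))
    theta = np.array([np.log(4.0), 0.0])
    kernel_values = sp.csr_matrix(np.array([[1.0, 1.0], [1.0, 1.0]]))
    labels = LabelSet(
        protein_labels={"P1": 1},
        protein_regions={"P1": [0, 1]},
    )
    return X, theta, kernel_values, labels
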