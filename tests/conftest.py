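import numpy as np
import pytest

from pharmensemble import generate_world
from pharmensemble.pharmacophore import ConformerFeatures, FeaturePoint


@pytest.fixture(scope="session")
def small_world():
    """A 3-template planted world shared across tests (read-only)."""
    return generate_world(n_templates=3, actives_per_template=8,
                          n_inactives=16, noise_sigma=0.2, seed=11)


def feature_cloud(types_xyz, cid="c", conf=0):
    """Build ConformerFeatures from (type, (x, y, z)) pairs."""
    return ConformerFeatures(cid, conf,
                             [FeaturePoint(t, tuple(map(float, xyz)))
                              for t, xyz in types_xyz])


@pytest.fixture
def square_hypothesis():
    """A 4-feature planar hypothesis on a 4 Å square."""
    from pharmensemble.pharmacophore import PharmacophoreHypothesis
    coords = np.array([[0, 0, 0], [4, 0, 0], [4, 4, 0], [0, 4, 0]], float)
    return PharmacophoreHypothesis("sq", ["A", "D", "P", "R"], coords)
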