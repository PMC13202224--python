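import numpy as np
import pytest

import petrange as pr


@pytest.fixture(scope="session")
def capillary_spec():
    return pr.CapillaryPhantomSpec(material=pr.default_material("PLA"))


@pytest.fixture(scope="session")
def capillary_phantom(capillary_spec):
    """Default capillary phantom at 0.5 mm voxels: (activity, density)."""
    return pr.build_capillary_phantom(capillary_spec, pr.GridParams())


@pytest.fixture(scope="session")
def derenzo_spec():
    return pr.DerenzoPhantomSpec()


@pytest.fixture(scope="session")
def derenzo_activity(derenzo_spec):
    """Default microDerenzo phantom at 0.25 mm voxels."""
    return pr.build_derenzo_phantom(derenzo_spec, pr.GridParams(voxel_size=0.25, margin=4.0))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
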