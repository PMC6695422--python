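import numpy as np
import pytest

from tractlanes import PhantomSpec, generate_phantom
from tractlanes.tractometry import resample_bundle


@pytest.fixture(scope="session")
def default_phantom():
    """Default segregated phantom (d = 8 mm) with scalar map, seed 1."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def phantom_nomap():
    """Default segregated phantom without the scalar map (cheap)."""
    return generate_phantom(PhantomSpec(seed=1), include_scalar_map=False)


def lane_bundles(phantom, n_nodes=100):
    """Resampled (reading, math) sub-bundles of a phantom, truth-labelled."""
    tracts = phantom.tracts
    a = resample_bundle(tracts.subset(tracts.network == "reading"), n_nodes)
    b = resample_bundle(tracts.subset(tracts.network == "math"), n_nodes)
    return a, b


@pytest.fixture(scope="session")
def default_lanes(phantom_nomap):
    return lane_bundles(phantom_nomap)
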