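import numpy as np
import pytest

import tractweave as tw


@pytest.fixture(scope="session")
def phantom_vol():
    return tw.make_phantom()


@pytest.fixture(scope="session")
def phantom_field():
    return tw.make_default_fodf()


@pytest.fixture(scope="session")
def protocols():
    return tw.load_protocols()


@pytest.fixture(scope="session")
def bundle_phantom():
    """Straight-bundle phantom shared by tracker and reliability tests."""
    from tractweave.synthetic import make_bundle_phantom
    return make_bundle_phantom()


@pytest.fixture(scope="session")
def bundle_tracked(bundle_phantom):
    """One tracked realization (50 streamlines) on the straight bundle."""
    rng = np.random.default_rng(42)
    return tw.track(bundle_phantom["protocol"], bundle_phantom["field"],
                    bundle_phantom["rois"], rng, n_streamlines=50)


def binary_map(grid, affine=None):
    affine = np.eye(4) if affine is None else affine
    return tw.ScalarMap(np.asarray(grid, dtype=np.uint8), affine, role="binary")
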