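import numpy as np
import pytest

from gpcrstate import (
    BundleParams,
    CentroidTable,
    build_bundle,
    cb1_like_map,
    cb1_like_segments,
)


@pytest.fixture(scope="session")
def params():
    return BundleParams()


@pytest.fixture(scope="session")
def bundle_active(params):
    return build_bundle(params, "A")


@pytest.fixture(scope="session")
def bundle_inactive(params):
    return build_bundle(params, "I")


@pytest.fixture(scope="session")
def gmap():
    return cb1_like_map()


@pytest.fixture(scope="session")
def segments():
    return cb1_like_segments()


@pytest.fixture(scope="session")
def tm_ranges(segments):
    return [segments[name] for name in segments.names()]


@pytest.fixture(scope="session")
def centroid_table(bundle_active, bundle_inactive, gmap):
    return CentroidTable.from_references(bundle_active, bundle_inactive, gmap)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-20, 20, size=3)


def apply_rigid(structure, rot, trans):
    moved = structure.copy()
    moved.set_coordinates(structure.coordinates() @ rot.T + trans)
    return moved
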