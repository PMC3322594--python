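import numpy as np
import pytest

from minisitus.fixtures import make_hexamer_map


@pytest.fixture(scope="session")
def hexamer():
    """C6 hexamer fixture at 15 A resolution, 3 A voxels (seed 1)."""
    return make_hexamer_map(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def nearest_protomer_error(pose_transform, fixture):
    """(translation A, rotation deg) error of a pose against the nearest
    planted protomer transform."""
    c = fixture.monomer.centroid
    errs = []
    for rt in fixture.transforms:
        dt = float(np.linalg.norm(pose_transform.apply(c) - rt.apply(c)))
        dr = pose_transform.rotation_angle_deg(rt)
        errs.append((dt, dr))
    return min(errs, key=lambda e: e[0] + e[1] / 10.0)
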