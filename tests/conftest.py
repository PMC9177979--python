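import numpy as np
import pytest

from salt_twist.synthetic import DuplexSpec, FluctuationSpec, build_duplex, make_trajectory


@pytest.fixture(scope="session")
def ideal_spec():
    """33-bp reference duplex, ideal B-helix step parameters."""
    return DuplexSpec()


@pytest.fixture(scope="session")
def ideal_conf(ideal_spec):
    return build_duplex(ideal_spec)


@pytest.fixture(scope="session")
def small_spec():
    return DuplexSpec(sequence="CAGGTTCCTTAG")


@pytest.fixture(scope="session")
def small_conf(small_spec):
    return build_duplex(small_spec)


@pytest.fixture(scope="session")
def fluct_traj(small_spec):
    """200-frame fluctuating 12-bp trajectory (fast shared fixture)."""
    return make_trajectory(small_spec, FluctuationSpec(n_frames=200, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng, n=None):
    """Uniformly random rotation matrices via normalized quaternions."""
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=(4,) if n is None else (n, 4))
    q = q / np.linalg.norm(q, axis=-1, keepdims=True)
    return Rotation.from_quat(q).as_matrix()
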