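import numpy as np
import pytest

from femaw import PhantomSpec, build_phantom, measure_femur


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """Mesh + landmarks for the study-mean dial settings (built once)."""
    return build_phantom(default_spec)


@pytest.fixture(scope="session")
def default_measurement(default_phantom):
    mesh, landmarks = default_phantom
    return measure_femur(mesh, landmarks)


def random_rigid_transform(rng) -> np.ndarray:
    """Uniformly random proper rigid motion as a 4x4 matrix."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    Q *= np.sign(np.linalg.det(Q))
    T = np.eye(4)
    T[:3, :3] = Q
    T[:3, 3] = rng.uniform(-80, 80, size=3)
    return T
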