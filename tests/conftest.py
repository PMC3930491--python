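import numpy as np
import pytest

from spiralpath.camera import CameraModel
from spiralpath.mstd import ModelParams, TemplateBankConfig, build_template_bank
from spiralpath.stimulus import make_scene


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    return CameraModel()


@pytest.fixture(scope="session")
def small_bank(camera):
    """A small template bank (5 pattern angles x 5 x 4 CoMs) for fast
    dynamics tests."""
    return build_template_bank(TemplateBankConfig(n_pattern=5, n_x=5, n_y=4), camera)


@pytest.fixture(scope="session")
def ground_scene(camera):
    return make_scene("ground_plane", 200, (1.4, 25.0), 1.6, seed=11, camera=camera)


@pytest.fixture()
def params() -> ModelParams:
    return ModelParams()


def fd_projection_oracle(dot, position_fn, yaw_fn, t, camera, dt=1e-4):
    """Finite-difference flow oracle: re-project one world dot at t +/- dt/2
    under the continuous pose functions and difference the image positions.

    Returns (xy, uv) at time t.  Independent of the analytic flow path.
    """
    def project(tt):
        pos = position_fn(tt)
        phi = yaw_fn(tt)
        s, c = np.sin(phi), np.cos(phi)
        right = np.array([c, 0.0, s])
        up = np.array([0.0, 1.0, 0.0])
        fwd = np.array([-s, 0.0, c])
        rel = np.asarray(dot) - pos
        X, Y, Z = rel @ right, rel @ up, rel @ fwd
        return np.array([camera.focal_length * X / Z, camera.focal_length * Y / Z])

    p0 = project(t - dt / 2.0)
    p1 = project(t + dt / 2.0)
    return project(t), (p1 - p0) / dt
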