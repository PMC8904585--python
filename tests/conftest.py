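import numpy as np
import pytest
from hypothesis import settings

import choromel as cm
from choromel import polarimetry as P

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def demo_phantom():
    """One reduced-grid phantom shared across the suite (seed fixed)."""
    spec = cm.demo_spec(seed=1)
    jones, gt = cm.make_phantom(spec)
    return spec, jones, gt


@pytest.fixture(scope="session")
def demo_dopu(demo_phantom):
    spec, jones, gt = demo_phantom
    stokes = P.jones_to_stokes(jones)
    noise = P.estimate_noise(jones)
    dopu = P.compute_dopu(stokes, noise=noise)
    return stokes, noise, dopu


@pytest.fixture(scope="session")
def eye_result(demo_phantom):
    spec, jones, gt = demo_phantom
    cfg = cm.RunConfig(eye_id="demo", seed=1)
    return cm.run_eye(cfg, volume=jones)


def uniform_block(state=(1.0, 0.0), shape=(16, 16, 8), power=None, seed=None):
    """A volume in a single pure polarization state.

    With ``power`` None the amplitude is constant 1; otherwise fully
    developed speckle of the given mean power is drawn with ``seed``.
    """
    e = np.asarray(state, dtype=np.complex128)
    e = e / np.linalg.norm(e)
    if power is None:
        amp = np.ones(shape, dtype=np.complex128)
    else:
        rng = np.random.default_rng(seed)
        g = rng.standard_normal((2,) + shape)
        amp = (g[0] + 1j * g[1]) * np.sqrt(power / 2.0)
    return cm.JonesVolume(h=amp * e[0], v=amp * e[1], dz=13 / 3, dx=35 / 3, dy=23.4)
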