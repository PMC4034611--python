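import numpy as np
import pytest

import spiroform as sf


@pytest.fixture(scope="session")
def study():
    """One synthetic study at the reference conditions, shared read-only."""
    return sf.simulate_study(seed=1)


@pytest.fixture(scope="session")
def helix_axis():
    """Dextral circular helix a=2, c=1 (kappa=0.4, tau=+0.2) with truth."""
    params = sf.HelicospiralParams(r0=2.0, alpha=0.0, c=1.0, theta_max=3 * np.pi, ds=0.005)
    axis, truth = sf.generate_helicospiral(params)
    return axis, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20140515)


def random_closed_outline(rng, n=64, n_harmonics=4, anterior=None):
    """Smooth random closed 3D curve around a dominant ellipse."""
    t = 2 * np.pi * np.arange(n) / n
    pts = np.zeros((n, 3))
    for k in range(1, n_harmonics + 1):
        amp = rng.normal(scale=1.0 / k**2, size=(3, 2))
        pts += np.outer(np.cos(k * t), amp[:, 0]) + np.outer(np.sin(k * t), amp[:, 1])
    pts[:, 0] += 2.5 * np.cos(t)
    pts[:, 1] += 1.5 * np.sin(t)
    idx = int(rng.integers(n)) if anterior is None else anterior
    return sf.ApertureOutline(points=pts, anterior_index=idx)
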