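import numpy as np
import pytest

from saxskit import ScatteringProfile, synthetic


SPHERE_RG_FACTOR = np.sqrt(3.0 / 5.0)  # Rg of a homogeneous sphere is R*sqrt(3/5)


@pytest.fixture
def q_grid():
    return np.linspace(0.005, 0.25, 400)


@pytest.fixture
def sphere30(q_grid):
    """Noiseless sphere, R = 30 A, I(0) = 100."""
    return synthetic.sphere_profile(30.0, 100.0, q_grid)


@pytest.fixture
def simple_profile():
    q = np.linspace(0.01, 0.1, 10)
    return ScatteringProfile("p", q, 10.0 + q, np.ones_like(q))


def make_guinier_profile(rg=20.0, i0=100.0, qmin=0.001, qmax=0.15, n=200, name="guinier"):
    q = np.linspace(qmin, qmax, n)
    return ScatteringProfile(name, q, i0 * np.exp(-(q**2) * rg**2 / 3.0),
                             np.zeros_like(q))


def make_overlap_series(seed=7, n_frames=100, noise=0.01):
    """Two overlapping Gaussian elutions (spheres R=20 and R=35, centers
    40 and 55, width 8) over a flat buffer; returns (frames, truth dict)."""
    q = np.linspace(0.005, 0.25, 200)
    buffer = ScatteringProfile("buf", q, np.full_like(q, 10.0), np.zeros_like(q))
    p1 = synthetic.sphere_profile(20.0, 60.0, q)
    p2 = synthetic.sphere_profile(35.0, 60.0, q)
    comps = [synthetic.ComponentSpec(p1, 40.0, 8.0),
             synthetic.ComponentSpec(p2, 55.0, 8.0)]
    frames = synthetic.simulate_sec(comps, buffer, n_frames, noise=noise,
                                    floor=1e-3, seed=seed)
    return frames, {"q": q, "buffer": buffer, "profiles": [p1, p2],
                    "components": comps}
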