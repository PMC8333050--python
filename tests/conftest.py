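import numpy as np
import pytest

from corrtomo.phantom import generate_phantom
from corrtomo.psf import PSFModel
from corrtomo.simulate import NoiseModel, ShiftLaw, simulate_views


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_psf():
    return PSFModel(1.0, 1.0, 2.0)


@pytest.fixture(scope="session")
def tiny_viewset(small_psf):
    """A fast 3-view acquisition of a smooth bead phantom (32 cube)."""
    phantom = generate_phantom("bead_field", (32, 32, 32), seed=7, margin=10,
                               n_beads=4, min_sep=4)
    return simulate_views(phantom, small_psf, [0.0, 90.0, 180.0],
                          ShiftLaw(max_abs=2), NoiseModel(), seed=11, order=1)


@pytest.fixture(scope="session")
def tiny_phantom():
    return generate_phantom("bead_field", (32, 32, 32), seed=7, margin=10,
                            n_beads=4, min_sep=4)


def brute_correlate_circular(a, b):
    """Direct-sum circular correlation oracle: (a ⋆ b)(ξ) = Σ a(y) b(y+ξ),
    computed lag by lag with explicit rolls (no FFT)."""
    out = np.zeros(a.shape)
    center = tuple(s // 2 for s in a.shape)
    for idx in np.ndindex(a.shape):
        lag = tuple(i - c for i, c in zip(idx, center))
        out[idx] = np.sum(a * np.roll(b, tuple(-l for l in lag),
                                      axis=tuple(range(a.ndim))))
    return out


def brute_convolve_circular(a, b):
    """Direct-sum circular convolution oracle (centered convention)."""
    out = np.zeros(a.shape)
    center = tuple(s // 2 for s in a.shape)
    for idx in np.ndindex(a.shape):
        x = tuple(i - c for i, c in zip(idx, center))
        acc = 0.0
        for ydx in np.ndindex(a.shape):
            y = tuple(i - c for i, c in zip(ydx, center))
            zdx = tuple((xi - yi + c) % s
                        for xi, yi, c, s in zip(x, y, center, a.shape))
            acc += a[ydx] * b[zdx]
        out[idx] = acc
    return out
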