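import numpy as np
import pytest

from saxsdrive.scatter_core import FormFactorTable, ParticleSystem
from saxsdrive.toy_dynamics import build_hjh_toy


@pytest.fixture
def ff_const():
    return FormFactorTable("constant")


@pytest.fixture
def random_system():
    """Factory: seeded random bead system of given size and extent."""

    def make(n, seed=0, scale=5.0):
        rng = np.random.default_rng(seed)
        return ParticleSystem(rng.normal(scale=scale, size=(n, 3)), ["bead"] * n)

    return make


@pytest.fixture
def hjh_model():
    return build_hjh_toy()


def brute_force_orientational_average(coords, f_values, q, n_theta=100,
                                      n_phi=200):
    """Independent oracle: spherical product quadrature of |A(q u)|^2.

    Gauss-Legendre nodes in cos(theta) times a uniform grid in phi — a
    direct numerical average over >= n_theta * n_phi directions sharing
    no code path with the implementation.
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_theta)
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    total = 0.0
    for ct, w in zip(nodes, weights):
        st = np.sqrt(1.0 - ct * ct)
        for phi in phis:
            u = np.array([st * np.cos(phi), st * np.sin(phi), ct])
            amp = np.sum(f_values * np.exp(-1j * q * (coords @ u)))
            total += w * abs(amp) ** 2
    return total / (2.0 * n_phi)
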