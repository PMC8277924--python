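import numpy as np
import pytest

from hydrashell.geometry import ClusterGeometry, WaterMolecule
from hydrashell.ga import random_cluster
from hydrashell.potential import EnergyModel

THETA0 = np.deg2rad(109.47)


def water_at(
    oxygen,
    bisector=None,
    h1_dir=None,
    r_oh: float = 1.0,
    theta: float = THETA0,
) -> WaterMolecule:
    """Water with its dipole along ``bisector`` or one O-H along ``h1_dir``."""
    oxygen = np.asarray(oxygen, dtype=float)
    if h1_dir is not None:
        h1 = np.asarray(h1_dir, dtype=float)
        h1 = h1 / np.linalg.norm(h1)
        perp = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(perp, h1)) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        perp = perp - np.dot(perp, h1) * h1
        perp /= np.linalg.norm(perp)
        h2 = np.cos(theta) * h1 + np.sin(theta) * perp
        return WaterMolecule(oxygen, oxygen + r_oh * np.array([h1, h2]))
    b = np.asarray(bisector, dtype=float)
    b = b / np.linalg.norm(b)
    perp = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(perp, b)) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    perp = perp - np.dot(perp, b) * b
    perp /= np.linalg.norm(perp)
    half = theta / 2.0
    h1 = np.cos(half) * b + np.sin(half) * perp
    h2 = np.cos(half) * b - np.sin(half) * perp
    return WaterMolecule(oxygen, oxygen + r_oh * np.array([h1, h2]))


@pytest.fixture(scope="session")
def model() -> EnergyModel:
    return EnergyModel()


@pytest.fixture
def one_water():
    """Ca2+ with a single outward-oriented water at 5 Å."""
    return ClusterGeometry(
        np.zeros(3), 2, (water_at([5.0, 0.0, 0.0], bisector=[1.0, 0.0, 0.0]),)
    )


@pytest.fixture
def random_clusters():
    """Factory of seeded random valid clusters."""

    def factory(n: int, seed: int = 0, count: int = 1):
        rng = np.random.default_rng(seed)
        out = [random_cluster(n, rng) for _ in range(count)]
        return out[0] if count == 1 else out

    return factory
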