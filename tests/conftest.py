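"""Shared fixtures: density-preserving scaled networks and firing tables.

Scaled networks shrink the ellipsoid with the neuron count so the arbor
density — hence mean overlap (~11), CAC structure and percolation behavior —
matches the full-size (100,000-arbor) system while staying fast.
"""

import numpy as np
import pytest
from hypothesis import settings

from striatum.geometry import (
    ArborNetwork,
    EllipsoidStriatum,
    NetworkConfig,
    generate_striatum,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

FULL_N = 100_000
FULL_AXES = (14.0, 9.0, 9.0)


def scaled_config(n_neurons: int, seed: int = 0, **kwargs) -> NetworkConfig:
    """Config with the default arbor density at a reduced neuron count."""
    scale = (n_neurons / FULL_N) ** (1.0 / 3.0)
    axes = tuple(a * scale for a in FULL_AXES)
    return NetworkConfig(
        n_neurons=n_neurons, ellipsoid=EllipsoidStriatum(axes), seed=seed, **kwargs
    )


def toy_network(centers, radius: float = 0.5) -> ArborNetwork:
    """Hand-placed arbors for exact-geometry tests."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    cfg = NetworkConfig(n_neurons=len(centers), arbor_radius=radius)
    return ArborNetwork(cfg, centers, np.full(len(centers), radius))


@pytest.fixture(scope="session")
def net10k() -> ArborNetwork:
    return generate_striatum(scaled_config(10_000, seed=3))


@pytest.fixture(scope="session")
def net20k() -> ArborNetwork:
    return generate_striatum(scaled_config(20_000, seed=4))


@pytest.fixture(scope="session")
def hh_table_nc():
    """Default HH firing lookup table (no compensation), shared by pipeline
    tests."""
    from striatum.pipeline import build_firing_table

    return build_firing_table("hh", seed=42)
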