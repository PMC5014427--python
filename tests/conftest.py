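"""Shared fixtures: hand-built toy networks and cached generator runs."""

from __future__ import annotations

import numpy as np
import pytest

from mycomorph.network import HyphalNetwork, HyphalNode, Segment
from mycomorph.simulate import GrowthConfig, grow


def build_network(node_positions, edges, time=0.0):
    """Construct a network from {id: (x, y, z)} and [(parent, child)] with
    straight segments, or (parent, child, polyline) for curved ones."""
    nodes = [HyphalNode(i, np.asarray(p, dtype=float)) for i, p in node_positions.items()]
    segments = []
    for e in edges:
        if len(e) == 2:
            p, c = e
            poly = np.vstack([node_positions[p], node_positions[c]]).astype(float)
        else:
            p, c, poly = e
            poly = np.asarray(poly, dtype=float)
        segments.append(Segment(p, c, poly))
    return HyphalNetwork(nodes, segments, time=time)


@pytest.fixture
def straight_hypha():
    """Root -> internal -> tip along +x: segments of 10 and 15 µm."""
    return build_network(
        {0: (0, 0, 0), 1: (10, 0, 0), 2: (25, 0, 0)},
        [(0, 1), (1, 2)],
    )


@pytest.fixture
def y_network():
    """An apical bifurcation: mother along +x, daughters at ±40° in plane."""
    import math
    a = math.radians(40)
    d = 30.0
    return build_network(
        {0: (0, 0, 0), 1: (50, 0, 0),
         2: (50 + d * math.cos(a), d * math.sin(a), 0),
         3: (50 + d * math.cos(a), -d * math.sin(a), 0)},
        [(0, 1), (1, 2), (1, 3)],
    )


@pytest.fixture
def lateral_network():
    """A lateral branch at 90° from a straight mother."""
    return build_network(
        {0: (0, 0, 0), 1: (50, 0, 0), 2: (100, 0, 0), 3: (50, 40, 0)},
        [(0, 1), (1, 2), (1, 3)],
    )


@pytest.fixture(scope="session")
def small_colony():
    """A branched exponential-phase colony with its event log (seed 7)."""
    cfg = GrowthConfig(seed=7, n_initial_hyphae=20, duration_hours=48,
                       snapshot_hours=(24, 48), lag_hours=0, max_tips=400)
    return grow(cfg)


@pytest.fixture(scope="session")
def clean_colony():
    """Noise-free, tilt-free colony: measured angles equal sampled ones."""
    cfg = GrowthConfig(seed=11, n_initial_hyphae=10, duration_hours=48,
                       snapshot_hours=(48,), lag_hours=0, max_tips=250,
                       tilt_sd_deg=0.0, direction_noise_sd_deg=0.0)
    return grow(cfg)
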