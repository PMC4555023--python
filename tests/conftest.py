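import numpy as np
import pytest

from h2sync import DEFAULT_CONFIG, RegionRole
from h2sync.h2core import DirectedEdgeEstimate, Direction
from h2sync.graphnet import WindowGraph


@pytest.fixture
def cfg():
    return DEFAULT_CONFIG


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_graph(t_center, edge_spec, roles):
    """Build a WindowGraph from (source, target, h2, direction) tuples.

    direction: '>' source->target, '<' target->source, '0' undirected.
    """
    edges = []
    for a, b, h2, d in edge_spec:
        direction = {
            ">": Direction.X_TO_Y,
            "<": Direction.Y_TO_X,
            "0": Direction.UNDIRECTED,
        }[d]
        delay = 0.0 if d == "0" else (0.01 if d == ">" else -0.01)
        edges.append(
            DirectedEdgeEstimate(pair=(a, b), h2=h2, delay_s=delay, direction=direction)
        )
    return WindowGraph(t_center=t_center, edges=edges, available_roles=list(roles))
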