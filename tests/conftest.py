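import numpy as np
import pytest

from mvflow.network import VascularNetwork


def make_net(nodes, segments) -> VascularNetwork:
    """Build a validated network from plain tuples.

    nodes: (id, x, y, z, category, is_boundary)
    segments: (id, node_from, node_to, diameter_um, length_um, category)
    """
    net = VascularNetwork(
        node_ids=np.array([n[0] for n in nodes], dtype=int),
        positions=np.array([[n[1], n[2], n[3]] for n in nodes], dtype=float),
        node_categories=np.array([n[4] for n in nodes], dtype=object),
        is_boundary=np.array([n[5] for n in nodes], dtype=bool),
        seg_ids=np.array([s[0] for s in segments], dtype=int),
        seg_start=np.array([{n[0]: k for k, n in enumerate(nodes)}[s[1]] for s in segments], dtype=int),
        seg_end=np.array([{n[0]: k for k, n in enumerate(nodes)}[s[2]] for s in segments], dtype=int),
        diameters=np.array([s[3] for s in segments], dtype=float),
        lengths=np.array([s[4] for s in segments], dtype=float),
        seg_categories=np.array([s[5] for s in segments], dtype=object),
    )
    net.validate()
    return net


@pytest.fixture
def chain4():
    """b1 - a - b - c - b2: four segments, boundary ends."""
    nodes = [
        (0, 0, 0, 0, "C", True),
        (1, 100, 0, 0, "C", False),
        (2, 200, 0, 0, "C", False),
        (3, 300, 0, 0, "C", False),
        (4, 400, 0, 0, "C", True),
    ]
    segs = [
        (0, 0, 1, 5.0, 100.0, "C"),
        (1, 1, 2, 5.0, 100.0, "C"),
        (2, 2, 3, 5.0, 100.0, "C"),
        (3, 3, 4, 5.0, 100.0, "C"),
    ]
    return make_net(nodes, segs)


@pytest.fixture
def two_segment_series():
    """Two identical segments in series between two boundary nodes."""
    nodes = [
        (0, 0, 0, 0, "C", True),
        (1, 100, 0, 0, "C", False),
        (2, 200, 0, 0, "C", True),
    ]
    segs = [
        (0, 0, 1, 8.0, 100.0, "C"),
        (1, 1, 2, 8.0, 100.0, "C"),
    ]
    return make_net(nodes, segs)


@pytest.fixture
def y_junction():
    """Three identical segments meeting at one interior node."""
    nodes = [
        (0, 0, 0, 0, "C", True),
        (1, 100, 0, 0, "C", True),
        (2, 0, 100, 0, "C", True),
        (3, 50, 50, 0, "C", False),
    ]
    segs = [
        (0, 0, 3, 8.0, 100.0, "C"),
        (1, 1, 3, 8.0, 100.0, "C"),
        (2, 2, 3, 8.0, 100.0, "C"),
    ]
    return make_net(nodes, segs)
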