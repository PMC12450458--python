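"""Vascular network data model, file I/O, and topological annotations.

A network is a graph of nodes (with 3-D positions in micrometres, the z axis
being cortical depth increasing downward from the pial surface at z = 0) and
vessel segments (with diameter, length, and a vessel category).  Boundary
nodes are degree-1 nodes where a vessel was cut by the domain boundary; they
are the nodes at which boundary conditions must be imposed.

Topological annotations implemented here:

* segment *generation* -- an iterative boundary-set expansion metric: starting
  from the set of all boundary nodes, nodes reachable along incident segments
  are repeatedly merged in, and a segment is assigned generation k when both
  of its end-nodes are first contained in the merged set at iteration k;
* *analysis layers* (ALs) -- 200-um cortical-depth bins assigned from the mean
  endpoint depth of each segment;
* *reference groups* -- per-layer sets of interior capillary nodes (endpoints
  of capillary segments with generation >= 2) used to anchor relative
  (adaptive) pressure boundary conditions.  The deepest layer reuses the
  layer-5 group, which in real cortical meshes contains too few candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The six vessel categories: surface arterioles, descending arterioles and
#: arterioles, capillaries, ascending venules and venules, surface venules,
#: and vessels of unknown type.
CATEGORIES = ("SA", "DA+A", "C", "AV+V", "SV", "UNK")

ARTERIOLE_CATEGORIES = ("SA", "DA+A")
VENULE_CATEGORIES = ("AV+V", "SV")

NODE_COLUMNS = ["id", "x", "y", "z", "category", "is_boundary"]
SEGMENT_COLUMNS = ["id", "node_from", "node_to", "diameter_um", "length_um", "category"]


class NetworkValidationError(ValueError):
    """Raised when a network (or its on-disk representation) is inconsistent."""


@dataclass
class Node:
    id: int
    position: tuple[float, float, float]
    category: str
    is_boundary: bool


@dataclass
class Segment:
    id: int
    start_node: int
    end_node: int
    diameter: float  # um
    length: float  # um
    category: str


@dataclass
class VascularNetwork:
    """Column-oriented vascular graph.

    Nodes and segments are stored as parallel numpy arrays; ``node_index`` /
    ``segment_index`` map external integer ids to array positions.  The flow
    sign convention is positive from ``seg_start`` to ``seg_end``.
    """

    node_ids: np.ndarray  # (n,) int
    positions: np.ndarray  # (n, 3) float, um
    node_categories: np.ndarray  # (n,) str
    is_boundary: np.ndarray  # (n,) bool
    seg_ids: np.ndarray  # (m,) int
    seg_start: np.ndarray  # (m,) int, node array index
    seg_end: np.ndarray  # (m,) int, node array index
    diameters: np.ndarray  # (m,) float, um
    lengths: np.ndarray  # (m,) float, um
    seg_categories: np.ndarray  # (m,) str

    node_index: dict[int, int] = field(default_factory=dict, repr=False)
    segment_index: dict[int, int] = field(default_factory=dict, repr=False)
    _incident: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.node_index:
            self.node_index = {int(i): k for k, i in enumerate(self.node_ids)}
        if not self.segment_index:
            self.segment_index = {int(i): k for k, i in enumerate(self.seg_ids)}

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def m(self) -> int:
        return len(self.seg_ids)

    def incident_segments(self, node_pos: int) -> np.ndarray:
        """Array positions of segments incident to node array position."""
        if self._incident is None:
            inc: list[list[int]] = [[] for _ in range(self.n)]
            for j in range(self.m):
                inc[self.seg_start[j]].append(j)
                inc[self.seg_end[j]].append(j)
            self._incident = [np.asarray(a, dtype=int) for a in inc]
        return self._incident[node_pos]

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        np.add.at(deg, self.seg_start, 1)
        np.add.at(deg, self.seg_end, 1)
        return deg

    def validate(self) -> None:
        """Check all structural invariants; raise NetworkValidationError."""
        if len(np.unique(self.node_ids)) != self.n:
            raise NetworkValidationError("duplicate node ids")
        if len(np.unique(self.seg_ids)) != self.m:
            raise NetworkValidationError("duplicate segment ids")
        for name, arr in (("node", self.node_categories), ("segment", self.seg_categories)):
            bad = set(arr) - set(CATEGORIES)
            if bad:
                raise NetworkValidationError(f"unknown {name} categories: {sorted(bad)}")
        if np.any(self.seg_start == self.seg_end):
            j = int(np.argmax(self.seg_start == self.seg_end))
            raise NetworkValidationError(f"segment id {self.seg_ids[j]} is a self-loop")
        if np.any(self.diameters <= 0):
            j = int(np.argmax(self.diameters <= 0))
            raise NetworkValidationError(
                f"segment id {self.seg_ids[j]} has nonpositive diameter {self.diameters[j]}"
            )
        if np.any(self.lengths <= 0):
            j = int(np.argmax(self.lengths <= 0))
            raise NetworkValidationError(
                f"segment id {self.seg_ids[j]} has nonpositive length {self.lengths[j]}"
            )
        deg = self.degrees
        bad_bnd = self.is_boundary & (deg != 1)
        if np.any(bad_bnd):
            k = int(np.argmax(bad_bnd))
            raise NetworkValidationError(
                f"boundary node id {self.node_ids[k]} has degree {deg[k]} (must be 1)"
            )
        # every connected component must contain a boundary node
        comp = self._components()
        has_boundary = np.zeros(comp.max() + 1, dtype=bool)
        np.logical_or.at(has_boundary, comp, self.is_boundary)
        if not has_boundary.all():
            c = int(np.argmax(~has_boundary))
            example = self.node_ids[comp == c][0]
            raise NetworkValidationError(
                f"connected component containing node id {example} has no boundary node"
            )

    def _components(self) -> np.ndarray:
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        adj = coo_matrix(
            (np.ones(self.m), (self.seg_start, self.seg_end)), shape=(self.n, self.n)
        )
        _, labels = connected_components(adj, directed=False)
        return labels

    # -- convenience accessors ------------------------------------------------

    def node_positions_of_segment(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        return self.positions[self.seg_start[j]], self.positions[self.seg_end[j]]

    def boundary_node_positions(self) -> np.ndarray:
        return np.flatnonzero(self.is_boundary)


def from_frames(nodes: pd.DataFrame, segments: pd.DataFrame) -> VascularNetwork:
    """Build a validated network from node/segment tables (documented schema)."""
    for col in NODE_COLUMNS:
        if col not in nodes.columns:
            raise NetworkValidationError(f"node table missing column '{col}'")
    for col in SEGMENT_COLUMNS:
        if col not in segments.columns:
            raise NetworkValidationError(f"segment table missing column '{col}'")
    node_ids = nodes["id"].to_numpy(dtype=int)
    index = {int(i): k for k, i in enumerate(node_ids)}
    for col in ("node_from", "node_to"):
        for sid, nid in zip(segments["id"], segments[col]):
            if int(nid) not in index:
                raise NetworkValidationError(
                    f"segment id {sid}: {col} references absent node id {nid}"
                )
    net = VascularNetwork(
        node_ids=node_ids,
        positions=nodes[["x", "y", "z"]].to_numpy(dtype=float),
        node_categories=nodes["category"].to_numpy(dtype=object),
        is_boundary=nodes["is_boundary"].to_numpy(dtype=bool),
        seg_ids=segments["id"].to_numpy(dtype=int),
        seg_start=np.array([index[int(i)] for i in segments["node_from"]], dtype=int),
        seg_end=np.array([index[int(i)] for i in segments["node_to"]], dtype=int),
        diameters=segments["diameter_um"].to_numpy(dtype=float),
        lengths=segments["length_um"].to_numpy(dtype=float),
        seg_categories=segments["category"].to_numpy(dtype=object),
        node_index=index,
    )
    net.validate()
    return net


def to_frames(net: VascularNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = pd.DataFrame(
        {
            "id": net.node_ids,
            "x": net.positions[:, 0],
            "y": net.positions[:, 1],
            "z": net.positions[:, 2],
            "category": net.node_categories,
            "is_boundary": net.is_boundary.astype(int),
        }
    )
    segments = pd.DataFrame(
        {
            "id": net.seg_ids,
            "node_from": net.node_ids[net.seg_start],
            "node_to": net.node_ids[net.seg_end],
            "diameter_um": net.diameters,
            "length_um": net.lengths,
            "category": net.seg_categories,
        }
    )
    return nodes, segments


def read_network(path: str | Path, format: str | None = None) -> VascularNetwork:
    """Read a network from a CSV pair or a single JSON document.

    ``path`` for the CSV pair is the stem: ``<stem>_nodes.csv`` and
    ``<stem>_segments.csv`` must both exist.  JSON holds two arrays of
    records under keys ``"nodes"`` and ``"segments"`` with the same fields.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv-pair"
    if format == "json":
        with open(path) as fh:
            doc = json.load(fh)
        nodes = pd.DataFrame(doc["nodes"])
        segments = pd.DataFrame(doc["segments"])
    elif format == "csv-pair":
        nodes_path = path.parent / f"{path.name}_nodes.csv"
        seg_path = path.parent / f"{path.name}_segments.csv"
        for p in (nodes_path, seg_path):
            if not p.exists():
                raise FileNotFoundError(p)
        nodes = pd.read_csv(nodes_path)
        segments = pd.read_csv(seg_path)
    else:
        raise ValueError(f"unknown format {format!r}")
    nodes["is_boundary"] = nodes["is_boundary"].astype(bool)
    return from_frames(nodes, segments)


def write_network(net: VascularNetwork, path: str | Path, format: str | None = None) -> None:
    """Write as CSV pair (``<stem>_nodes.csv`` + ``<stem>_segments.csv``) or JSON."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv-pair"
    nodes, segments = to_frames(net)
    if format == "json":
        doc = {
            "nodes": nodes.to_dict(orient="records"),
            "segments": segments.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    elif format == "csv-pair":
        nodes.to_csv(path.parent / f"{path.name}_nodes.csv", index=False)
        segments.to_csv(path.parent / f"{path.name}_segments.csv", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def to_graphml(net: VascularNetwork, path: str | Path) -> None:
    """Export with node/edge attributes preserved, for visualization tools."""
    import networkx as nx

    g = nx.Graph()
    for k in range(net.n):
        g.add_node(
            int(net.node_ids[k]),
            x=float(net.positions[k, 0]),
            y=float(net.positions[k, 1]),
            z=float(net.positions[k, 2]),
            category=str(net.node_categories[k]),
            is_boundary=bool(net.is_boundary[k]),
        )
    for j in range(net.m):
        g.add_edge(
            int(net.node_ids[net.seg_start[j]]),
            int(net.node_ids[net.seg_end[j]]),
            id=int(net.seg_ids[j]),
            diameter_um=float(net.diameters[j]),
            length_um=float(net.lengths[j]),
            category=str(net.seg_categories[j]),
        )
    nx.write_graphml(g, str(path))


def compute_segment_generations(net: VascularNetwork) -> np.ndarray:
    """Segment generation by iterative boundary-set expansion.

    Start from the set of all boundary nodes.  At each iteration, add every
    node reachable along segments incident to the current set; unassigned
    segments whose two end-nodes are both contained in the merged set receive
    the current iteration number as their generation (>= 1).
    """
    if not net.is_boundary.any():
        raise NetworkValidationError("network has no boundary nodes; generations undefined")
    in_set = net.is_boundary.copy()
    generation = np.zeros(net.m, dtype=int)
    unassigned = np.ones(net.m, dtype=bool)
    k = 0
    while unassigned.any():
        k += 1
        # nodes reachable along segments incident to the current set
        touch = in_set[net.seg_start] | in_set[net.seg_end]
        new_set = in_set.copy()
        new_set[net.seg_start[touch]] = True
        new_set[net.seg_end[touch]] = True
        both_in = new_set[net.seg_start] & new_set[net.seg_end] & unassigned
        if not both_in.any() and not (new_set & ~in_set).any():
            # disconnected remainder would loop forever; validate() prevents
            # this, but guard against direct misuse
            raise NetworkValidationError(
                "segments unreachable from any boundary node; generations undefined"
            )
        generation[both_in] = k
        unassigned &= ~both_in
        in_set = new_set
    return generation


def assign_analysis_layers(
    net: VascularNetwork, thickness: float = 200.0, n_layers: int = 6
) -> np.ndarray:
    """Analysis layer per segment from mean endpoint depth.

    Layer ell covers depths [(ell-1)*thickness, ell*thickness), ell = 1..n_layers,
    with the deepest layer closed above (depths beyond the last boundary clip
    to n_layers).
    """
    z = net.positions[:, 2]
    if np.any(z < 0):
        k = int(np.argmax(z < 0))
        raise NetworkValidationError(
            f"node id {net.node_ids[k]} has negative depth z = {z[k]}"
        )
    mean_depth = 0.5 * (z[net.seg_start] + z[net.seg_end])
    layer = 1 + np.floor(mean_depth / thickness).astype(int)
    return np.clip(layer, 1, n_layers)


def select_reference_groups(
    net: VascularNetwork,
    generations: np.ndarray | None = None,
    layers: np.ndarray | None = None,
    min_generation: int = 2,
    n_layers: int = 6,
) -> dict[int, np.ndarray]:
    """Interior capillary reference-node groups per analysis layer.

    For layers 1..n_layers-1 the group is the set of interior nodes that are
    end-nodes of capillary segments in that layer with generation >=
    ``min_generation``.  The deepest layer aliases the group of layer
    n_layers-1 (it typically contains too few interior capillary candidates).
    Returns a dict layer -> sorted array of node array-positions.
    """
    if generations is None:
        generations = compute_segment_generations(net)
    if layers is None:
        layers = assign_analysis_layers(net, n_layers=n_layers)
    groups: dict[int, np.ndarray] = {}
    eligible = (net.seg_categories == "C") & (generations >= min_generation)
    for ell in range(1, n_layers):
        segs = np.flatnonzero(eligible & (layers == ell))
        members = np.unique(np.concatenate([net.seg_start[segs], net.seg_end[segs]]))\
            if len(segs) else np.array([], dtype=int)
        members = members[~net.is_boundary[members]]
        if len(members) == 0:
            raise NetworkValidationError(
                f"analysis layer {ell} has no eligible interior capillary reference "
                f"nodes; use a denser network or lower min_generation"
            )
        groups[ell] = members
    groups[n_layers] = groups[n_layers - 1]
    return groups
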