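"""Seeded generator of cortical-like synthetic vascular networks.

The generator emulates the structural features of cortical penetrating-
vessel networks at desk scale: a capillary lattice spanning six 200-um
analysis layers down to 1.2 mm below the pial surface, penetrating
arteriole and venule trunks entering at the pial surface (tapering with
depth, venules wider than arterioles), boundary nodes on the lateral and
bottom faces but not on the pial face (except the vessel trunk ends), and
capillary-dominated segment counts.  Diameter conventions: capillaries ~
Normal(4, 1) um truncated above 2 um; arterioles taper 25 -> 10 um from the
pial surface to full depth (inside the < 30 um range covered by awake-mouse
velocity measurements, so surface vessels are eligible velocity-target
sites); venules are 1.15x the arteriole diameter.  The capillary bed is an
irregular seeded spanning structure plus a fraction of loop-closing edges;
a fully regular symmetric lattice (loop fraction 1) is available but is the
canonical configuration in which the coupled flow/phase-separation model
sustains limit cycles instead of a steady state.  These are fixture
conventions with plausible cortical values, not morphometric claims.

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mvflow.network import (
    VascularNetwork,
    assign_analysis_layers,
    compute_segment_generations,
    select_reference_groups,
)
from mvflow.solver import BoundaryCondition, ReferenceGroup, groups_from_layers


@dataclass
class SynthSpec:
    nx: int = 7
    ny: int = 7
    nz: int = 6
    depth_um: float = 1200.0
    lateral_spacing_um: float = 100.0
    capillary_diameter_mean: float = 4.0
    capillary_diameter_sd: float = 1.0
    capillary_diameter_min: float = 2.0
    n_arterioles: int = 2
    n_venules: int = 2
    arteriole_surface_diameter: float = 25.0
    arteriole_deep_diameter: float = 10.0
    venule_diameter_scale: float = 1.15
    capillary_loop_fraction: float = 0.2
    boundary_stub_fraction: float = 1.0
    unk_fraction: float = 0.2
    stub_length_um: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny) < 5 or self.nz < 2:
            raise ValueError(
                "lattice too small: need nx, ny >= 5 and nz >= 2 to place "
                "interior trunks and reference nodes"
            )
        if self.n_arterioles < 1 or self.n_venules < 1:
            raise ValueError("need at least one arteriole and one venule trunk")


def _trunk_columns(spec: SynthSpec) -> tuple[list, list]:
    """Deterministic interior (ix, iy) columns for arteriole/venule trunks."""
    interior = [
        (ix, iy)
        for ix in range(1, spec.nx - 1)
        for iy in range(1, spec.ny - 1)
    ]
    k = spec.n_arterioles + spec.n_venules
    if k > len(interior):
        raise ValueError("lattice too small to place the requested trunks")
    idx = np.linspace(0, len(interior) - 1, k).astype(int)
    cols = [interior[i] for i in idx]
    return cols[: spec.n_arterioles], cols[spec.n_arterioles:]


def generate_network(spec: SynthSpec) -> VascularNetwork:
    rng = np.random.default_rng(spec.seed)
    dz = spec.depth_um / spec.nz
    a = spec.lateral_spacing_um
    art_cols, ven_cols = _trunk_columns(spec)
    trunk_cols = set(art_cols) | set(ven_cols)

    def cap_diam(size=None):
        d = rng.normal(spec.capillary_diameter_mean, spec.capillary_diameter_sd, size)
        return np.maximum(d, spec.capillary_diameter_min)

    def art_diam(z):
        f = z / spec.depth_um
        return spec.arteriole_surface_diameter + f * (
            spec.arteriole_deep_diameter - spec.arteriole_surface_diameter
        )

    nodes: list[tuple[float, float, float, str, bool]] = []
    node_of: dict[tuple[int, int, int], int] = {}
    for iz in range(spec.nz):
        z = dz * (iz + 0.5)
        for ix in range(spec.nx):
            for iy in range(spec.ny):
                col = (ix, iy)
                cat = "DA+A" if col in art_cols else ("AV+V" if col in ven_cols else "C")
                node_of[(ix, iy, iz)] = len(nodes)
                nodes.append((ix * a, iy * a, z, cat, False))

    segs: list[tuple[int, int, float, float, str]] = []

    def add_seg(i, k, diameter, length, cat):
        segs.append((i, k, float(diameter), float(length), cat))

    # trunk vertical segments (always kept)
    for ix in range(spec.nx):
        for iy in range(spec.ny):
            col = (ix, iy)
            if col not in trunk_cols:
                continue
            for iz in range(spec.nz - 1):
                i, k = node_of[(ix, iy, iz)], node_of[(ix, iy, iz + 1)]
                zmid = dz * (iz + 1)
                if col in art_cols:
                    add_seg(i, k, art_diam(zmid), dz, "DA+A")
                else:
                    add_seg(i, k, art_diam(zmid) * spec.venule_diameter_scale, dz, "AV+V")

    # candidate capillary edges: an irregular bed is built from a seeded
    # random spanning structure over the lattice plus a fraction of the
    # remaining candidate edges; the fully regular lattice (loop fraction 1)
    # is the symmetric configuration in which the coupled phase-separation
    # fixed point is known to admit sustained oscillations
    candidates: list[tuple[int, int, float]] = []
    for ix in range(spec.nx):
        for iy in range(spec.ny):
            if (ix, iy) not in trunk_cols:
                for iz in range(spec.nz - 1):
                    candidates.append((node_of[(ix, iy, iz)], node_of[(ix, iy, iz + 1)], dz))
    for iz in range(spec.nz):
        for ix in range(spec.nx):
            for iy in range(spec.ny):
                if ix + 1 < spec.nx:
                    candidates.append((node_of[(ix, iy, iz)], node_of[(ix + 1, iy, iz)], a))
                if iy + 1 < spec.ny:
                    candidates.append((node_of[(ix, iy, iz)], node_of[(ix, iy + 1, iz)], a))

    parent = list(range(len(nodes) + len(candidates) + 64))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> bool:
        rx, ry = find(x), find(y)
        if rx == ry:
            return False
        parent[rx] = ry
        return True

    for i, k, *_ in segs:
        union(i, k)
    extras: list[tuple[int, int, float]] = []
    order = rng.permutation(len(candidates))
    for idx in order:
        i, k, length = candidates[idx]
        if union(i, k):
            add_seg(i, k, cap_diam(), length, "C")
        else:
            extras.append((i, k, length))
    for i, k, length in extras:
        if rng.random() < spec.capillary_loop_fraction:
            add_seg(i, k, cap_diam(), length, "C")

    # pial trunk ends: SA / SV boundary nodes at z = 0
    for cols, cat, scale in ((art_cols, "SA", 1.0), (ven_cols, "SV", spec.venule_diameter_scale)):
        for (ix, iy) in cols:
            top = node_of[(ix, iy, 0)]
            nodes.append((ix * a, iy * a, 0.0, cat, True))
            add_seg(len(nodes) - 1, top, art_diam(0.0) * scale, dz / 2.0, cat)

    # boundary stubs on lateral and bottom faces (not on trunk columns)
    for (ix, iy, iz), i in sorted(node_of.items()):
        if (ix, iy) in trunk_cols:
            continue
        lateral = ix in (0, spec.nx - 1) or iy in (0, spec.ny - 1)
        bottom = iz == spec.nz - 1
        if not (lateral or bottom):
            continue
        if rng.random() > spec.boundary_stub_fraction:
            continue
        x, y, z = ix * a, iy * a, dz * (iz + 0.5)
        if ix == 0:
            x -= spec.stub_length_um
        elif ix == spec.nx - 1:
            x += spec.stub_length_um
        elif iy == 0:
            y -= spec.stub_length_um
        elif iy == spec.ny - 1:
            y += spec.stub_length_um
        else:  # bottom-face interior column
            z += spec.stub_length_um
        cat = "UNK" if rng.random() < spec.unk_fraction else "C"
        nodes.append((x, y, z, cat, True))
        add_seg(len(nodes) - 1, i, cap_diam(), spec.stub_length_um, cat)

    pos = np.array([(x, y, z) for x, y, z, _, _ in nodes])
    net = VascularNetwork(
        node_ids=np.arange(len(nodes)),
        positions=pos,
        node_categories=np.array([c for _, _, _, c, _ in nodes], dtype=object),
        is_boundary=np.array([b for _, _, _, _, b in nodes]),
        seg_ids=np.arange(len(segs)),
        seg_start=np.array([s[0] for s in segs]),
        seg_end=np.array([s[1] for s in segs]),
        diameters=np.array([s[2] for s in segs]),
        lengths=np.array([s[3] for s in segs]),
        seg_categories=np.array([s[4] for s in segs], dtype=object),
    )
    net.validate()
    return net


def sample_relative_bcs(boundary_node_ids, sd: float = 4.0, seed: int = 0) -> dict[int, float]:
    """I.i.d. zero-mean Gaussian pressure deviations (mmHg) per boundary node."""
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(seed)
    ids = np.asarray(boundary_node_ids, dtype=int)
    draws = rng.normal(0.0, sd, size=len(ids)) if sd > 0 else np.zeros(len(ids))
    return {int(i): float(v) for i, v in zip(ids, draws)}


#: plausible class-wise boundary-pressure ranges (mmHg) for fixtures
PRESSURE_RANGES = {
    "SA": (50.0, 70.0),
    "DA+A": (40.0, 60.0),
    "AV+V": (10.0, 25.0),
    "SV": (8.0, 20.0),
}
RELATIVE_RANGE = (-12.0, 12.0)


def boundary_layers(net: VascularNetwork, layers: np.ndarray | None = None) -> dict[int, int]:
    """Analysis layer of each boundary node (layer of its single segment)."""
    if layers is None:
        layers = assign_analysis_layers(net)
    out = {}
    for i in np.flatnonzero(net.is_boundary):
        j = net.incident_segments(int(i))[0]
        out[int(net.node_ids[i])] = int(layers[j])
    return out


def standard_bcs(
    net: VascularNetwork,
    pressures: dict[int, float],
    deviations: dict[int, float],
    groups: dict[int, ReferenceGroup] | None = None,
    layers: np.ndarray | None = None,
) -> tuple[list[BoundaryCondition], dict[int, ReferenceGroup]]:
    """Experiment-style conditions: conventional pressures at arteriole and
    venule boundary nodes, relative (adaptive) conditions at capillary and
    UNK boundary nodes, referenced to the layer-wise capillary groups."""
    if groups is None:
        groups = groups_from_layers(net, select_reference_groups(net))
    blayers = boundary_layers(net, layers)
    bcs = []
    for i in np.flatnonzero(net.is_boundary):
        nid = int(net.node_ids[i])
        cat = net.node_categories[i]
        if cat in ("C", "UNK"):
            bcs.append(BoundaryCondition(nid, "relative_pressure",
                                         deviations.get(nid, 0.0),
                                         reference=blayers[nid]))
        else:
            bcs.append(BoundaryCondition(nid, "pressure", pressures[nid]))
    return bcs, groups


def calibration_fixture(seed: int = 0):
    """Seeded recovery fixture: a network with ~60 unknown boundary pressures
    plus the truth, priors, boundary-condition template, reference groups,
    and noise-free targets generated from that truth.

    Returns (net, parameter_nodes, truth, priors, bcs, groups, targets).
    """
    spec = SynthSpec(nx=5, ny=5, nz=6, seed=seed, boundary_stub_fraction=0.5)
    net = generate_network(spec)
    pn, truth, priors, bcs, groups, targets = make_truth_and_targets(net, seed=seed + 1)
    return net, pn, truth, priors, bcs, groups, targets


def make_truth_and_targets(
    net: VascularNetwork,
    seed: int = 0,
    velocity_noise_sd: float = 0.0,
    uniform_hd: float = 0.40,
):
    """Ground-truth boundary pressures and the targets they generate.

    Conventional pressures are drawn from class-wise Beta(2, 2) priors over
    plausible ranges; relative deviations from a Beta(2, 2) prior centered at
    zero.  A forward solve at the truth yields RBC-velocity targets for the
    arteriole/venule segments eligible under the < 30 um / layer-1 filter
    and direction targets (signs of the true flows) for all arteriole and
    venule segments.  Returns (parameter_nodes, truth, priors, bcs, groups,
    targets).
    """
    from mvflow.calibrate import CalibrationTarget, LinearForwardModel, PriorSpec
    from mvflow.network import ARTERIOLE_CATEGORIES, VENULE_CATEGORIES

    rng = np.random.default_rng(seed)
    groups = groups_from_layers(net, select_reference_groups(net))
    boundary = np.flatnonzero(net.is_boundary)
    parameter_nodes = [int(net.node_ids[i]) for i in boundary]
    lower, upper = [], []
    for i in boundary:
        cat = net.node_categories[i]
        lo, hi = RELATIVE_RANGE if cat in ("C", "UNK") else PRESSURE_RANGES[cat]
        lower.append(lo)
        upper.append(hi)
    priors = PriorSpec(np.array(lower), np.array(upper), 2.0, 2.0)
    truth = priors.sample(1, rng)[0]

    pressures, deviations = {}, {}
    for nid, i, val in zip(parameter_nodes, boundary, truth):
        if net.node_categories[i] in ("C", "UNK"):
            deviations[nid] = float(val)
        else:
            pressures[nid] = float(val)
    bcs, groups = standard_bcs(net, pressures, deviations, groups)

    layers = assign_analysis_layers(net)
    probe = LinearForwardModel(
        net, bcs, groups, parameter_nodes,
        targets=[], uniform_hd=uniform_hd,
    )
    flows = probe.flows(truth)
    d = net.diameters
    from mvflow.rheology import tube_hematocrit

    bulk = 4.0 * flows / (np.pi * d**2) / 1e3
    ht = tube_hematocrit(d, uniform_hd)
    rbc_v = bulk * np.where(ht > 0, uniform_hd / ht, 1.0)

    targets: list[CalibrationTarget] = []
    art = np.isin(net.seg_categories, ARTERIOLE_CATEGORIES)
    ven = np.isin(net.seg_categories, VENULE_CATEGORIES)
    eligible = (d < 30.0) & (layers == 1) & (art | ven)
    for j in np.flatnonzero(eligible):
        v = abs(rbc_v[j])
        if velocity_noise_sd > 0:
            v = abs(v + rng.normal(0.0, velocity_noise_sd))
        if v > 0:
            targets.append(CalibrationTarget(int(net.seg_ids[j]), "velocity", float(v)))
    for j in np.flatnonzero(art | ven):
        s = np.sign(flows[j])
        if s != 0:
            targets.append(CalibrationTarget(int(net.seg_ids[j]), "direction", int(s)))
    return parameter_nodes, truth, priors, bcs, groups, targets
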