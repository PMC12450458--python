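"""Sparse Poiseuille solver with conventional and adaptive pressure BCs.

The steady-state model is q = M p (segment flows from node pressures through
hydraulic conductances) closed by mass conservation at interior nodes and
boundary conditions at the degree-1 boundary nodes, yielding the sparse
linear system

    K p = R b,      K = L M + J + N,

where L encodes segment connectivity at interior (and flow-BC) nodes, J has
unit diagonal entries at pressure- and relative-pressure-BC nodes, and N
carries the reference-node weights of relative (adaptive) conditions: for a
boundary node i with a relative condition referencing interior nodes s with
normalized weights w_s, the row reads  p_i - sum_s w_s p_s = dp_i, i.e.
N[i, s] = -w_s and b[i] = dp_i.  R is the identity in the ungrouped
encoding; the grouped (sparsity-preserving) encoding modifies N and R so
that the dense reference row appears once per group (see
``apply_grouped_encoding``).

At least one conventional pressure condition is required per connected
component; otherwise pressures are determined only up to a constant.

Internal units: um, mmHg, cP, s; flows in um^3/s; velocities reported in
mm/s and wall shear stress in dyn/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from mvflow.network import VascularNetwork, NetworkValidationError
from mvflow.rheology import hydraulic_conductance, tube_hematocrit, CP_TO_PA_S

PRESSURE, FLOW, RELATIVE = "pressure", "flow", "relative_pressure"


@dataclass
class BoundaryCondition:
    """One condition at one boundary node.

    kind 'pressure': value in mmHg.
    kind 'flow': value in um^3/s, positive = into the network.
    kind 'relative_pressure': value is the deviation dp_i in mmHg relative to
    the weighted mean pressure of the reference group named by ``reference``.
    """

    node_id: int
    kind: str
    value: float
    reference: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (PRESSURE, FLOW, RELATIVE):
            raise ValueError(f"unknown boundary-condition kind {self.kind!r}")
        if self.kind == RELATIVE and self.reference is None:
            raise ValueError("relative_pressure condition requires a reference group id")


@dataclass
class ReferenceGroup:
    """Set of interior reference nodes with normalized positive weights."""

    id: int
    node_ids: np.ndarray  # external node ids
    weights: np.ndarray | None = None  # defaults to equal weights

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        if len(self.node_ids) == 0:
            raise ValueError(f"reference group {self.id} is empty")
        if self.weights is None:
            self.weights = np.full(len(self.node_ids), 1.0 / len(self.node_ids))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("reference weights must be positive")
            if abs(self.weights.sum() - 1.0) > 1e-12:
                raise ValueError("reference weights must sum to 1")


def groups_from_layers(net: VascularNetwork, layer_groups: dict[int, np.ndarray]
                       ) -> dict[int, ReferenceGroup]:
    """Equal-weight ReferenceGroups (keyed by layer) from node array positions."""
    return {
        ell: ReferenceGroup(id=ell, node_ids=net.node_ids[pos])
        for ell, pos in layer_groups.items()
    }


@dataclass
class SystemMatrices:
    """Assembled operators of the governing linear system."""

    M: sp.csr_matrix  # m x n conductance/incidence: q = M p
    L: sp.csr_matrix  # n x m connectivity (conservation / flow-BC rows)
    J: sp.csr_matrix  # n x n boundary indicator diagonal
    N: sp.csr_matrix  # n x n reference-weight operator
    R: sp.csr_matrix  # n x n right-hand-side mapping
    b: np.ndarray  # (n,) boundary values / deviations
    K: sp.csr_matrix  # L M + J + N
    conductances: np.ndarray  # (m,)
    node_kind: np.ndarray  # (n,) str: interior | pressure | flow | relative_pressure
    relative_info: dict[int, tuple[np.ndarray, np.ndarray]]  # node pos -> (ref pos, w)
    group_of: dict[int, int] = field(default_factory=dict)  # node pos -> group id


@dataclass
class FlowSolution:
    """Node pressures and segment-level hemodynamics for one parameter setting."""

    p: np.ndarray  # mmHg
    q: np.ndarray  # um^3/s, positive start -> end
    velocity: np.ndarray | None = None  # mm/s (bulk)
    wall_shear_stress: np.ndarray | None = None  # dyn/cm^2
    discharge_hematocrit: np.ndarray | None = None
    effective_viscosity: np.ndarray | None = None  # cP
    rbc_velocity: np.ndarray | None = None  # mm/s


def assemble(
    net: VascularNetwork,
    viscosities: np.ndarray,
    bcs: list[BoundaryCondition],
    groups: dict[int, ReferenceGroup] | None = None,
) -> SystemMatrices:
    """Assemble K p = R b for a network, per-segment viscosities (cP), and BCs."""
    n, m = net.n, net.m
    viscosities = np.asarray(viscosities, dtype=float)
    if viscosities.shape != (m,) or np.any(viscosities <= 0):
        raise ValueError("viscosities must be positive, one per segment")
    groups = groups or {}

    g = hydraulic_conductance(net.diameters, net.lengths, viscosities)
    rows = np.repeat(np.arange(m), 2)
    cols = np.column_stack([net.seg_start, net.seg_end]).ravel()
    vals = np.column_stack([g, -g]).ravel()
    M = sp.csr_matrix((vals, (rows, cols)), shape=(m, n))

    node_kind = np.full(n, "interior", dtype=object)
    b = np.zeros(n)
    relative_info: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    group_of: dict[int, int] = {}
    seen: set[int] = set()
    for bc in bcs:
        if bc.node_id not in net.node_index:
            raise NetworkValidationError(f"boundary condition names absent node id {bc.node_id}")
        i = net.node_index[bc.node_id]
        if not net.is_boundary[i]:
            raise NetworkValidationError(
                f"boundary condition on non-boundary node id {bc.node_id}"
            )
        if i in seen:
            raise NetworkValidationError(
                f"multiple boundary conditions on node id {bc.node_id}"
            )
        seen.add(i)
        node_kind[i] = bc.kind
        b[i] = bc.value
        if bc.kind == RELATIVE:
            if bc.reference not in groups:
                raise NetworkValidationError(
                    f"relative condition on node id {bc.node_id} cites unknown "
                    f"reference group {bc.reference}"
                )
            grp = groups[bc.reference]
            ref_pos = np.array([net.node_index[int(s)] for s in grp.node_ids], dtype=int)
            if np.any(net.is_boundary[ref_pos]):
                raise NetworkValidationError(
                    f"reference group {grp.id} contains boundary nodes"
                )
            relative_info[i] = (ref_pos, grp.weights.copy())
            group_of[i] = grp.id

    uncovered = np.flatnonzero(net.is_boundary & (node_kind == "interior"))
    if len(uncovered):
        raise NetworkValidationError(
            f"boundary node id {net.node_ids[uncovered[0]]} has no boundary condition"
        )

    # anchor requirement: >= 1 conventional pressure condition per component
    comp = net._components()
    for c in range(comp.max() + 1):
        in_c = comp == c
        if not np.any(in_c & (node_kind == PRESSURE)):
            raise NetworkValidationError(
                f"connected component {c} has no conventional pressure boundary "
                f"condition; the pressure level is undetermined (add an anchor)"
            )

    # L: signed incidence rows at interior nodes (net outflow = 0) and
    # inflow rows at flow-BC nodes (flow into network = b)
    lr, lc, lv = [], [], []
    for j in range(m):
        s, e = net.seg_start[j], net.seg_end[j]
        if node_kind[s] == "interior":
            lr.append(s); lc.append(j); lv.append(1.0)
        elif node_kind[s] == FLOW:
            lr.append(s); lc.append(j); lv.append(1.0)
        if node_kind[e] == "interior":
            lr.append(e); lc.append(j); lv.append(-1.0)
        elif node_kind[e] == FLOW:
            lr.append(e); lc.append(j); lv.append(-1.0)
    L = sp.csr_matrix((lv, (lr, lc)), shape=(n, m))

    jdiag = np.isin(node_kind, (PRESSURE, RELATIVE)).astype(float)
    J = sp.diags(jdiag, format="csr")

    nr, nc, nv = [], [], []
    for i, (ref_pos, w) in relative_info.items():
        nr.extend([i] * len(ref_pos))
        nc.extend(ref_pos.tolist())
        nv.extend((-w).tolist())
    N = sp.csr_matrix((nv, (nr, nc)), shape=(n, n))
    R = sp.identity(n, format="csr")
    K = (L @ M + J + N).tocsr()
    return SystemMatrices(M=M, L=L, J=J, N=N, R=R, b=b, K=K, conductances=g,
                          node_kind=node_kind, relative_info=relative_info,
                          group_of=group_of)


def apply_grouped_encoding(sys: SystemMatrices,
                           groups: dict[int, ReferenceGroup] | None = None
                           ) -> SystemMatrices:
    """Sparsity-preserving, mathematically equivalent relative-BC encoding.

    For every reference group shared by two or more relative-BC boundary
    nodes, a single designated representative node keeps the full row
    p_rep - sum_s w_s p_s = dp_rep, while every other member i of the group
    carries the sparse differencing row p_i - p_rep = dp_i - dp_rep (encoded
    via N[i, rep] = -1 and R mapping b into the combined deviation).  Solved
    pressures are identical to the ungrouped encoding.
    """
    n = sys.b.shape[0]
    members_by_group: dict[int, list[int]] = {}
    for i, gid in sys.group_of.items():
        members_by_group.setdefault(gid, []).append(i)

    nr, nc, nv = [], [], []
    R = sp.identity(n, format="lil")
    for gid, members in members_by_group.items():
        members = sorted(members)
        rep = members[0]
        ref_pos, w = sys.relative_info[rep]
        nr.extend([rep] * len(ref_pos))
        nc.extend(ref_pos.tolist())
        nv.extend((-w).tolist())
        for i in members[1:]:
            nr.append(i); nc.append(rep); nv.append(-1.0)
            R[i, rep] = -1.0
    N = sp.csr_matrix((nv, (nr, nc)), shape=(n, n))
    R = R.tocsr()
    K = (sys.L @ sys.M + sys.J + N).tocsr()
    return SystemMatrices(M=sys.M, L=sys.L, J=sys.J, N=N, R=R, b=sys.b, K=K,
                          conductances=sys.conductances, node_kind=sys.node_kind,
                          relative_info=sys.relative_info, group_of=sys.group_of)


class SingularSystemError(RuntimeError):
    pass


def splu_factor(sys: SystemMatrices):
    """Sparse LU factorization of K (reusable across right-hand sides)."""
    return spla.splu(sys.K.tocsc())


def solve(sys: SystemMatrices, *, factor=None) -> FlowSolution:
    """Solve K p = R b by sparse direct factorization; return pressures and flows.

    ``factor`` optionally supplies a precomputed ``splu`` factorization of K
    (re-used only when K is unchanged; callers solving many right-hand sides
    for the same operator are responsible for that invariant).
    """
    rhs = sys.R @ sys.b
    try:
        lu = factor if factor is not None else splu_factor(sys)
        p = lu.solve(rhs)
        # two steps of iterative refinement: conservation rows carry large
        # conductances while boundary rows are O(1), and refinement recovers
        # the digits that this scale mixing costs the factorization
        for _ in range(2):
            r = rhs - sys.K @ p
            p = p + lu.solve(r)
    except RuntimeError as err:  # pragma: no cover - scipy raises on exact singularity
        raise SingularSystemError(
            "singular system: likely a missing pressure anchor or a disconnected "
            "component without boundary conditions"
        ) from err
    if not np.all(np.isfinite(p)):
        raise SingularSystemError(
            "non-finite pressures: likely a missing pressure anchor or a "
            "disconnected component without boundary conditions"
        )
    q = sys.M @ p
    resid = interior_residual(sys, q)
    qmax = np.max(np.abs(q)) if len(q) else 0.0
    if qmax > 0 and resid > 1e-8 * qmax:
        raise SingularSystemError(
            f"interior mass-conservation residual {resid:.3e} exceeds tolerance"
        )
    return FlowSolution(p=p, q=q)


def interior_residual(sys: SystemMatrices, q: np.ndarray) -> float:
    """Max absolute net flow over interior nodes (um^3/s)."""
    interior = sys.node_kind == "interior"
    if not interior.any():
        return 0.0
    net_flow = sys.L @ q
    return float(np.max(np.abs(net_flow[interior])))


def enforce_adaptive_identity_check(sol: FlowSolution, sys: SystemMatrices) -> float:
    """Max violation (mmHg) of p_i - sum_s w_s p_s = dp_i over relative-BC nodes."""
    worst = 0.0
    for i, (ref_pos, w) in sys.relative_info.items():
        viol = abs(sol.p[i] - float(w @ sol.p[ref_pos]) - sys.b[i])
        worst = max(worst, viol)
    return worst


def derived_quantities(
    sol: FlowSolution,
    net: VascularNetwork,
    viscosities: np.ndarray,
    discharge_hematocrit: np.ndarray | None = None,
) -> FlowSolution:
    """Attach bulk velocity (mm/s), wall shear stress (dyn/cm^2), and
    optionally RBC velocity = bulk velocity * H_D / H_T via the Fahraeus
    relation."""
    d = net.diameters
    # bulk velocity: 4 q / (pi d^2), um/s -> mm/s
    sol.velocity = 4.0 * sol.q / (np.pi * d**2) / 1e3
    # wall shear stress: 32 mu |q| / (pi d^3); Pa -> dyn/cm^2 is x10
    mu_pa_s = np.asarray(viscosities, dtype=float) * CP_TO_PA_S
    sol.wall_shear_stress = 32.0 * mu_pa_s * np.abs(sol.q) / (np.pi * d**3) * 10.0
    sol.effective_viscosity = np.asarray(viscosities, dtype=float)
    if discharge_hematocrit is not None:
        hd = np.asarray(discharge_hematocrit, dtype=float)
        sol.discharge_hematocrit = hd
        ht = tube_hematocrit(d, hd)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ht > 0, hd / ht, 1.0)
        sol.rbc_velocity = sol.velocity * ratio
    return sol
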