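"""Coupled flow / phase-separation / viscosity fixed-point iteration.

Hematocrit feeds back on flow through the viscosity law, and flow feeds back
on hematocrit through the phase-separation split at diverging bifurcations.
The coupled problem is solved by an under-relaxed fixed-point iteration in
which the linear pressure solve appears as a sub-step:

1. evaluate per-segment viscosities and conductances at the current
   discharge hematocrits;
2. solve the linear system for pressures and flows;
3. propagate hematocrit downstream along the current flow directions
   (boundary inflow segments carry the configured inlet hematocrit,
   converging nodes mix by flux-weighted average, diverging bifurcations
   apply the logit split law, higher-order branchings recurse pairwise in
   descending daughter-flow order, and flow cycles are broken by falling
   back on previous-iteration values);
4. under-relaxed update and convergence test on the max absolute change.

Residuals of this fixed point are known to oscillate; the relaxation factor
is halved automatically when the residual grows on consecutive iterations.
Convergence is verified by one final un-relaxed propagation pass, which also
restores exact red-cell flux conservation with respect to the final flow
field (up to the physical ceiling H_D <= 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from mvflow.network import VascularNetwork
from mvflow.rheology import ViscosityModel, effective_viscosity, phase_separation_split
from mvflow.solver import (
    BoundaryCondition,
    ReferenceGroup,
    FlowSolution,
    assemble,
    solve,
    derived_quantities,
)


@dataclass
class HematocritSolverConfig:
    inlet_discharge_hematocrit: float = 0.40
    tolerance: float = 1e-6  # max absolute H_D change per iteration
    max_iterations: int = 200
    relaxation: float = 0.5
    zero_flow_threshold: float = 1e-10  # um^3/s, absolute floor
    zero_flow_rel_threshold: float = 1e-6  # fraction of max |q|
    phase_separation: bool = True  # False -> proportional split

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0 < self.relaxation <= 1:
            raise ValueError("relaxation must lie in (0, 1]")


@dataclass
class ConvergenceReport:
    converged: bool
    iterations: int
    final_residual: float
    residuals: list[float] = field(default_factory=list)
    n_zero_flow: int = 0


class HematocritConvergenceError(RuntimeError):
    def __init__(self, message: str, report: ConvergenceReport):
        super().__init__(message)
        self.report = report


def _split_flux(daughters, flux_in, h_mix, parent_d, net, cfg):
    """Distribute red-cell flux among >= 2 outgoing segments.

    ``daughters`` is a list of (segment index, outgoing flow) sorted by
    descending flow.  Pairs are split recursively: the largest daughter
    against the aggregate of the rest (aggregate diameter taken as the
    area-preserving sqrt of summed squares).  Returns dict seg -> H_D.
    """
    out: dict[int, float] = {}

    def recurse(ds, flux):
        if len(ds) == 1:
            j, qj = ds[0]
            out[j] = min(1.0, flux / qj) if qj > 0 else 0.0
            return
        (j0, q0), rest = ds[0], ds[1:]
        q_rest = sum(q for _, q in rest)
        d0 = net.diameters[j0]
        d_rest = float(np.sqrt(sum(net.diameters[j] ** 2 for j, _ in rest)))
        fqb = q0 / (q0 + q_rest)
        if cfg.phase_separation and h_mix > 0:
            fqe = phase_separation_split(fqb, parent_d, d0, d_rest, min(h_mix, 1.0))
        else:
            fqe = fqb
        flux0 = min(fqe * flux, q0)  # H_D ceiling of 1
        out[j0] = flux0 / q0 if q0 > 0 else 0.0
        recurse(rest, flux - flux0)

    recurse(daughters, flux_in)
    return out


def _propagate(net, q, h_prev, cfg, threshold=None):
    """One downstream hematocrit propagation pass for a fixed flow field.

    Segments below the zero-flow threshold (the larger of the absolute
    configuration value and the relative fraction of the network's peak
    flow) keep their previous hematocrit and are excluded from splits:
    split fractions are undefined at zero flow, and direction noise in
    stagnant vessels would otherwise never let the iteration settle.
    """
    m = net.m
    absq = np.abs(q)
    if threshold is None:
        threshold = max(cfg.zero_flow_threshold,
                        cfg.zero_flow_rel_threshold * (absq.max() if m else 0.0))
    active = absq > threshold
    # upstream/downstream node (array position) of each active segment
    up = np.where(q >= 0, net.seg_start, net.seg_end)
    dn = np.where(q >= 0, net.seg_end, net.seg_start)

    inflow_segs: list[list[int]] = [[] for _ in range(net.n)]
    outflow_segs: list[list[int]] = [[] for _ in range(net.n)]
    for j in range(m):
        if active[j]:
            inflow_segs[dn[j]].append(j)
            outflow_segs[up[j]].append(j)

    h_new = h_prev.copy()
    resolved = np.zeros(m, dtype=bool)
    resolved[~active] = True  # zero-flow segments keep previous values

    n_unresolved_in = np.array([len(s) for s in inflow_segs])
    # boundary nodes feeding the network start the traversal
    ready = [
        i for i in range(net.n)
        if n_unresolved_in[i] == 0 and outflow_segs[i]
    ]
    fallback = False

    def process(i: int) -> None:
        outs = outflow_segs[i]
        if not outs:  # pure sink (e.g. outflow boundary node)
            return
        if net.is_boundary[i]:
            h_mix = cfg.inlet_discharge_hematocrit
            flow_in = sum(absq[j] for j in outs)
            flux_in = h_mix * flow_in
            parent_d = net.diameters[outs[0]]
        else:
            ins = inflow_segs[i]
            flow_in = sum(absq[j] for j in ins)
            flux_in = sum(absq[j] * h_new[j] for j in ins)
            if flow_in <= 0:
                for j in outs:
                    resolved[j] = True  # keep previous H in dead subgraphs
                return
            h_mix = flux_in / flow_in
            parent_d = net.diameters[max(ins, key=lambda j: absq[j])]
        if len(outs) == 1:
            j = outs[0]
            h_new[j] = min(1.0, flux_in / absq[j]) if absq[j] > 0 else h_mix
        else:
            daughters = sorted(((j, absq[j]) for j in outs), key=lambda t: -t[1])
            split = _split_flux(daughters, flux_in, h_mix, parent_d, net, cfg)
            for j, h in split.items():
                h_new[j] = h
        for j in outs:
            resolved[j] = True

    queue = list(ready)
    processed = np.zeros(net.n, dtype=bool)
    while True:
        while queue:
            i = queue.pop()
            if processed[i]:
                continue
            processed[i] = True
            process(i)
            for j in outflow_segs[i]:
                k = dn[j]
                n_unresolved_in[k] -= 1
                if n_unresolved_in[k] == 0 and not processed[k]:
                    queue.append(k)
        remaining = [
            i for i in range(net.n)
            if not processed[i] and outflow_segs[i]
        ]
        if not remaining:
            break
        # flow cycle: resolve the remaining node with fewest unresolved
        # inflows using previous-iteration values for those inflows
        fallback = True
        i = min(remaining, key=lambda k: (n_unresolved_in[k], k))
        for j in inflow_segs[i]:
            if not resolved[j]:
                resolved[j] = True  # h_new[j] already holds previous value
        n_unresolved_in[i] = 0
        queue.append(i)

    n_zero = int(np.sum(~active))
    return h_new, n_zero, fallback


def rbc_flux_residual(net, sol: FlowSolution, node_kind: np.ndarray) -> float:
    """Max relative red-cell flux imbalance over interior nodes."""
    h = sol.discharge_hematocrit
    flux = sol.q * h
    net_flux = np.zeros(net.n)
    np.add.at(net_flux, net.seg_start, flux)
    np.add.at(net_flux, net.seg_end, -flux)
    interior = node_kind == "interior"
    scale = np.max(np.abs(flux)) if np.any(flux) else 1.0
    if scale == 0:
        return 0.0
    return float(np.max(np.abs(net_flux[interior])) / scale)


def solve_nonlinear(
    net: VascularNetwork,
    bcs: list[BoundaryCondition],
    groups: dict[int, ReferenceGroup] | None,
    model: ViscosityModel,
    cfg: HematocritSolverConfig | None = None,
) -> tuple[FlowSolution, ConvergenceReport]:
    """Converged biphasic flow solution and a convergence report."""
    cfg = cfg or HematocritSolverConfig()
    h = np.full(net.m, cfg.inlet_discharge_hematocrit)
    # per-segment relaxation: this fixed point oscillates locally, so each
    # segment's factor is halved when its update flips sign on consecutive
    # iterations and grown gently while progress is monotone
    omega = np.full(net.m, cfg.relaxation)
    d_prev = np.zeros(net.m)
    residuals: list[float] = []
    sol = None
    n_zero = 0
    for it in range(1, cfg.max_iterations + 1):
        mu = effective_viscosity(net.diameters, h, model)
        sys = assemble(net, mu, bcs, groups)
        sol = solve(sys)
        h_prop, n_zero, _ = _propagate(net, sol.q, h, cfg)
        d = h_prop - h
        resid = float(np.max(np.abs(d)))
        residuals.append(resid)
        if resid <= cfg.tolerance:
            break
        osc = d * d_prev < 0
        mono = d * d_prev > 0
        omega[osc] = np.maximum(0.02, omega[osc] * 0.5)
        omega[mono] = np.minimum(1.0, omega[mono] * 1.1)
        d_prev = d
        h = np.clip(h + omega * d, 0.0, 1.0)
    else:
        report = ConvergenceReport(False, cfg.max_iterations, residuals[-1], residuals, n_zero)
        raise HematocritConvergenceError(
            f"hematocrit iteration did not converge in {cfg.max_iterations} "
            f"iterations (residual {residuals[-1]:.3e})", report
        )

    # verification pass: one extra un-relaxed propagation against the final
    # flow field; restores exact flux conservation for that field
    h_final, n_zero, _ = _propagate(net, sol.q, h, cfg)
    final_resid = float(np.max(np.abs(h_final - h)))
    mu = effective_viscosity(net.diameters, h_final, model)
    sol = derived_quantities(sol, net, mu, discharge_hematocrit=h_final)
    report = ConvergenceReport(True, it, final_resid, residuals, n_zero)
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-flow segments kept previous hematocrit", stacklevel=2
        )
    return sol, report
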