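"""Flow-path tracking from surface arterioles to surface venules.

Paths are sampled by flow-proportional random walks launched at surface-
arteriole (SA) boundary nodes carrying inflow: at every diverging node the
walk picks an outgoing segment with probability proportional to its flow,
so the product of branch fractions along a walk is the fraction of the
inlet flow following that exact route.  A retained path's weight is the
inlet boundary flow times that product; duplicate walks (identical segment
sequences) collapse to a single path, and the weights of all distinct
complete paths from one inlet sum to the inlet flow.

Walks are retained when their vessel-category sequence follows the
canonical order SA -> DA+A -> C -> AV+V -> SV, with up to two subsequent
deviating transitions permitted and UNK segments transparent to the
matcher.

The depth analyses summarize per-category pressure drops grouped by the
analysis layer of the first capillary segment, and the relation between
capillary entry depth (zIn) and exit depth (zOut), all statistics weighted
by path flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mvflow.network import VascularNetwork, CATEGORIES, assign_analysis_layers
from mvflow.solver import FlowSolution

CANONICAL = ["SA", "DA+A", "C", "AV+V", "SV"]


@dataclass
class FlowPath:
    segments: tuple[int, ...]  # segment array positions, in flow order
    categories: tuple[str, ...]
    weight: float  # blood flow rate along this exact route, um^3/s
    pressure_drops: dict[str, float]  # per-category cumulative drop, mmHg
    z_in: float | None  # depth of first capillary segment, um
    z_out: float | None  # depth of last capillary segment, um
    first_capillary_layer: int | None
    mean_dar: dict[str, float] = field(default_factory=dict)


def _sequence_ok(categories, max_deviations: int = 2) -> bool:
    """Match against the canonical category order, UNK transparent.

    Consecutive duplicates collapse; a transition that neither stays at the
    current canonical stage nor advances to the next counts as a deviation.
    The walk must visit all five stages in order and deviate at most
    ``max_deviations`` times.
    """
    seq = [c for c in categories if c != "UNK"]
    compressed = [c for k, c in enumerate(seq) if k == 0 or c != seq[k - 1]]
    if not compressed or compressed[0] != "SA":
        return False
    stage = 0
    deviations = 0
    for c in compressed[1:]:
        if c == CANONICAL[stage]:
            continue
        if stage + 1 < len(CANONICAL) and c == CANONICAL[stage + 1]:
            stage += 1
        else:
            deviations += 1
            if deviations > max_deviations:
                return False
    return stage == len(CANONICAL) - 1


def track_paths(
    sol: FlowSolution,
    net: VascularNetwork,
    n_walks: int = 1000,
    seed: int = 0,
    max_length: int = 10000,
    zero_flow_threshold: float = 1e-10,
    layers: np.ndarray | None = None,
    max_deviations: int = 2,
) -> tuple[list[FlowPath], dict]:
    """Sample flow paths; returns (paths, diagnostics).

    ``n_walks`` walks are launched from each SA boundary inflow node.
    Diagnostics report counts of discarded (overlong) and rejected
    (non-canonical) walks.
    """
    if layers is None:
        layers = assign_analysis_layers(net)
    q = sol.q
    absq = np.abs(q)
    active = absq > zero_flow_threshold
    up = np.where(q >= 0, net.seg_start, net.seg_end)
    dn = np.where(q >= 0, net.seg_end, net.seg_start)
    outflow: list[list[int]] = [[] for _ in range(net.n)]
    for j in range(net.m):
        if active[j]:
            outflow[up[j]].append(j)

    sa_inlets = [
        int(i)
        for i in np.flatnonzero(net.is_boundary & (net.node_categories == "SA"))
        if outflow[i]
    ]
    rng = np.random.default_rng(seed)
    mean_depth = 0.5 * (net.positions[net.seg_start, 2] + net.positions[net.seg_end, 2])

    found: dict[tuple[int, ...], FlowPath] = {}
    n_discarded = 0
    n_rejected = 0
    for inlet in sa_inlets:
        inlet_flow = sum(absq[j] for j in outflow[inlet])
        for _ in range(n_walks):
            node = inlet
            frac = 1.0
            segs: list[int] = []
            while True:
                outs = outflow[node]
                if not outs or (net.is_boundary[node] and node != inlet):
                    break
                if len(segs) >= max_length:
                    segs = None
                    break
                flows = np.array([absq[j] for j in outs])
                probs = flows / flows.sum()
                k = rng.choice(len(outs), p=probs) if len(outs) > 1 else 0
                j = outs[k]
                frac *= probs[k]
                segs.append(j)
                node = int(dn[j])
            if segs is None:
                n_discarded += 1
                continue
            key = tuple(segs)
            if key in found:
                continue
            cats = tuple(net.seg_categories[j] for j in segs)
            if not _sequence_ok(cats, max_deviations):
                n_rejected += 1
                continue
            drops: dict[str, float] = {}
            for j in segs:
                drop = float(sol.p[up[j]] - sol.p[dn[j]])
                drops[net.seg_categories[j]] = drops.get(net.seg_categories[j], 0.0) + drop
            cap = [j for j in segs if net.seg_categories[j] == "C"]
            z_in = float(mean_depth[cap[0]]) if cap else None
            z_out = float(mean_depth[cap[-1]]) if cap else None
            first_al = int(layers[cap[0]]) if cap else None
            found[key] = FlowPath(
                segments=key, categories=cats, weight=float(inlet_flow * frac),
                pressure_drops=drops, z_in=z_in, z_out=z_out,
                first_capillary_layer=first_al,
            )
    diagnostics = {
        "n_inlets": len(sa_inlets),
        "n_paths": len(found),
        "n_discarded": n_discarded,
        "n_rejected": n_rejected,
    }
    return list(found.values()), diagnostics


def weighted_percentile(values, weights, pct):
    """Weighted percentile with expanded-sample semantics.

    Equivalent to numpy.percentile (linear interpolation) applied to the
    sample in which each value is repeated ``weight`` times; exact for
    integer weights and continuous in the weights.  Unit weights reduce to
    the unweighted percentile exactly.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    order = np.argsort(v)
    v, w = v[order], w[order]
    keep = w > 0
    v, w = v[keep], w[keep]
    cum = np.cumsum(w)
    total = cum[-1]
    scalar_in = np.ndim(pct) == 0
    if len(v) == 1:
        out = np.full(np.atleast_1d(pct).shape, float(v[0]))
        return float(out[0]) if scalar_in else out
    h = np.atleast_1d(np.asarray(pct, dtype=float)) / 100.0 * (total - 1.0)
    h = np.clip(h, 0.0, max(total - 1.0, 0.0))
    starts = cum - w  # block i occupies expanded positions [starts, cum - 1]
    ends = cum - 1.0
    idx = np.minimum(np.searchsorted(ends, h, side="left"), len(v) - 1)
    out = v[idx].astype(float)
    cross = (h < starts[idx]) & (idx > 0)
    if np.any(cross):
        i = idx[cross]
        frac = h[cross] - ends[i - 1]
        gap = starts[i] - ends[i - 1]
        out[cross] = v[i - 1] + frac / gap * (v[i] - v[i - 1])
    out[(h < starts[idx]) & (idx == 0)] = v[0]
    return float(out[0]) if scalar_in else out


def _weighted_band(values, weights):
    return {
        "median": weighted_percentile(values, weights, 50),
        "p12_5": weighted_percentile(values, weights, 12.5),
        "p87_5": weighted_percentile(values, weights, 87.5),
        "p5": weighted_percentile(values, weights, 5),
        "p95": weighted_percentile(values, weights, 95),
    }


def pressure_drop_profile(paths: list[FlowPath]) -> pd.DataFrame:
    """Flow-weighted per-category pressure-drop bands grouped by the
    analysis layer of the first capillary segment."""
    if not paths:
        raise ValueError("empty path set")
    rows = []
    by_layer: dict[int, list[FlowPath]] = {}
    for p in paths:
        if p.first_capillary_layer is not None:
            by_layer.setdefault(p.first_capillary_layer, []).append(p)
    for ell, group in sorted(by_layer.items()):
        for cat in CATEGORIES:
            vals = [p.pressure_drops.get(cat) for p in group]
            pairs = [(v, p.weight) for v, p in zip(vals, group) if v is not None]
            if not pairs:
                continue
            v, w = zip(*pairs)
            rows.append({"first_capillary_layer": ell, "category": cat,
                         "count": len(v), **_weighted_band(v, w)})
    return pd.DataFrame(rows)


def capillary_io_depths(paths: list[FlowPath]):
    """(zIn, zOut) pairs and the flow-weighted least-squares line zOut ~ zIn.

    Returns (z_in, z_out, weights, slope, intercept); slope/intercept are
    NaN when the fit is degenerate (all zIn equal).  Normal equations of the
    weighted 2-parameter fit, solved in closed form.
    """
    pts = [(p.z_in, p.z_out, p.weight) for p in paths if p.z_in is not None]
    if not pts:
        raise ValueError("no paths with capillary segments")
    z_in, z_out, w = (np.array(a, dtype=float) for a in zip(*pts))
    sw = w.sum()
    xbar = (w * z_in).sum() / sw
    ybar = (w * z_out).sum() / sw
    sxx = (w * (z_in - xbar) ** 2).sum()
    if sxx <= 0:
        return z_in, z_out, w, float("nan"), float("nan")
    sxy = (w * (z_in - xbar) * (z_out - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    return z_in, z_out, w, float(slope), float(intercept)


def path_dar(paths: list[FlowPath], segment_dar: np.ndarray) -> list[FlowPath]:
    """Attach the per-category arithmetic mean of segment DARs to each path."""
    for p in paths:
        sums: dict[str, list[float]] = {}
        for j, cat in zip(p.segments, p.categories):
            sums.setdefault(cat, []).append(float(segment_dar[j]))
        p.mean_dar = {c: float(np.mean(v)) for c, v in sums.items()}
    return paths


def path_dar_profile(paths: list[FlowPath]) -> pd.DataFrame:
    """Aggregate per-path category DARs like the pressure-drop profile."""
    rows = []
    by_layer: dict[int, list[FlowPath]] = {}
    for p in paths:
        if p.first_capillary_layer is not None and p.mean_dar:
            by_layer.setdefault(p.first_capillary_layer, []).append(p)
    for ell, group in sorted(by_layer.items()):
        for cat in CATEGORIES:
            pairs = [(p.mean_dar[cat], p.weight) for p in group if cat in p.mean_dar]
            if not pairs:
                continue
            v, w = zip(*pairs)
            rows.append({"first_capillary_layer": ell, "category": cat,
                         "count": len(v), **_weighted_band(v, w)})
    return pd.DataFrame(rows)


def paths_to_frame(paths: list[FlowPath]) -> pd.DataFrame:
    """One row per path: weight, zIn, zOut, per-category drops."""
    rows = []
    for p in paths:
        row = {"weight": p.weight, "z_in": p.z_in, "z_out": p.z_out,
               "first_capillary_layer": p.first_capillary_layer,
               "n_segments": len(p.segments)}
        for cat in CATEGORIES:
            row[f"drop_{cat}"] = p.pressure_drops.get(cat)
        rows.append(row)
    return pd.DataFrame(rows)
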