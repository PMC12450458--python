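"""Bayesian calibration of unknown boundary pressures.

Unknown boundary-condition values theta (conventional boundary pressures and
relative pressure deviations, all in mmHg) are inferred from target red-cell
velocities and presumed flow directions in a subset of arteriole/venule
segments by sampling the posterior p(theta | y) ~ p(y | theta) p(theta).

Priors are scaled and shifted beta distributions per parameter.  The
likelihood combines Gaussian velocity residuals with a smooth probit penalty
on flow directions; both terms are pluggable.  During calibration the flow
model uses a uniform discharge hematocrit (0.40 by default) so conductances
are fixed and segment flows are an affine map of theta; the forward model
precomputes that map once, making each likelihood evaluation a small
matrix-vector product.  Posterior draws are then propagated through the
nonlinear (phase-separation) model in a second step.

Sampling uses an archive-based differential-evolution MCMC with snooker
updates: proposals are built from differences of states sampled from a
growing archive of past states, which keeps a handful of parallel chains
effective in high dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from mvflow.network import (
    VascularNetwork,
    ARTERIOLE_CATEGORIES,
    VENULE_CATEGORIES,
    assign_analysis_layers,
)
from mvflow.rheology import ViscosityModel, effective_viscosity, tube_hematocrit
from mvflow.solver import BoundaryCondition, ReferenceGroup, assemble, solve
from mvflow.uq import influence_matrix, dar_empirical


@dataclass
class CalibrationTarget:
    segment_id: int
    kind: str  # "velocity" | "direction"
    value: float  # mm/s for velocity; sign (+1/-1) w.r.t. segment orientation

    def __post_init__(self) -> None:
        if self.kind not in ("velocity", "direction"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.kind == "velocity" and self.value <= 0:
            raise ValueError("velocity targets must be positive")
        if self.kind == "direction" and self.value not in (-1, 1):
            raise ValueError("direction targets must be +1 or -1")


@dataclass
class PriorSpec:
    """Per-parameter scaled+shifted beta priors on [lower, upper] (mmHg)."""

    lower: np.ndarray
    upper: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        self.alpha = np.broadcast_to(np.asarray(self.alpha, dtype=float), self.lower.shape).copy()
        self.beta = np.broadcast_to(np.asarray(self.beta, dtype=float), self.lower.shape).copy()
        if np.any(self.lower >= self.upper):
            raise ValueError("prior lower bounds must be below upper bounds")
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("beta shape parameters must be positive")

    @property
    def dim(self) -> int:
        return len(self.lower)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.beta(self.alpha, self.beta, size=(n, self.dim))
        return self.lower + u * (self.upper - self.lower)

    def mean(self) -> np.ndarray:
        return self.lower + (self.upper - self.lower) * self.alpha / (self.alpha + self.beta)


def log_prior(theta: np.ndarray, priors: PriorSpec) -> np.ndarray:
    """Sum of scaled-beta log densities; -inf outside the support."""
    theta = np.asarray(theta, dtype=float)
    scalar_in = theta.ndim == 1
    th = np.atleast_2d(theta)
    if th.shape[-1] != priors.dim:
        raise ValueError("theta dimension does not match priors")
    width = priors.upper - priors.lower
    u = (th - priors.lower) / width
    inside = np.all((u >= 0) & (u <= 1), axis=-1)
    u_safe = np.clip(u, 1e-300, 1 - 1e-16)
    lp = beta_dist.logpdf(u_safe, priors.alpha, priors.beta) - np.log(width)
    out = np.where(inside, lp.sum(axis=-1), -np.inf)
    return float(out[0]) if scalar_in else out


def _direction_targets(net: VascularNetwork, categories, start_from: str,
                       outward: bool) -> dict[int, int]:
    """Presumed flow signs from a traversal of same-class vessel trees.

    Starting from boundary nodes of ``start_from`` category, walk segments
    of the listed categories; ``outward`` True means flow presumed away from
    the starting boundary nodes (arteriolar inflow), False means toward them
    (venular outflow).  Sign is +1 when the presumed direction runs start ->
    end of the segment.
    """
    in_cats = np.isin(net.seg_categories, categories)
    visited_nodes = set(
        int(i) for i in np.flatnonzero(net.is_boundary & (net.node_categories == start_from))
    )
    signs: dict[int, int] = {}
    frontier = list(visited_nodes)
    while frontier:
        nxt = []
        for i in frontier:
            for j in net.incident_segments(i):
                if not in_cats[j] or j in signs:
                    continue
                s, e = int(net.seg_start[j]), int(net.seg_end[j])
                other = e if s == i else s
                away_sign = 1 if s == i else -1  # +1: start->end leads away from i
                signs[int(j)] = away_sign if outward else -away_sign
                if other not in visited_nodes:
                    visited_nodes.add(other)
                    nxt.append(other)
        frontier = nxt
    return signs


def build_velocity_targets(
    net: VascularNetwork,
    fit: dict[str, tuple[float, float]],
    diameter_max: float = 30.0,
    layer: int = 1,
    layers: np.ndarray | None = None,
) -> list[CalibrationTarget]:
    """Velocity and direction targets for arteriole/venule segments.

    ``fit`` maps class "Art"/"Ven" to (slope, intercept) of a linear
    diameter -> velocity (mm/s) relation.  Velocity targets cover Art and
    Ven segments with diameter < ``diameter_max`` inside analysis layer
    ``layer``; direction targets come from tree traversals starting at SA
    (inflow) and SV (outflow) boundary nodes.
    """
    if layers is None:
        layers = assign_analysis_layers(net)
    targets: list[CalibrationTarget] = []
    art = np.isin(net.seg_categories, ARTERIOLE_CATEGORIES)
    ven = np.isin(net.seg_categories, VENULE_CATEGORIES)
    eligible = (net.diameters < diameter_max) & (layers == layer)
    for cls, mask in (("Art", art), ("Ven", ven)):
        slope, intercept = fit[cls]
        for j in np.flatnonzero(mask & eligible):
            v = slope * net.diameters[j] + intercept
            targets.append(CalibrationTarget(int(net.seg_ids[j]), "velocity", float(v)))
    art_signs = _direction_targets(net, ARTERIOLE_CATEGORIES, "SA", outward=True)
    ven_signs = _direction_targets(net, VENULE_CATEGORIES, "SV", outward=False)
    for j, s in {**art_signs, **ven_signs}.items():
        targets.append(CalibrationTarget(int(net.seg_ids[j]), "direction", s))
    if not targets:
        raise ValueError("empty calibration target set (no eligible Art/Ven segments)")
    return targets


class LinearForwardModel:
    """Affine map theta -> target-segment RBC velocities (mm/s).

    Assembles the flow system at a uniform discharge hematocrit, computes
    the influence-matrix columns of the parameterized boundary nodes, and
    restricts to the target segments.  ``parameter_nodes`` lists external
    node ids in the order of theta; their boundary-condition values in
    ``bcs`` act as defaults (used for the fixed part when a boundary node is
    not parameterized).
    """

    def __init__(
        self,
        net: VascularNetwork,
        bcs: list[BoundaryCondition],
        groups: dict[int, ReferenceGroup] | None,
        parameter_nodes: list[int],
        targets: list[CalibrationTarget],
        model: ViscosityModel | None = None,
        uniform_hd: float = 0.40,
    ) -> None:
        self.net = net
        self.targets = targets
        self.parameter_nodes = list(parameter_nodes)
        model = model or ViscosityModel()
        mu = effective_viscosity(net.diameters, np.full(net.m, uniform_hd), model)
        self.viscosities = np.asarray(mu)
        self.sys = assemble(net, self.viscosities, bcs, groups)
        pos = np.array([net.node_index[i] for i in self.parameter_nodes], dtype=int)
        self._param_pos = pos
        H = influence_matrix(self.sys, pos)  # (m, d)
        b_fixed = self.sys.b.copy()
        b_fixed[pos] = 0.0
        import scipy.sparse.linalg as spla

        lu = spla.splu(self.sys.K.tocsc())
        q_fixed = np.asarray(self.sys.M @ lu.solve(self.sys.R @ b_fixed))
        # RBC velocity conversion per segment: bulk velocity * H_D / H_T
        d = net.diameters
        bulk = 4.0 / (np.pi * d**2) / 1e3  # um^3/s -> mm/s
        ht = tube_hematocrit(d, uniform_hd)
        conv = bulk * np.where(ht > 0, uniform_hd / ht, 1.0)
        self._H_flow = H
        self._q_fixed = q_fixed
        vel_idx = [net.segment_index[t.segment_id] for t in targets if t.kind == "velocity"]
        dir_idx = [net.segment_index[t.segment_id] for t in targets if t.kind == "direction"]
        self.velocity_values = np.array(
            [t.value for t in targets if t.kind == "velocity"])
        self.direction_signs = np.array(
            [t.value for t in targets if t.kind == "direction"])
        self._Hv = conv[vel_idx, None] * H[vel_idx, :]
        self._cv = conv[vel_idx] * q_fixed[vel_idx]
        self._Hd = conv[dir_idx, None] * H[dir_idx, :]
        self._cd = conv[dir_idx] * q_fixed[dir_idx]

    @property
    def dim(self) -> int:
        return len(self.parameter_nodes)

    def velocity_predictions(self, theta: np.ndarray) -> np.ndarray:
        """RBC velocities (mm/s, signed) at velocity-target segments."""
        return np.asarray(theta) @ self._Hv.T + self._cv

    def direction_predictions(self, theta: np.ndarray) -> np.ndarray:
        return np.asarray(theta) @ self._Hd.T + self._cd

    def flows(self, theta: np.ndarray) -> np.ndarray:
        """All segment flows (um^3/s) for parameter vector(s) theta."""
        return np.asarray(theta) @ self._H_flow.T + self._q_fixed

    def bcs_for(self, theta: np.ndarray) -> np.ndarray:
        """Full boundary-value vector b with theta substituted."""
        b = self.sys.b.copy()
        b[self._param_pos] = theta
        return b


def log_likelihood(
    theta: np.ndarray,
    forward: LinearForwardModel,
    velocity_sd: float = 0.5,
    direction_scale: float = 0.1,
) -> np.ndarray:
    """Gaussian velocity term + smooth probit direction term.

    Velocity residuals are compared on speed (absolute predicted velocity)
    so a velocity target does not constrain the sign; flow direction is
    scored by log Phi(sign * v / direction_scale), a smooth penalty that
    saturates once the predicted velocity agrees at a margin of a few
    ``direction_scale`` (mm/s).
    """
    theta = np.asarray(theta, dtype=float)
    scalar_in = theta.ndim == 1
    th = np.atleast_2d(theta)
    ll = np.zeros(th.shape[0])
    if forward._Hv.shape[0]:
        v = np.abs(forward.velocity_predictions(th))
        resid = (v - forward.velocity_values) / velocity_sd
        ll += -0.5 * np.sum(resid**2, axis=-1) - forward._Hv.shape[0] * (
            0.5 * np.log(2 * np.pi) + np.log(velocity_sd)
        )
    if forward._Hd.shape[0]:
        vd = forward.direction_predictions(th)
        ll += np.sum(norm.logcdf(forward.direction_signs * vd / direction_scale), axis=-1)
    return float(ll[0]) if scalar_in else ll


@dataclass
class PosteriorArchive:
    """Thinned MCMC output over boundary-pressure parameters."""

    draws: np.ndarray  # (n_draws, d), thinned, all chains interleaved
    chain_ids: np.ndarray  # (n_draws,)
    log_posterior: np.ndarray  # (n_draws,)
    history: np.ndarray  # (n_chains, n_kept, d) thinned per-chain history
    priors: PriorSpec
    thin: int
    seed: int
    acceptance_rate: float
    rhat: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.history.shape[0]


class StagnationError(RuntimeError):
    pass


def run_mcmc(
    log_posterior,
    priors: PriorSpec,
    n_chains: int = 5,
    n_iterations: int = 20000,
    seed: int = 0,
    thin: int = 10,
    archive_every: int = 10,
    snooker_prob: float = 0.1,
    archive_init: int | None = None,
    stagnation_window: int = 2000,
) -> PosteriorArchive:
    """Archive-based differential-evolution MCMC with snooker updates.

    ``log_posterior(theta_matrix) -> vector`` must accept a (k, d) array.
    Proposals are formed from differences of states sampled from an archive
    of past states (initialized from the prior, extended every
    ``archive_every`` iterations with the current chain states), which keeps
    few chains effective in many dimensions; with probability
    ``snooker_prob`` a snooker move along the direction to an archive state
    is used instead, with the standard Jacobian acceptance correction.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    d = priors.dim
    m0 = archive_init if archive_init is not None else max(10 * d, 5 * n_chains)
    Z = priors.sample(m0, rng)
    X = priors.sample(n_chains, rng)
    lp = np.asarray(log_posterior(X), dtype=float)
    for _ in range(100):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        X[bad] = priors.sample(int(bad.sum()), rng)
        lp[bad] = log_posterior(X[bad])
    if not np.all(np.isfinite(lp)):
        raise ValueError("could not find finite log-posterior starting points")

    jitter = 1e-6 * (priors.upper - priors.lower)
    kept: list[np.ndarray] = []
    kept_lp: list[np.ndarray] = []
    accepts = np.zeros(0)
    acc_window: list[float] = []
    n_accept = 0
    n_prop = 0

    z_rows = np.empty((n_chains, 3), dtype=int)
    for it in range(1, n_iterations + 1):
        nz = Z.shape[0]
        for c in range(n_chains):
            z_rows[c] = rng.choice(nz, size=3, replace=False)
        use_snooker = rng.random(n_chains) < snooker_prob
        gamma_mode = rng.random(n_chains) < 0.1
        prop = X.copy()
        log_corr = np.zeros(n_chains)

        de = ~use_snooker
        if de.any():
            z1 = Z[z_rows[de, 0]]
            z2 = Z[z_rows[de, 1]]
            cr = rng.choice((0.25, 0.5, 1.0), size=int(de.sum()))
            mask = rng.random((int(de.sum()), d)) < cr[:, None]
            none = ~mask.any(axis=1)
            if none.any():
                cols = rng.integers(0, d, size=int(none.sum()))
                mask[np.flatnonzero(none), cols] = True
            dstar = mask.sum(axis=1)
            gamma = 2.38 / np.sqrt(2.0 * dstar)
            gamma[gamma_mode[de]] = 1.0
            step = gamma[:, None] * (z1 - z2) * mask
            step += jitter * rng.standard_normal(step.shape)
            prop[de] = X[de] + step

        if use_snooker.any():
            idx = np.flatnonzero(use_snooker)
            z = Z[z_rows[idx, 0]]
            z1 = Z[z_rows[idx, 1]]
            z2 = Z[z_rows[idx, 2]]
            e = X[idx] - z
            norm2 = np.einsum("ij,ij->i", e, e)
            ok = norm2 > 0
            gamma_s = rng.uniform(1.2, 2.2, size=len(idx))
            proj1 = np.einsum("ij,ij->i", z1, e) / np.where(ok, norm2, 1.0)
            proj2 = np.einsum("ij,ij->i", z2, e) / np.where(ok, norm2, 1.0)
            step = gamma_s[:, None] * (proj1 - proj2)[:, None] * e
            xprop = np.where(ok[:, None], X[idx] + step, X[idx])
            dist_old = np.sqrt(norm2)
            dist_new = np.linalg.norm(xprop - z, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.where(
                    ok & (dist_old > 0) & (dist_new > 0),
                    (d - 1) * (np.log(dist_new) - np.log(dist_old)),
                    0.0,
                )
            prop[idx] = xprop
            log_corr[idx] = corr

        lp_prop = np.asarray(log_posterior(prop), dtype=float)
        log_alpha = lp_prop - lp + log_corr
        accept = np.log(rng.random(n_chains)) < log_alpha
        X[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        n_accept += int(accept.sum())
        n_prop += n_chains

        if it % archive_every == 0:
            Z = np.vstack([Z, X])
        if it % thin == 0:
            kept.append(X.copy())
            kept_lp.append(lp.copy())
        if it % stagnation_window == 0:
            rate = n_accept / max(n_prop, 1)
            acc_window.append(rate)
            if rate < 0.01:
                raise StagnationError(
                    f"all chains stagnated: acceptance {rate:.4f} over the last "
                    f"{stagnation_window} iterations"
                )
            n_accept = 0
            n_prop = 0

    history = np.stack(kept, axis=1)  # (n_chains, n_kept, d)
    n_kept = history.shape[1]
    draws = history.reshape(n_chains * n_kept, d, order="F")
    chain_ids = np.tile(np.arange(n_chains), n_kept)
    logp = np.stack(kept_lp, axis=1).reshape(n_chains * n_kept, order="F")
    total_rate = float(np.mean(acc_window)) if acc_window else n_accept / max(n_prop, 1)
    arch = PosteriorArchive(
        draws=draws, chain_ids=chain_ids, log_posterior=logp, history=history,
        priors=priors, thin=thin, seed=seed, acceptance_rate=total_rate,
    )
    arch.rhat = gelman_rubin(arch)
    return arch


def gelman_rubin(archive: PosteriorArchive, discard_frac: float = 0.5) -> np.ndarray:
    """Potential scale reduction per parameter from between/within variances.

    Uses the retained (post-discard) portion of each chain's thinned
    history; requires >= 2 chains and >= 10 retained draws per chain.
    """
    hist = archive.history if isinstance(archive, PosteriorArchive) else np.asarray(archive)
    c, L, d = hist.shape
    if c < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    start = int(L * discard_frac)
    h = hist[:, start:, :]
    L = h.shape[1]
    if L < 10:
        raise ValueError("need at least 10 retained draws per chain")
    means = h.mean(axis=1)  # (c, d)
    W = h.var(axis=1, ddof=1).mean(axis=0)  # (d,)
    B = L * means.var(axis=0, ddof=1)  # (d,)
    var_hat = (L - 1) / L * W + B / L
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    # values below 1 are estimator noise; floor them
    return np.maximum(np.where(W > 0, rhat, 1.0), 1.0)


def posterior_predictive(
    archive: PosteriorArchive,
    runner,
    n_keep: int = 1000,
    rhat_threshold: float = 1.2,
    force: bool = False,
):
    """Propagate evenly thinned posterior draws through a forward runner.

    ``runner(theta) -> FlowSolution`` (typically the nonlinear hematocrit
    solver with the inferred boundary values).  Requires convergence
    (max R-hat <= threshold) unless ``force``.  Returns (solutions,
    mean_flows, empirical_dar, n_failed).
    """
    if archive.rhat is not None and not force:
        if np.nanmax(archive.rhat) > rhat_threshold:
            raise RuntimeError(
                f"archive not converged (max R-hat {np.nanmax(archive.rhat):.3f}); "
                f"pass force=True to override"
            )
    n = archive.draws.shape[0]
    idx = np.unique(np.linspace(0, n - 1, min(n_keep, n)).astype(int))
    solutions = []
    flows = []
    n_failed = 0
    for i in idx:
        try:
            sol = runner(archive.draws[i])
        except Exception:
            n_failed += 1
            continue
        solutions.append(sol)
        flows.append(sol.q)
    if not flows:
        raise RuntimeError("every posterior-predictive forward run failed")
    Q = np.stack(flows)
    mean_flows = Q.mean(axis=0)
    dar = dar_empirical(Q, axis=0) if Q.shape[0] >= 2 else np.full(Q.shape[1], np.nan)
    return solutions, mean_flows, dar, n_failed
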