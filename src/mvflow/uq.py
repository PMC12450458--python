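"""Forward uncertainty propagation and the direction agreement rate (DAR).

Because segment flows are a linear map of the boundary-value vector,
q = H b with H = M K^{-1} R, Gaussian uncertainty on a subset A of boundary
values propagates in closed form: with b_A ~ N(b_A, Sigma_A),

    q ~ N(m, Omega),   m = H_A b_A + q_B,   Omega = H_A Sigma_A H_A'.

The DAR of segment j summarizes how stable its flow direction is under that
uncertainty: DAR_j = 100 * max(P(q_j > 0), 1 - P(q_j > 0)) in percent, 100
meaning a fully stable direction and 50 maximal instability.  Under the
Gaussian law P(q_j > 0) = Phi(m_j / sigma_j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla
from scipy.stats import norm

from mvflow.solver import SystemMatrices


@dataclass
class BoundaryPartition:
    """Boundary nodes under study (A) and the untouched complement (B)."""

    A: np.ndarray  # node array positions under study
    B: np.ndarray  # complement boundary node positions

    @classmethod
    def from_system(cls, sys: SystemMatrices, A) -> "BoundaryPartition":
        A = np.asarray(A, dtype=int)
        boundary = np.flatnonzero(sys.node_kind != "interior")
        if not np.all(np.isin(A, boundary)):
            raise ValueError("A must contain boundary (condition-bearing) nodes only")
        B = np.setdiff1d(boundary, A)
        return cls(A=A, B=B)


@dataclass
class FlowDistribution:
    """Gaussian (or ensemble) distribution over segment flows."""

    mean: np.ndarray  # um^3/s
    sd: np.ndarray  # um^3/s
    dar: np.ndarray  # percent, in [50, 100]
    cov: np.ndarray | None = None  # m x m, optional


def influence_matrix(sys: SystemMatrices, A) -> np.ndarray:
    """Columns of H = M K^{-1} R restricted to the node positions in ``A``.

    Column for node a solves K x = R e_a and applies M; the result maps a
    unit change of b[a] to the change of every segment flow.
    """
    A = np.asarray(A, dtype=int)
    lu = spla.splu(sys.K.tocsc())
    rhs = np.asarray(sys.R[:, A].todense())
    X = lu.solve(rhs)
    return np.asarray(sys.M @ X)


def propagate(
    H_A: np.ndarray,
    b_A: np.ndarray,
    var_A: np.ndarray,
    q_B: np.ndarray,
    full_cov: bool = False,
    Sigma_A: np.ndarray | None = None,
) -> FlowDistribution:
    """Gaussian propagation through the linear flow model.

    ``var_A`` is the diagonal of Sigma_A (mmHg^2); a full covariance can be
    supplied through ``Sigma_A`` instead (extension hook, diagonal is the
    studied configuration).  ``q_B`` is the flow contribution of the fixed
    boundary values, so mean = H_A b_A + q_B equals the deterministic
    solution.
    """
    var_A = np.asarray(var_A, dtype=float)
    if np.any(var_A < 0):
        raise ValueError("variances must be nonnegative")
    mean = H_A @ np.asarray(b_A, dtype=float) + np.asarray(q_B, dtype=float)
    if Sigma_A is not None:
        cov = H_A @ Sigma_A @ H_A.T
        var = np.diag(cov)
    else:
        var = (H_A**2) @ var_A
        cov = (H_A * var_A) @ H_A.T if full_cov else None
    sd = np.sqrt(np.maximum(var, 0.0))
    return FlowDistribution(mean=mean, sd=sd, dar=dar_analytic(mean, sd), cov=cov)


def dar_analytic(mean, sd):
    """DAR (%) under the Gaussian flow law.

    P = Phi(m/sigma); DAR = 100 max(P, 1-P).  Limits: sigma -> 0 with m != 0
    gives exactly 100; m = 0 gives exactly 50.
    """
    m = np.asarray(mean, dtype=float)
    s = np.asarray(sd, dtype=float)
    if np.any(s < 0):
        raise ValueError("standard deviations must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, m / np.where(s > 0, s, 1.0), np.inf * np.sign(m))
    z = np.where((s == 0) & (m == 0), 0.0, z)
    p = norm.cdf(z)
    out = 100.0 * np.maximum(p, 1.0 - p)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def dar_empirical(samples: np.ndarray, axis: int = 0):
    """DAR (%) from an ensemble of flow realizations.

    The majority sign defines the predominant direction; exact zeros are
    counted with the majority.  All-zero ensembles have no direction and
    return NaN.
    """
    s = np.sign(np.asarray(samples, dtype=float))
    n = s.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 samples")
    pos = np.sum(s > 0, axis=axis)
    neg = np.sum(s < 0, axis=axis)
    zero = n - pos - neg
    with np.errstate(invalid="ignore"):
        frac = (np.maximum(pos, neg) + zero) / n
    out = np.where(pos + neg == 0, np.nan, 100.0 * frac)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def summarize_by_group(
    values: np.ndarray,
    layers: np.ndarray,
    generations: np.ndarray,
) -> pd.DataFrame:
    """Median and [12.5, 87.5] / [5, 95] percentile bands per (layer, generation).

    One row per nonempty cell with the segment count.
    """
    df = pd.DataFrame({"layer": layers, "generation": generations, "value": values})
    rows = []
    for (ell, gen), grp in df.groupby(["layer", "generation"]):
        v = grp["value"].to_numpy()
        rows.append(
            {
                "layer": ell,
                "generation": gen,
                "count": len(v),
                "median": float(np.median(v)),
                "p12_5": float(np.percentile(v, 12.5)),
                "p87_5": float(np.percentile(v, 87.5)),
                "p5": float(np.percentile(v, 5)),
                "p95": float(np.percentile(v, 95)),
            }
        )
    return pd.DataFrame(rows)


def monte_carlo_flows(
    sys: SystemMatrices,
    A: np.ndarray,
    var_A: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    batch: int = 2000,
) -> np.ndarray:
    """Flows from repeated linear solves under perturbed boundary values.

    Draws b_A ~ N(b_A, diag(var_A)) and re-solves K p = R b for every draw
    (factorized once); the empirical ensemble is the sampling oracle for the
    closed-form propagation.  Returns (n_samples, m).
    """
    lu = spla.splu(sys.K.tocsc())
    sd = np.sqrt(np.asarray(var_A, dtype=float))
    out = np.empty((n_samples, sys.M.shape[0]))
    done = 0
    while done < n_samples:
        k = min(batch, n_samples - done)
        bmat = np.tile(sys.b[:, None], (1, k))
        bmat[A, :] += sd[:, None] * rng.standard_normal((len(A), k))
        P = lu.solve(np.asarray(sys.R @ bmat))
        out[done:done + k] = (sys.M @ P).T
        done += k
    return out
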