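# mvflow

Steady-state blood-flow simulation, boundary-condition handling, and
uncertainty quantification for microvascular networks.

Imaged microvascular volumes are cut out of larger tissue, so hundreds to
thousands of vessels end at the domain boundary, and the simulated flow
field depends strongly on the pressures imposed at those cut vessels —
which are almost never measured.  `mvflow` is built for people who run
Poiseuille-type network simulations (cortical angiograms, mesentery,
synthetic capillary beds) and need to (i) impose defensible pressure
boundary conditions without hand-picking absolute pressure levels, (ii)
quantify how boundary-pressure uncertainty propagates into flow
predictions, and (iii) infer unknown boundary pressures from sparse
velocity and flow-direction data.

## The model

Flow in a network of `m` cylindrical segments and `n` nodes follows
Poiseuille's law, `q = M p`, where `M` holds segment hydraulic conductances
`G = π d⁴ / (128 μ_eff L)` and the effective viscosity `μ_eff(d, H_D)`
comes from empirical in-vitro / in-vivo / endothelial-surface-layer laws
(the Fåhræus–Lindqvist effect).  Mass conservation at interior nodes plus
boundary conditions close the sparse linear system

```
K p = R b,    K = L·M + J + N .
```

Three boundary-condition kinds are supported at the degree-1 boundary
nodes:

* **pressure** — a conventional Dirichlet value (mmHg);
* **flow** — an imposed inflow (μm³/s);
* **relative pressure** (adaptive) — the boundary pressure is tied to a
  weighted mean of interior reference-node pressures plus a deviation:
  `p_i = Σ_s w_{i,s} p_s + Δp_i`.  The reference groups are layer-wise sets
  of interior capillary nodes, so boundary pressures inherit the interior
  pressure level of their cortical depth instead of requiring an absolute
  declaration.  A sparsity-preserving grouped encoding makes this scalable
  when many boundary nodes share a reference group.

On top of the linear solver:

* **Nonlinear hematocrit coupling** — red cells split disproportionately at
  diverging bifurcations (plasma skimming, logit split law), hematocrit
  feeds back on viscosity, and the coupled fixed point is solved by an
  adaptively relaxed iteration.
* **Forward UQ** — flows are linear in the boundary values, `q = H b` with
  `H = M K⁻¹ R`, so Gaussian boundary uncertainty propagates in closed
  form: `Ω = H_A Σ_A H_Aᵀ`.  The **direction agreement rate**
  `DAR = 100·max(P, 1−P)` with `P = Φ(m_j/σ_j)` summarizes how stable each
  segment's flow direction is (100 = fully stable, 50 = coin flip).
* **Bayesian calibration** — unknown boundary pressures (conventional and
  relative) get scaled-beta priors and are sampled with an archive-based
  differential-evolution MCMC (snooker updates, Gelman–Rubin diagnostics),
  against Gaussian velocity targets and probit flow-direction targets;
  posterior draws are then propagated through the nonlinear model.
* **Path analysis** — flow-proportional random walks from surface
  arterioles to surface venules, retained when they follow
  SA → DA+A → C → AV+V → SV, yield depth-resolved pressure-drop profiles
  and capillary entry/exit depth fits.
* **Synthetic networks** — a seeded generator of cortical-like fixtures
  (penetrating trunks + irregular capillary bed, six 200 μm analysis
  layers, boundary stubs on lateral/bottom faces) so everything above is
  testable without downloading imaging data.

## Worked example

```python
import numpy as np
import mvflow as mv
from mvflow.rheology import effective_viscosity
from mvflow.solver import assemble, solve
from mvflow.synth import (SynthSpec, generate_network, standard_bcs,
                          sample_relative_bcs, PRESSURE_RANGES)
from mvflow.uq import influence_matrix, propagate

net = generate_network(SynthSpec(seed=1))
print(f"network: {net.n} nodes, {net.m} segments, "
      f"{net.is_boundary.sum()} boundary nodes")

# conventional pressures at arteriole/venule stumps, adaptive (relative)
# conditions at capillary/UNK stumps with deviations ~ N(0, 4 mmHg)
rng = np.random.default_rng(0)
pressures = {int(net.node_ids[i]): rng.uniform(*PRESSURE_RANGES[net.node_categories[i]])
             for i in np.flatnonzero(net.is_boundary)
             if net.node_categories[i] in PRESSURE_RANGES}
cap_nodes = [int(net.node_ids[i]) for i in np.flatnonzero(net.is_boundary)
             if net.node_categories[i] in ("C", "UNK")]
bcs, groups = standard_bcs(net, pressures, sample_relative_bcs(cap_nodes, sd=4.0, seed=1))

mu = effective_viscosity(net.diameters, np.full(net.m, 0.40), mv.ViscosityModel())
sys = assemble(net, mu, bcs, groups)
sol = solve(sys)
print(f"pressure range: {sol.p.min():.1f} to {sol.p.max():.1f} mmHg")

# propagate 4 mmHg boundary-pressure uncertainty into flow-direction stability
A = np.array([net.node_index[n] for n in cap_nodes])
H = influence_matrix(sys, A)
dist = propagate(H, sys.b[A], np.full(len(A), 4.0**2), sol.q - H @ sys.b[A])
print(f"median DAR: {np.median(dist.dar):.1f}%, "
      f"fraction of segments with DAR > 90%: {np.mean(dist.dar > 90):.2f}")
```

prints

```
network: 463 nodes, 535 segments, 169 boundary nodes
pressure range: 8.2 to 62.7 mmHg
median DAR: 92.2%, fraction of segments with DAR > 90%: 0.53
```

The pressure range brackets realistic arteriolar-to-venular levels; half
the segments keep a stable flow direction (DAR > 90 %) under 4 mmHg of
boundary-pressure uncertainty, and instability concentrates in low
generation (boundary-adjacent) segments — `mvflow.uq.summarize_by_group`
tabulates that depth/generation pattern.

The same pipelines are scriptable from the shell:

```bash
mvflow generate --seed 1 --out out/
mvflow uq --config run.yaml --seed 7 --out out/
mvflow calibrate --seed 1 --out out/
mvflow paths --config run.yaml --out out/
```

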