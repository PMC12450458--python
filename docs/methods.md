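# Methods

## Governing equations and units

Blood is treated as an equivalent continuum fluid in a graph of `m`
cylindrical segments joining `n` nodes.  Segment flows are linear in node
pressures, `q = M p`, with per-segment hydraulic conductance
`G = π d⁴ / (128 μ_eff L)`.  Internally all lengths are μm, pressures
mmHg, viscosities cP, and time s; with the conversions
1 mmHg = 133.322 Pa and 1 cP = 10⁻³ Pa·s, flows come out in μm³/s
(reported also as nL/min = μm³/s × 60/10⁶).  Velocities are reported in
mm/s and wall shear stress in dyn/cm² (τ = 32 μ_eff |q| / (π d³), equal to
d·Δp/(4L)).

Mass conservation at interior nodes plus one row per boundary node closes
the sparse system `K p = R b` with `K = L·M + J + N`:

* interior rows of `L·M` encode zero net flow;
* pressure-condition rows are identity rows of `J` with `b_i` the imposed
  pressure;
* flow-condition rows keep the `L·M` form with `b_i` the imposed inflow
  (positive into the network);
* relative (adaptive) pressure rows read `p_i − Σ_s w_{i,s} p_s = Δp_i`,
  encoded as `J_ii = 1`, `N_{i,s} = −w_{i,s}`, `b_i = Δp_i`.

At least one conventional pressure condition is required per connected
component; without it the system determines pressures only up to a
constant and assembly refuses to continue.

**Grouped encoding.** When many boundary nodes share one reference group,
the dense reference rows would destroy sparsity.  One designated
representative per group keeps the full row
`p_rep − Σ w_s p_s = Δp_rep`; every other member `i` carries the
two-nonzero row `p_i − p_rep = Δp_i − Δp_rep`, with `R` combining the two
deviations.  The encodings are algebraically identical; the test suite
verifies agreement to 10⁻¹⁰ relative in pressures and flows.

**Numerics.** The system is solved by sparse LU (SuperLU) followed by two
steps of iterative refinement.  Refinement matters because conservation
rows carry conductances of order 10⁴–10⁶ while boundary rows are O(1);
without it the adaptive-condition identity holds only to ~10⁻⁹ mmHg,
with it to machine precision.  Interior mass-conservation residuals are
checked against 10⁻⁸ of the peak flow after every solve.

## Rheology

The empirical viscosity laws are transcribed from the Pries et al.
formulations that the field uses for network simulation:

* **in vitro** (1992 fit): `η₄₅(d) = 220 e^{−1.3d} + 3.2 − 2.44 e^{−0.06 d^{0.645}}`
  with the shape exponent `C(d)` shared by all laws and the hematocrit
  dependence `1 + (η₄₅ − 1)·((1−H_D)^C − 1)/((0.55)^C − 1)`;
* **in vivo** (1994 fit): same structure with
  `η₄₅ = 6 e^{−0.085d} + 3.2 − 2.44 e^{−0.06 d^{0.645}}` and the
  `(d/(d−1.1))²` wall factors;
* **ESL** (2004/2005): the in-vitro law evaluated at the effective
  diameter `d_eff = d − 2 w(d)` of the endothelial-surface-layer model
  (parameters d_off = 2.4 μm, d_crit = 10.5 μm, D₅₀ = 100 μm,
  E_amp = 1.1, E_width = 0.03, E_peak = 0.6, w_max = 2.6 μm).

`relative_viscosity()` returns the hematocrit-dependence law, which is 1
at `H_D = 0` for all three laws.  The lumen-narrowing factors of the
in-vivo law (the outer `(d/(d−1.1))²`) and of the ESL model (`(d/d_eff)⁴`)
are geometric conductance effects; they are folded into
`effective_viscosity()` — the conductance-equivalent viscosity referred to
the physical diameter stored in the data model — so the Poiseuille formula
applied to the physical diameter yields the narrowed lumen's conductance.
The physics entering the flow solve is the full cited law.

For mouse networks the human-fitted laws are evaluated at the
MCV-adjusted diameter `d·(MCV_ref/MCV_actual)^{1/3}` (defaults 92 fL
human, 45 fL mouse): cube-root volume scaling maps the vessel diameter to
a red-cell-size-relative scale.  Plasma viscosity defaults to 1.2 cP.

The Fåhræus relation
`H_T/H_D = H_D + (1−H_D)(1 + 1.7 e^{−0.415d} − 0.6 e^{−0.011d})` converts
bulk to red-blood-cell velocity (`v_RBC = v_bulk · H_D/H_T`).

**Phase separation** at a diverging bifurcation follows the 1989 logit
law: with `FQ_B` the blood-flow fraction entering daughter α,

```
logit FQ_E = A + B · logit((FQ_B − X0)/(1 − 2·X0))
A = −6.96 ln(d_α/d_β)/d_p,  B = 1 + 6.98 (1−H_D)/d_p,  X0 = 0.4/d_p ,
```

with `FQ_E = 0` below the plasma-skimming threshold `X0` and 1 above
`1 − X0`.  Daughter fluxes always sum to the parent flux (the swap
`α ↔ β` maps `FQ_E → 1 − FQ_E` exactly).  Branchings with more than two
outgoing segments are split recursively in descending daughter-flow
order, the remainder aggregated as a pseudo-daughter of area-preserving
diameter `√(Σ d_i²)`; nodes of degree > 3 are rare in real capillary beds
and in the default generator output.

## Hematocrit fixed point

The coupled flow/phase-separation/viscosity problem is solved by
fixed-point iteration: evaluate conductances at current `H_D`, solve the
linear system, propagate hematocrit downstream along current flow
directions (boundary inflow segments carry the configured inlet `H_D`,
default 0.40; converging nodes mix by flux-weighted average; diverging
nodes apply the split law; flow cycles fall back on previous-iteration
values), then update with per-segment relaxation.  Two numerical choices
matter:

* **Per-segment sign-adaptive relaxation.**  The factor (initial 0.5) is
  halved (floor 0.02) for a segment whose update flips sign on consecutive
  iterations and grown by 1.1× (cap 1.0) while updates stay monotone.
  A single global factor stalls: oscillatory local modes need damping
  while slow near-neutral modes need full steps.
* **Flow-scale-relative zero-flow threshold.**  Segments with
  `|q| < max(threshold_abs, 10⁻⁶·max|q|)` keep their previous hematocrit
  and are excluded from splits.  Split fractions are undefined at zero
  flow, and stagnant vessels otherwise flip direction on solver noise
  every iteration and pin the residual.

Convergence is declared when the un-relaxed update falls below the
tolerance (default 10⁻⁶ in `H_D`) and verified by one final un-relaxed
propagation pass, which also restores exact red-cell flux conservation
with respect to the final flow field (checked to 10⁻⁸ relative).
Residual decrease is *not* monotone and is not asserted.

A genuine limitation, not an implementation artifact: on strongly looped,
symmetric capillary topologies the coupled model can have no stable steady
state — the iteration settles into sustained limit cycles, consistent with
the known oscillatory solutions of this model class on symmetric networks.
The solver then raises an error carrying the residual trajectory, and
ensemble pipelines log and exclude such draws.  The synthetic generator's
default irregular bed avoids the pathological symmetric-lattice regime.

## Forward uncertainty quantification

Because `q = H b` with `H = M K⁻¹ R`, splitting the boundary nodes into a
studied set A and fixed complement B gives `q = H_A b_A + q_B`.  With
Gaussian uncertainty `b_A ~ N(b_A, Σ_A)` (Σ_A diagonal in the studied
configuration; a full covariance is accepted as an extension hook),

```
q ~ N(m, Ω),   m = H_A b_A + q_B,   Ω = H_A Σ_A H_Aᵀ .
```

`H_A` columns are computed by factorized solves `K x = R e_a`.  Only
per-segment variances are formed unless the full Ω is requested.  The
default boundary-pressure standard deviation is 4 mmHg, applied to the
capillary and unknown-category boundary nodes — the forward-UQ study
configuration.

The **direction agreement rate** is `DAR_j = 100·max(P_j, 1−P_j)` with
`P_j = Φ(m_j/σ_j)`; `σ_j = 0, m_j ≠ 0` gives exactly 100 and `m_j = 0`
exactly 50.  The empirical counterpart counts the fraction of ensemble
realizations matching the majority sign; exact zeros count with the
majority (documented tie rule; an all-zero ensemble has no direction and
returns NaN).  Analytic and empirical DAR agree within binomial sampling
error on Gaussian ensembles, and both are invariant to flipping a
segment's stored orientation.

Group summaries report medians with [12.5, 87.5] and [5, 95] percentile
bands per (analysis layer, generation) cell.

## Bayesian calibration

Unknown boundary values θ (conventional pressures for arteriole/venule
stumps, deviations Δp for capillary/UNK stumps, all mmHg) get scaled and
shifted beta priors; Δp priors are centered at zero.  The likelihood
combines

* Gaussian residuals on target red-cell *speeds* (default noise sd
  0.5 mm/s), so a velocity target does not constrain the sign, and
* a smooth probit direction penalty `log Φ(sign·v/v_scale)` (default
  v_scale 0.1 mm/s) that saturates once the direction is satisfied at a
  margin.

Both terms are pluggable.  During calibration a uniform discharge
hematocrit (0.40) fixes conductances, so target velocities are an affine
map of θ; the forward model precomputes the influence-matrix restriction
to target segments once, and each likelihood evaluation is a small
matrix-vector product.  This is an exact reformulation of the linear
calibration stage, not an approximation.  Posterior draws are subsequently
propagated through the nonlinear phase-separation model (the two-step
scheme: linear calibration, then nonlinear posterior-predictive
propagation; calibration itself never invokes the hematocrit iteration).

**Sampler.**  An archive-based differential-evolution MCMC: five parallel
chains propose jumps `γ·(z_{r1} − z_{r2})` from differences of states
drawn from a growing archive of past states (initialized with 10·dim
prior draws, extended with the chain states every 10 iterations), with
per-proposal random coordinate subsets (crossover 0.25/0.5/1.0),
`γ = 2.38/√(2 d*)` (10 % of proposals use γ = 1 for mode jumping), a
small jitter of 10⁻⁶ of the prior width, and 10 % snooker updates along
the direction to an archive state with the `(‖x*−z‖/‖x−z‖)^{d−1}`
acceptance correction.  Archive-based differences keep a handful of
chains effective in ~60 dimensions, where population-difference proposals
from five chains alone would be confined to a four-dimensional subspace.
The sampler is deterministic under a fixed seed, is verified against a
known Gaussian posterior and against prior recovery under a flat
likelihood (KS test), and reports the per-parameter Gelman–Rubin
potential scale reduction (between/within-chain variances on the second
half of the thinned history, floored at 1; convergence threshold 1.2).

The desk-scale default is 5 chains × 20 000 iterations with thinning 10.
On the bundled recovery fixture (~60 unknown boundary pressures,
noise-free targets) this reaches R̂ ≤ 1.05 for all parameters and
posterior means within 2 posterior standard deviations of the truth for
well over 90 % of parameters.  Most Δp parameters are weakly informed by
design — direction targets constrain sums of flows, not individual
stumps — so their posteriors are honest, prior-dominated credible
intervals rather than point identifications.

## Path tracking

Flow paths are sampled by random walks from surface-arteriole boundary
nodes carrying inflow, choosing each outgoing segment with probability
proportional to its flow, so a walk's product of branch fractions is the
fraction of inlet flow following exactly that route; the path weight is
the inlet flow times that product.  Duplicate walks (identical segment
sequences) collapse to one path keeping that deterministic weight, and
the weights of all distinct complete paths from one inlet sum to the
inlet flow.  Retention requires the category sequence
SA → DA+A → C → AV+V → SV (consecutive duplicates collapsed, UNK
segments transparent), with at most two deviating transitions — category
changes that neither stay at nor advance the canonical stage.  Walks
exceeding the cycle-guard length are discarded and counted.

Pressure-drop profiles aggregate per-category drops per path, grouped by
the analysis layer of the first capillary segment, with flow-weighted
medians and [12.5, 87.5]/[5, 95] bands.  Weighted percentiles use
expanded-sample semantics (equivalent to repeating each value
weight-many times and applying the standard linear-interpolation
percentile; exact for integer weights, continuous in the weights).  The
capillary entry/exit depth relation `z_out ~ z_in` is fitted by weighted
least squares solved in closed form from the 2×2 normal equations; the
fit is flagged NaN when all entry depths coincide.  Per-path DAR
averages segment DARs within each category stretch.

## Synthetic networks

The generator emulates the structural features of cortical
penetrating-vessel networks at desk scale — not their morphometric
statistics.  Nodes sit on an nx × ny × nz grid (default 7 × 7 × 6,
lateral spacing 100 μm) spanning six 200 μm analysis layers down to
1.2 mm.  Penetrating arteriole and venule trunks occupy interior columns
(default 2 + 2), taper 25 → 10 μm with depth (inside the < 30 μm range
covered by awake-mouse velocity measurements, so surface vessels are
eligible velocity-target sites), venules 1.15× wider, and end in SA/SV
boundary nodes at the pial surface.  The capillary bed is a seeded random
spanning structure over the grid plus a fraction (default 0.2) of
loop-closing edges; capillary diameters are Normal(4, 1) μm truncated at
2 μm.  Boundary stubs (length 50 μm, 20 % labeled UNK) attach to
lateral- and bottom-face nodes — never the pial face — and are the
degree-1 boundary nodes.  Output is deterministic in (spec, seed).

What passing tests on these fixtures does *not* show: real angiograms
have tortuous segments, heavy-tailed diameter and length distributions,
mixed-category nodes, labeling errors, and orders of magnitude more
vessels; the generator makes no claim to reproduce layer-wise vessel
densities or real boundary-pressure correlations.  It provides networks
on which every contract of the solver stack is exactly checkable.

Fixture conventions for boundary values: SA 50–70, DA+A 40–60, AV+V
10–25, SV 8–20 mmHg (class-wise plausible cortical ranges), relative
deviations ±12 mmHg, truth drawn from Beta(2, 2) on those ranges; the
relative-condition sampler draws i.i.d. N(0, 4 mmHg) deviations.

## Problem sizes

Default test/acceptance scales, chosen as desk-scale study conditions:
synthetic networks of ~500–900 segments; 10⁵ Monte-Carlo draws for the
UQ and sampler-calibration checks; calibration with 5 chains × 2×10⁴
iterations on ~60 parameters (the production-scale analogue of this
design runs millions of iterations on thousands of parameters; the
sampler and encodings are the same, only the budget differs).

## Known limitations

* No transient/pulsatile flow, vessel compliance, or oxygen transport.
* Hematocrit limit cycles on strongly looped symmetric topologies (see
  above) are reported as non-convergence rather than resolved in time.
* Σ_A off-diagonal structure is accepted but untested against any
  reference; the studied configuration is diagonal.
* The likelihood's noise model is a pragmatic default (Gaussian speeds +
  probit directions), deliberately pluggable rather than canonical.
* Node categories are taken as given input; no re-categorization of
  mixed-category junction nodes is attempted.
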