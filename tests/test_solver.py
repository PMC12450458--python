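import numpy as np
import pytest

from mvflow.network import NetworkValidationError
from mvflow.rheology import hydraulic_conductance
from mvflow.solver import (
    BoundaryCondition,
    ReferenceGroup,
    apply_grouped_encoding,
    assemble,
    derived_quantities,
    enforce_adaptive_identity_check,
    interior_residual,
    solve,
)

from conftest import make_net

MU = np.array


def visc(net, value=1.2):
    return np.full(net.m, value)


class TestAssembly:
    def test_hand_assembled_chain(self, two_segment_series):
        net = two_segment_series
        bcs = [BoundaryCondition(0, "pressure", 100.0),
               BoundaryCondition(2, "pressure", 0.0)]
        sys = assemble(net, visc(net), bcs)
        g = hydraulic_conductance(8.0, 100.0, 1.2)
        K = sys.K.toarray()
        assert K[0].tolist() == [1, 0, 0]
        assert K[2].tolist() == [0, 0, 1]
        assert np.allclose(K[1], [-g, 2 * g, -g])
        assert sys.b.tolist() == [100.0, 0.0, 0.0]

    def test_missing_condition_rejected(self, two_segment_series):
        with pytest.raises(NetworkValidationError, match="no boundary condition"):
            assemble(two_segment_series, visc(two_segment_series),
                     [BoundaryCondition(0, "pressure", 100.0)])

    def test_no_pressure_anchor_rejected(self, two_segment_series):
        net = two_segment_series
        groups = {1: ReferenceGroup(1, node_ids=np.array([1]))}
        bcs = [BoundaryCondition(0, "relative_pressure", 1.0, reference=1),
               BoundaryCondition(2, "relative_pressure", -1.0, reference=1)]
        with pytest.raises(NetworkValidationError, match="anchor"):
            assemble(net, visc(net), bcs, groups)

    def test_relative_row_nonzero_count(self, chain4):
        net = chain4
        groups = {1: ReferenceGroup(1, node_ids=np.array([1, 2, 3]))}
        bcs = [BoundaryCondition(0, "pressure", 50.0),
               BoundaryCondition(4, "relative_pressure", 2.0, reference=1)]
        sys = assemble(net, visc(net), bcs, groups)
        i = net.node_index[4]
        row = sys.K.getrow(i)
        assert row.nnz == 3 + 1  # |N_i| reference weights + unit diagonal
        assert sys.K[i, i] == 1.0
        for s, w in zip([1, 2, 3], [1 / 3] * 3):
            assert sys.K[i, net.node_index[s]] == pytest.approx(-w)

    def test_empty_reference_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ReferenceGroup(1, node_ids=np.array([], dtype=int))


class TestSolve:
    def test_series_midpoint_pressure(self, two_segment_series):
        net = two_segment_series
        bcs = [BoundaryCondition(0, "pressure", 100.0),
               BoundaryCondition(2, "pressure", 0.0)]
        sol = solve(assemble(net, visc(net), bcs))
        assert sol.p[1] == pytest.approx(50.0)
        assert sol.q[0] == pytest.approx(sol.q[1])

    def test_pressure_shift_invariance(self, y_junction):
        net = y_junction
        bcs = [BoundaryCondition(0, "pressure", 80.0),
               BoundaryCondition(1, "pressure", 40.0),
               BoundaryCondition(2, "pressure", 20.0)]
        sol = solve(assemble(net, visc(net), bcs))
        shifted = [BoundaryCondition(b.node_id, b.kind, b.value + 10.0) for b in bcs]
        sol2 = solve(assemble(net, visc(net), shifted))
        assert np.allclose(sol2.p, sol.p + 10.0)
        assert np.allclose(sol2.q, sol.q)

    def test_y_junction_mean_pressure(self, y_junction):
        net = y_junction
        bcs = [BoundaryCondition(0, "pressure", 80.0),
               BoundaryCondition(1, "pressure", 40.0),
               BoundaryCondition(2, "pressure", 20.0)]
        sol = solve(assemble(net, visc(net), bcs))
        # equal conductances: junction pressure is the mean of the ends
        assert sol.p[3] == pytest.approx((80 + 40 + 20) / 3)

    def test_flow_boundary_condition(self, two_segment_series):
        net = two_segment_series
        inflow = 5000.0  # um^3/s into the network
        bcs = [BoundaryCondition(0, "flow", inflow),
               BoundaryCondition(2, "pressure", 10.0)]
        sol = solve(assemble(net, visc(net), bcs))
        assert sol.q[0] == pytest.approx(inflow)
        assert sol.q[1] == pytest.approx(inflow)

    def test_mass_conservation(self, y_junction):
        net = y_junction
        bcs = [BoundaryCondition(0, "pressure", 80.0),
               BoundaryCondition(1, "pressure", 40.0),
               BoundaryCondition(2, "pressure", 20.0)]
        sys = assemble(net, visc(net), bcs)
        sol = solve(sys)
        assert interior_residual(sys, sol.q) <= 1e-8 * np.max(np.abs(sol.q))

    def test_resolve_after_segment_removal(self, chain4):
        net = chain4
        bcs = [BoundaryCondition(0, "pressure", 100.0),
               BoundaryCondition(4, "pressure", 0.0)]
        sol = solve(assemble(net, visc(net), bcs))
        # halve one conductance by raising its viscosity and re-solve: flows
        # must change (no stale factorization reuse)
        mu = visc(net)
        mu[1] *= 2
        sol2 = solve(assemble(net, mu, bcs))
        assert not np.allclose(sol2.q, sol.q)
        assert sol2.p[0] == pytest.approx(100.0)


class TestAdaptiveConditions:
    def _relative_setup(self, chain4, dp):
        net = chain4
        groups = {1: ReferenceGroup(1, node_ids=np.array([2]))}
        bcs = [BoundaryCondition(0, "pressure", 60.0),
               BoundaryCondition(4, "relative_pressure", dp, reference=1)]
        sys = assemble(net, visc(net), bcs, groups)
        return net, sys, solve(sys)

    def test_single_reference_deviation(self, chain4):
        net, sys, sol = self._relative_setup(chain4, 5.0)
        assert sol.p[net.node_index[4]] - sol.p[net.node_index[2]] == pytest.approx(5.0)
        assert enforce_adaptive_identity_check(sol, sys) <= 1e-9

    def test_zero_deviation_equals_group_mean(self, chain4):
        net, sys, sol = self._relative_setup(chain4, 0.0)
        assert sol.p[net.node_index[4]] == pytest.approx(sol.p[net.node_index[2]])

    def test_random_deviations_identity_residual(self):
        from mvflow.synth import SynthSpec, generate_network, standard_bcs, sample_relative_bcs
        net = generate_network(SynthSpec(seed=7))
        rng = np.random.default_rng(0)
        from mvflow.synth import PRESSURE_RANGES
        pressures = {
            int(net.node_ids[i]): rng.uniform(*PRESSURE_RANGES[net.node_categories[i]])
            for i in np.flatnonzero(net.is_boundary)
            if net.node_categories[i] in PRESSURE_RANGES
        }
        dev = sample_relative_bcs(
            [int(net.node_ids[i]) for i in np.flatnonzero(net.is_boundary)
             if net.node_categories[i] in ("C", "UNK")], sd=4, seed=1)
        bcs, groups = standard_bcs(net, pressures, dev)
        sys = assemble(net, visc(net), bcs, groups)
        sol = solve(sys)
        assert enforce_adaptive_identity_check(sol, sys) < 1e-9


class TestGroupedEncoding:
    def _shared_group_system(self, seed=4):
        from mvflow.synth import (
            SynthSpec, generate_network, sample_relative_bcs, PRESSURE_RANGES,
        )
        from mvflow.network import select_reference_groups
        net = generate_network(SynthSpec(seed=seed))
        groups_pos = select_reference_groups(net)
        shared = ReferenceGroup(1, node_ids=net.node_ids[groups_pos[3]])
        rng = np.random.default_rng(seed)
        bcs = []
        for i in np.flatnonzero(net.is_boundary):
            nid = int(net.node_ids[i])
            cat = net.node_categories[i]
            if cat in PRESSURE_RANGES:
                bcs.append(BoundaryCondition(nid, "pressure",
                                             rng.uniform(*PRESSURE_RANGES[cat])))
            else:
                bcs.append(BoundaryCondition(nid, "relative_pressure",
                                             rng.normal(0, 4), reference=1))
        sys = assemble(net, visc(net), bcs, {1: shared})
        return net, sys, {1: shared}

    def test_grouped_equals_ungrouped(self):
        net, sys, groups = self._shared_group_system()
        sol = solve(sys)
        gsys = apply_grouped_encoding(sys, groups)
        gsol = solve(gsys)
        pscale = np.max(np.abs(sol.p))
        qscale = np.max(np.abs(sol.q))
        assert np.max(np.abs(gsol.p - sol.p)) <= 1e-10 * pscale
        assert np.max(np.abs(gsol.q - sol.q)) <= 1e-10 * qscale

    def test_sparsity_gain(self):
        net, sys, groups = self._shared_group_system()
        gsys = apply_grouped_encoding(sys, groups)
        n_members = len(sys.group_of)
        group_size = len(groups[1].node_ids)
        assert sys.N.nnz == n_members * group_size
        assert gsys.N.nnz == group_size + (n_members - 1)
        assert gsys.K.nnz < sys.K.nnz

    def test_single_member_group_identical(self, chain4):
        net = chain4
        groups = {1: ReferenceGroup(1, node_ids=np.array([2]))}
        bcs = [BoundaryCondition(0, "pressure", 60.0),
               BoundaryCondition(4, "relative_pressure", 3.0, reference=1)]
        sys = assemble(net, visc(net), bcs, groups)
        gsys = apply_grouped_encoding(sys, groups)
        assert (gsys.N != sys.N).nnz == 0
        assert (gsys.R != sys.R).nnz == 0


class TestDerivedQuantities:
    def test_zero_flow(self, two_segment_series):
        net = two_segment_series
        bcs = [BoundaryCondition(0, "pressure", 10.0),
               BoundaryCondition(2, "pressure", 10.0)]
        sol = solve(assemble(net, visc(net), bcs))
        sol = derived_quantities(sol, net, visc(net))
        assert np.allclose(sol.velocity, 0)
        assert np.allclose(sol.wall_shear_stress, 0)

    def test_velocity_diameter_scaling(self):
        net = make_net(
            [(0, 0, 0, 0, "C", True), (1, 100, 0, 0, "C", False),
             (2, 200, 0, 0, "C", True)],
            [(0, 0, 1, 10.0, 100.0, "C"), (1, 1, 2, 5.0, 100.0, "C")],
        )
        bcs = [BoundaryCondition(0, "pressure", 50.0),
               BoundaryCondition(2, "pressure", 0.0)]
        sol = solve(assemble(net, visc(net), bcs))
        sol = derived_quantities(sol, net, visc(net))
        # same q through both; half the diameter gives 4x the velocity
        assert sol.velocity[1] == pytest.approx(4 * sol.velocity[0])

    def test_shear_stress_arithmetic(self, two_segment_series):
        net = two_segment_series
        bcs = [BoundaryCondition(0, "pressure", 100.0),
               BoundaryCondition(2, "pressure", 0.0)]
        mu = visc(net, 2.0)
        sol = solve(assemble(net, mu, bcs))
        sol = derived_quantities(sol, net, mu)
        q, d = abs(sol.q[0]), 8.0
        expected_pa = 32 * 2.0e-3 * q / (np.pi * d**3)
        assert sol.wall_shear_stress[0] == pytest.approx(expected_pa * 10.0)
        # cross-check: tau = d |dp| / (4 L)
        dp_pa = abs(sol.p[0] - sol.p[1]) * 133.322
        assert sol.wall_shear_stress[0] == pytest.approx(d * dp_pa / (4 * 100.0) * 10, rel=1e-9)
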