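import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import kstest, norm

from mvflow.calibrate import (
    CalibrationTarget,
    LinearForwardModel,
    PosteriorArchive,
    PriorSpec,
    build_velocity_targets,
    gelman_rubin,
    log_likelihood,
    log_prior,
    posterior_predictive,
    run_mcmc,
)
from mvflow.synth import calibration_fixture


@pytest.fixture(scope="module")
def fixture():
    return calibration_fixture(seed=0)


@pytest.fixture(scope="module")
def forward(fixture):
    net, pn, truth, priors, bcs, groups, targets = fixture
    return LinearForwardModel(net, bcs, groups, pn, targets)


class TestPriors:
    def test_beta22_mode_value(self):
        priors = PriorSpec(np.array([0.0, -5.0]), np.array([10.0, 5.0]), 2.0, 2.0)
        mode = np.array([5.0, 0.0])
        expected = np.log(1.5 / 10.0) + np.log(1.5 / 10.0)
        assert log_prior(mode, priors) == pytest.approx(expected, rel=1e-12)

    def test_outside_support(self):
        priors = PriorSpec(np.array([0.0]), np.array([1.0]), 2.0, 2.0)
        assert log_prior(np.array([1.5]), priors) == -np.inf

    def test_uniform_special_case(self):
        priors = PriorSpec(np.array([2.0]), np.array([6.0]), 1.0, 1.0)
        for x in (2.5, 4.0, 5.9):
            assert log_prior(np.array([x]), priors) == pytest.approx(-np.log(4.0))

    def test_sampling_stays_in_support(self):
        priors = PriorSpec(np.array([-3.0, 10.0]), np.array([3.0, 20.0]), 2.0, 5.0)
        draws = priors.sample(1000, np.random.default_rng(0))
        assert np.all(draws >= priors.lower) and np.all(draws <= priors.upper)


class TestTargets:
    def test_filter_audit(self, fixture):
        net, pn, truth, priors, bcs, groups, targets = fixture
        from mvflow.network import assign_analysis_layers
        layers = assign_analysis_layers(net)
        for t in targets:
            j = net.segment_index[t.segment_id]
            assert net.seg_categories[j] in ("SA", "DA+A", "AV+V", "SV")
            if t.kind == "velocity":
                assert net.diameters[j] < 30.0
                assert layers[j] == 1

    def test_build_velocity_targets_filters(self, fixture):
        net = fixture[0]
        fit = {"Art": (0.1, 1.0), "Ven": (0.05, 0.5)}
        targets = build_velocity_targets(net, fit)
        vel = [t for t in targets if t.kind == "velocity"]
        assert vel, "expected eligible arteriole/venule segments"
        from mvflow.network import assign_analysis_layers
        layers = assign_analysis_layers(net)
        for t in vel:
            j = net.segment_index[t.segment_id]
            assert net.diameters[j] < 30.0 and layers[j] == 1

    def test_empty_target_set_rejected(self, chain4):
        with pytest.raises(ValueError):
            build_velocity_targets(chain4, {"Art": (0.1, 1.0), "Ven": (0.1, 1.0)})

    def test_direction_sign_validation(self):
        with pytest.raises(ValueError):
            CalibrationTarget(0, "direction", 0.5)
        with pytest.raises(ValueError):
            CalibrationTarget(0, "velocity", -1.0)


class TestLikelihood:
    def test_truth_is_near_optimal(self, fixture, forward):
        net, pn, truth, priors, bcs, groups, targets = fixture
        rng = np.random.default_rng(0)
        ll_truth = log_likelihood(truth, forward)
        for _ in range(20):
            other = priors.sample(1, rng)[0]
            assert log_likelihood(other, forward) <= ll_truth + 1e-9

    def test_gaussian_term_arithmetic(self, fixture, forward):
        net, pn, truth, priors, bcs, groups, targets = fixture
        theta = priors.mean()
        sd = 0.5
        v = np.abs(forward.velocity_predictions(theta))
        resid = (v - forward.velocity_values) / sd
        nv = len(forward.velocity_values)
        expected = -0.5 * np.sum(resid**2) - nv * (0.5 * np.log(2 * np.pi) + np.log(sd))
        vd = forward.direction_predictions(theta)
        expected += np.sum(norm.logcdf(forward.direction_signs * vd / 0.1))
        assert log_likelihood(theta, forward) == pytest.approx(expected, rel=1e-12)

    def test_flipping_satisfied_direction_decreases(self, fixture):
        net, pn, truth, priors, bcs, groups, targets = fixture
        flipped = [
            CalibrationTarget(t.segment_id, t.kind,
                              -t.value if t.kind == "direction" else t.value)
            for t in targets
        ]
        fwd = LinearForwardModel(net, bcs, groups, pn, targets)
        fwd_flip = LinearForwardModel(net, bcs, groups, pn, flipped)
        assert log_likelihood(truth, fwd_flip) < log_likelihood(truth, fwd)


class TestSampler:
    def test_known_gaussian_posterior(self):
        mean = np.array([1.0, -2.0])
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        icov = np.linalg.inv(cov)

        def logpost(th):
            d = th - mean
            return -0.5 * np.einsum("ij,jk,ik->i", d, icov, d)

        priors = PriorSpec(np.array([-20.0, -20.0]), np.array([20.0, 20.0]), 1.0, 1.0)
        arch = run_mcmc(logpost, priors, n_chains=5, n_iterations=8000, seed=3)
        draws = arch.draws[len(arch.draws) // 2:]
        n_eff = 200  # conservative effective sample size for the check
        se_mean = np.sqrt(np.diag(cov) / n_eff)
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3 * se_mean)
        emp_cov = np.cov(draws.T)
        assert np.all(np.abs(emp_cov - cov) < 0.5)

    def test_seed_determinism(self):
        priors = PriorSpec(np.array([0.0, 0.0]), np.array([1.0, 1.0]), 2.0, 2.0)

        def logpost(th):
            return -0.5 * np.sum(((th - 0.5) / 0.1) ** 2, axis=-1)

        a1 = run_mcmc(logpost, priors, n_chains=3, n_iterations=500, seed=9)
        a2 = run_mcmc(logpost, priors, n_chains=3, n_iterations=500, seed=9)
        assert np.array_equal(a1.draws, a2.draws)
        assert np.array_equal(a1.log_posterior, a2.log_posterior)

    def test_prior_recovery_under_flat_likelihood(self):
        priors = PriorSpec(np.array([-4.0]), np.array([8.0]), 2.0, 2.0)

        def logpost(th):
            return log_prior(th, priors)

        arch = run_mcmc(logpost, priors, n_chains=5, n_iterations=10000, seed=17)
        draws = arch.draws[len(arch.draws) // 2::25, 0]  # thin for independence
        u = (draws - (-4.0)) / 12.0
        stat = kstest(u, beta_dist(2, 2).cdf)
        assert stat.pvalue > 0.01

    def test_draws_respect_prior_support(self):
        priors = PriorSpec(np.array([0.0, -1.0]), np.array([2.0, 1.0]), 2.0, 2.0)

        def logpost(th):
            return log_prior(th, priors)

        arch = run_mcmc(logpost, priors, n_chains=4, n_iterations=2000, seed=5)
        assert np.all(arch.draws >= priors.lower) and np.all(arch.draws <= priors.upper)


class TestGelmanRubin:
    def _archive(self, history):
        priors = PriorSpec(np.zeros(history.shape[2]), np.ones(history.shape[2]), 1, 1)
        c, L, d = history.shape
        return PosteriorArchive(
            draws=history.reshape(c * L, d), chain_ids=np.repeat(np.arange(c), L),
            log_posterior=np.zeros(c * L), history=history, priors=priors,
            thin=1, seed=0, acceptance_rate=1.0,
        )

    def test_identical_chains_give_unity(self):
        rng = np.random.default_rng(0)
        one = rng.standard_normal((1, 200, 3))
        hist = np.repeat(one, 4, axis=0)
        assert np.allclose(gelman_rubin(self._archive(hist)), 1.0)

    def test_well_mixed_gaussian_chains(self):
        rng = np.random.default_rng(1)
        hist = rng.standard_normal((5, 2000, 2))
        assert np.all(gelman_rubin(self._archive(hist)) < 1.05)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        hist = rng.standard_normal((4, 500, 1))
        hist += 10.0 * np.arange(4)[:, None, None]
        assert np.all(gelman_rubin(self._archive(hist)) > 1.2)

    def test_single_chain_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            gelman_rubin(self._archive(rng.standard_normal((1, 100, 2))))


class TestPosteriorPredictive:
    def _pinned_archive(self, theta, priors, n=50):
        hist = np.tile(theta, (2, n, 1))
        return PosteriorArchive(
            draws=np.tile(theta, (2 * n, 1)), chain_ids=np.repeat([0, 1], n),
            log_posterior=np.zeros(2 * n), history=hist, priors=priors,
            thin=1, seed=0, acceptance_rate=1.0, rhat=np.ones(len(theta)),
        )

    def test_single_draw_deterministic(self, fixture, forward):
        net, pn, truth, priors, bcs, groups, targets = fixture
        arch = self._pinned_archive(truth, priors)

        def runner(theta):
            from mvflow.solver import FlowSolution
            return FlowSolution(p=np.zeros(net.n), q=forward.flows(theta))

        sols, mean_q, dar, failed = posterior_predictive(arch, runner, n_keep=1)
        assert len(sols) == 1 and failed == 0
        assert np.allclose(mean_q, forward.flows(truth))

    def test_pinned_archive_full_agreement(self, fixture, forward):
        net, pn, truth, priors, bcs, groups, targets = fixture
        arch = self._pinned_archive(truth, priors)

        def runner(theta):
            from mvflow.solver import FlowSolution
            return FlowSolution(p=np.zeros(net.n), q=forward.flows(theta))

        sols, mean_q, dar, failed = posterior_predictive(arch, runner, n_keep=20)
        flowing = np.abs(mean_q) > 0
        assert np.all(dar[flowing] == 100.0)

    def test_convergence_gate(self, fixture, forward):
        net, pn, truth, priors, bcs, groups, targets = fixture
        arch = self._pinned_archive(truth, priors)
        arch.rhat = np.full(len(truth), 2.0)
        with pytest.raises(RuntimeError, match="R-hat"):
            posterior_predictive(arch, lambda th: None, n_keep=1)

    def test_failures_are_counted(self, fixture, forward):
        net, pn, truth, priors, bcs, groups, targets = fixture
        arch = self._pinned_archive(truth, priors)
        calls = {"n": 0}

        def runner(theta):
            from mvflow.solver import FlowSolution
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise RuntimeError("forward failure")
            return FlowSolution(p=np.zeros(net.n), q=forward.flows(theta))

        sols, mean_q, dar, failed = posterior_predictive(arch, runner, n_keep=10)
        assert failed > 0 and len(sols) + failed == calls["n"]
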