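"""Priors, likelihood estimators and the log-posterior against exact oracles."""

import numpy as np
import pytest
from scipy import stats

from dpbtn.data import MISSING, ObservationDataset
from dpbtn.network import (
    Experiment,
    PerturbationDesign,
    SignalingNetwork,
    state_index,
    transition_matrix,
)
from dpbtn.posterior import (
    Hyperparameters,
    LikelihoodEvaluator,
    ModelParameters,
    estimate_log_likelihood,
    exact_log_likelihood,
    log_posterior,
    log_prior_basal,
    log_prior_tau,
    log_prior_weights,
)


class TestWeightPrior:
    def test_maximum_at_prior_mean(self, rng):
        n = 4
        mu = rng.normal(0, 1, (n, n))
        np.fill_diagonal(mu, 0.0)
        hyper = Hyperparameters(q=1.3, s=0.7, mu=mu)
        assert log_prior_weights(mu, hyper) == pytest.approx(0.0)
        other = mu + 0.1
        assert log_prior_weights(other, hyper) < 0.0

    def test_gaussian_kernel_q2(self):
        W = np.zeros((2, 2))
        W[0, 1] = 2.0
        assert log_prior_weights(W, Hyperparameters(q=2, s=1)) == pytest.approx(-4.0)

    def test_laplacian_kernel_q1(self):
        W = np.zeros((2, 2))
        W[0, 1], W[1, 0] = 1.0, -1.0
        assert log_prior_weights(W, Hyperparameters(q=1, s=1)) == pytest.approx(-2.0)

    def test_diagonal_excluded(self):
        W = np.eye(3) * 99.0
        net_prior = log_prior_weights(W, Hyperparameters(q=1, s=1))
        assert net_prior == pytest.approx(0.0)

    def test_concavity_along_random_directions(self, rng):
        # for q >= 1 the log-kernel is concave
        hyper = Hyperparameters(q=1.5, s=1.2)
        for _ in range(20):
            a = rng.normal(0, 2, (3, 3))
            b = rng.normal(0, 2, (3, 3))
            np.fill_diagonal(a, 0.0)
            np.fill_diagonal(b, 0.0)
            lam = rng.random()
            mid = lam * a + (1 - lam) * b
            assert (log_prior_weights(mid, hyper)
                    >= lam * log_prior_weights(a, hyper)
                    + (1 - lam) * log_prior_weights(b, hyper) - 1e-9)


class TestBasalPrior:
    def test_positive_basal_forbidden(self):
        assert log_prior_basal(np.array([-1.0, 0.1]), 8, 16) == -np.inf

    def test_mode_location(self):
        # gamma(shape s0, rate r0) on -w0 has mode (s0-1)/r0 = 1.875
        grid = -np.linspace(0.05, 6, 2000)
        vals = [log_prior_basal(np.array([w]), 8, 16) for w in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(-1.875, abs=0.01)

    def test_matches_gamma_logpdf_up_to_constant(self):
        grid = -np.linspace(0.1, 5, 50)
        ours = np.array([log_prior_basal(np.array([w]), 8.0, 16.0) for w in grid])
        ref = stats.gamma.logpdf(-grid, a=16.0, scale=1 / 8.0)
        diff = ours - ref
        np.testing.assert_allclose(diff, diff[0], atol=1e-9)


class TestTauPrior:
    def test_binomial_mean_is_six(self):
        # n=20, p=0.3: prior expectation of each tau_t is 6 model steps
        assert 20 * 0.3 == pytest.approx(6.0)
        support = np.arange(0, 21)
        pmf = stats.binom.pmf(support, 20, 0.3)
        assert pmf.sum() == pytest.approx(1.0)
        assert (support * pmf).sum() == pytest.approx(6.0)

    def test_matches_scipy_logpmf_inside_support(self):
        for t in (1, 5, 20):
            assert log_prior_tau(np.array([t]), 20, 0.3) == pytest.approx(
                stats.binom.logpmf(t, 20, 0.3))

    @pytest.mark.parametrize("tau", [0, 21])
    def test_outside_support(self, tau):
        assert log_prior_tau(np.array([tau]), 20, 0.3) == -np.inf


def _dataset(obs, experiments, n_nodes, tau):
    design = PerturbationDesign(n_nodes=n_nodes, experiments=experiments)
    return ObservationDataset(design=design, obs=np.asarray(obs, np.int8),
                              tau=np.asarray(tau))


def _enumeration_log_likelihood(net, dataset):
    """Oracle: exact marginalized likelihood by transition-matrix enumeration."""
    n = net.n_nodes
    states = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(np.int8)
    total = 0.0
    for k, exp in enumerate(dataset.design.experiments):
        P = transition_matrix(net, exp)
        init = dataset.obs[k, 0].copy()
        init[init == MISSING] = 0  # "off" convention for missing at t0
        if exp.clamped_off:
            init[list(exp.clamped_off)] = 0
        if exp.clamped_on:
            init[list(exp.clamped_on)] = 1
        dist = np.zeros(2 ** n)
        dist[state_index(init)] = 1.0
        for t in range(1, dataset.n_times):
            for _ in range(int(dataset.tau[t - 1])):
                dist = dist @ P
            obs_t = dataset.obs[k, t]
            keep = np.ones(2 ** n, dtype=bool)
            for i in range(n):
                if obs_t[i] != MISSING:
                    keep &= states[:, i] == obs_t[i]
            dist = np.where(keep, dist, 0.0)
        total += np.log(dist.sum())
    return total


class TestLikelihood:
    def setup_method(self):
        W = np.zeros((2, 2))
        W[0, 1] = 1.5
        self.net = SignalingNetwork(W, np.array([-0.5, -0.25]), gamma=1.8)

    def test_one_node_transition_contribution(self):
        net = SignalingNetwork(np.zeros((1, 1)), np.zeros(1), gamma=1.0)
        ds = _dataset([[[0], [1]]], [Experiment(label="e")], 1, [1])
        params = ModelParameters(net, np.array([1]))
        hyper = Hyperparameters(gamma=1.0)
        assert exact_log_likelihood(params, ds, hyper) == pytest.approx(np.log(0.5))

    def test_exact_requires_tau_one_and_complete(self):
        ds = _dataset([[[1, 0], [1, 1]]], [Experiment(label="e")], 2, [2])
        params = ModelParameters(self.net, np.array([2]))
        with pytest.raises(ValueError, match="marginalization"):
            exact_log_likelihood(params, ds, Hyperparameters())

    def test_exact_is_always_finite(self, rng):
        obs = rng.integers(0, 2, (3, 4, 2)).astype(np.int8)
        ds = _dataset(obs, [Experiment(label=f"e{i}") for i in range(3)], 2, [1, 1, 1])
        params = ModelParameters(self.net, np.ones(3, dtype=int))
        assert np.isfinite(exact_log_likelihood(params, ds, Hyperparameters()))

    def test_exact_matches_enumeration(self):
        ds = _dataset([[[1, 0], [1, 1]], [[0, 1], [0, 0]]],
                      [Experiment(clamped_on={0}, label="a"),
                       Experiment(clamped_off={0}, label="b")], 2, [1])
        params = ModelParameters(self.net, np.array([1]))
        exact = exact_log_likelihood(params, ds, Hyperparameters())
        assert exact == pytest.approx(_enumeration_log_likelihood(self.net, ds))

    @pytest.mark.parametrize("method", ["rao-blackwell", "matching"])
    def test_estimators_match_enumeration_with_marginalization(self, method):
        # tau = 2: one unobserved intermediate step must be marginalized
        ds = _dataset([[[1, 0], [1, 1]]], [Experiment(clamped_on={0}, label="e")],
                      2, [2])
        params = ModelParameters(self.net, np.array([2]))
        truth = _enumeration_log_likelihood(self.net, ds)
        R = 100_000
        est = estimate_log_likelihood(params, ds, Hyperparameters(estimator=method),
                                      np.random.default_rng(0), R=R)
        p = np.exp(truth)
        se = np.sqrt(p * (1 - p) / R)  # binomial SE bound on the fraction scale
        assert abs(np.exp(est) - p) <= 3 * se + 1e-4

    @pytest.mark.parametrize("method", ["rao-blackwell", "matching"])
    def test_estimators_match_enumeration_with_missing_values(self, method):
        obs = np.array([[[1, 0], [1, MISSING]], [[0, MISSING], [0, 1]]], np.int8)
        ds = _dataset(obs, [Experiment(clamped_on={0}, label="a"),
                            Experiment(label="b")], 2, [1])
        params = ModelParameters(self.net, np.array([1]))
        truth = _enumeration_log_likelihood(self.net, ds)
        est = estimate_log_likelihood(params, ds, Hyperparameters(estimator=method),
                                      np.random.default_rng(1), R=100_000)
        assert est == pytest.approx(truth, abs=0.05)

    def test_deterministic_limit_gives_zero_loglik(self):
        W = np.zeros((2, 2))
        W[0, 1] = 1.0
        net = SignalingNetwork(W, np.array([-0.25, -0.25]), gamma=1e6)
        ds = _dataset([[[1, 0], [1, 1]]], [Experiment(clamped_on={0}, label="e")],
                      2, [1])
        params = ModelParameters(net, np.array([1]))
        est = estimate_log_likelihood(params, ds, Hyperparameters(gamma=1e6),
                                      np.random.default_rng(0), R=1000)
        assert est == pytest.approx(0.0, abs=1e-9)

    def test_matching_floor_keeps_loglik_finite(self):
        # impossible observation under a near-deterministic model
        W = np.zeros((2, 2))
        W[0, 1] = 1.0
        net = SignalingNetwork(W, np.array([-0.25, -0.25]), gamma=1e6)
        ds = _dataset([[[1, 0], [1, 0]]], [Experiment(clamped_on={0}, label="e")],
                      2, [1])
        params = ModelParameters(net, np.array([1]))
        R = 200
        est = estimate_log_likelihood(
            params, ds, Hyperparameters(gamma=1e6, estimator="matching"),
            np.random.default_rng(0), R=R)
        assert est == pytest.approx(np.log(1.0 / (R + 1)))

    def test_monte_carlo_error_shrinks_as_sqrt_R(self):
        ds = _dataset([[[1, 0], [1, 1]]], [Experiment(clamped_on={0}, label="e")],
                      2, [2])
        params = ModelParameters(self.net, np.array([2]))
        truth = _enumeration_log_likelihood(self.net, ds)
        Rs = [100, 10_000]
        errs = []
        for R in Rs:
            reps = [estimate_log_likelihood(
                params, ds, Hyperparameters(estimator="matching"),
                np.random.default_rng(s), R=R) for s in range(30)]
            errs.append(np.sqrt(np.mean((np.array(reps) - truth) ** 2)))
        slope = (np.log(errs[1]) - np.log(errs[0])) / (np.log(Rs[1]) - np.log(Rs[0]))
        assert slope == pytest.approx(-0.5, abs=0.15)


class TestLogPosterior:
    def test_additivity_of_components(self):
        W = np.zeros((2, 2))
        W[0, 1] = 1.0
        net = SignalingNetwork(W, np.array([-1.0, -2.0]), gamma=1.8)
        ds = _dataset([[[1, 0], [1, 1]]], [Experiment(clamped_on={0}, label="e")],
                      2, [1])
        params = ModelParameters(net, np.array([1]))
        hyper = Hyperparameters()
        lp = log_posterior(params, ds, hyper, np.random.default_rng(0))
        expected = (exact_log_likelihood(params, ds, hyper)
                    + log_prior_weights(net.weights, hyper)
                    + log_prior_basal(net.basal, hyper.r0, hyper.s0)
                    + log_prior_tau(params.tau, hyper.n, hyper.p))
        assert lp == pytest.approx(expected)

    def test_prior_violation_propagates(self):
        net = SignalingNetwork(np.zeros((2, 2)), np.array([0.1, -1.0]), gamma=1.8)
        ds = _dataset([[[0, 0], [0, 0]]], [Experiment(label="e")], 2, [1])
        params = ModelParameters(net, np.array([1]))
        assert log_posterior(params, ds, Hyperparameters(),
                             np.random.default_rng(0)) == -np.inf

    def test_invariant_under_experiment_relabeling(self, rng):
        obs = rng.integers(0, 2, (3, 2, 2)).astype(np.int8)
        obs[0, :, 0] = 0  # consistent with clamp-off in experiment a
        obs[1, :, 1] = 1  # consistent with clamp-on in experiment b
        exps = [Experiment(clamped_off={0}, label="a"),
                Experiment(clamped_on={1}, label="b"),
                Experiment(label="c")]
        ds = _dataset(obs, exps, 2, [1])
        perm = [2, 0, 1]
        ds_perm = _dataset(obs[perm], [exps[i] for i in perm], 2, [1])
        W = np.zeros((2, 2))
        W[0, 1] = 0.7
        net = SignalingNetwork(W, np.array([-0.5, -0.5]), gamma=1.8)
        params = ModelParameters(net, np.array([1]))
        hyper = Hyperparameters()
        a = log_posterior(params, ds, hyper, np.random.default_rng(0))
        b = log_posterior(params, ds_perm, hyper, np.random.default_rng(0))
        assert a == pytest.approx(b)

    def test_grid_search_maximum_matches_brute_force(self):
        # 2-node chain data; scan the single weight over a coarse grid
        W_true = np.zeros((2, 2))
        W_true[0, 1] = 2.0
        net_true = SignalingNetwork(W_true, np.array([-0.5, -0.5]), gamma=1.8)
        exp = Experiment(clamped_on={0}, label="e")
        ds_obs = []
        r = np.random.default_rng(3)
        from dpbtn.network import simulate as simulate_net

        for _ in range(20):
            traj = simulate_net(net_true, np.array([1, 0]), exp, 1, r)
            ds_obs.append(traj.states)
        ds = _dataset(np.array(ds_obs),
                      [Experiment(clamped_on={0}, label=f"e{i}") for i in range(20)],
                      2, [1])
        hyper = Hyperparameters()
        grid = np.linspace(-2, 4, 25)

        def post(w):
            W = np.zeros((2, 2))
            W[0, 1] = w
            net = SignalingNetwork(W, np.array([-0.5, -0.5]), gamma=1.8)
            return log_posterior(ModelParameters(net, np.array([1])), ds, hyper,
                                 np.random.default_rng(0))

        vals = np.array([post(w) for w in grid])
        # independent brute-force scan: same function evaluated elementwise
        # in reverse order must give the same argmax
        vals_rev = np.array([post(w) for w in grid[::-1]])[::-1]
        assert int(np.argmax(vals)) == int(np.argmax(vals_rev))
        w_hat = grid[int(np.argmax(vals))]
        assert 0.5 <= w_hat <= 4.0  # pulled toward the generating weight


class TestEvaluatorCaching:
    def test_evaluator_and_module_function_agree(self, rng):
        obs = rng.integers(0, 2, (2, 2, 3)).astype(np.int8)
        exps = [Experiment(clamped_off={1}, label="a"), Experiment(label="b")]
        ds = _dataset(obs, exps, 3, [2])
        W = rng.normal(0, 0.5, (3, 3))
        np.fill_diagonal(W, 0.0)
        net = SignalingNetwork(W, -rng.random(3), gamma=1.8)
        params = ModelParameters(net, np.array([2]))
        hyper = Hyperparameters()
        ev = LikelihoodEvaluator(ds, hyper)
        a = ev.estimate_log_likelihood(W, net.basal, params.tau,
                                       np.random.default_rng(5), R=2000)
        b = estimate_log_likelihood(params, ds, hyper,
                                    np.random.default_rng(5), R=2000)
        assert a == pytest.approx(b)
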