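"""Estimation: MPLE closed forms, sampler stationarity, MCMC-MLE oracles."""

import dataclasses
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from refnet import (DegeneracyError, DistanceMatrix, Ergm, ErgmSpec,
                    QuasiSeparationWarning, ReferralNetwork, SeparationError,
                    TermDef, ValidationError, information_criteria, mcmc_mle,
                    mple, simulate_ergm, simulate_statistics)

from conftest import make_roster, net_from_edges, random_digraph


@pytest.fixture(scope="module")
def kilolo_edges_fit(request):
    roster, _, net = request.getfixturevalue("kilolo_childcare")
    spec = ErgmSpec([TermDef("edges")], roster=roster)
    return net, spec, mple(net, spec)


class TestMple:
    def test_edges_only_equals_logit_of_density(self, kilolo_edges_fit):
        net, _, fit = kilolo_edges_fit
        assert fit.params.iloc[0] == pytest.approx(logit(33 / 2070), abs=1e-8)

    def test_empty_and_complete_networks_are_separated(self, small_roster):
        spec = ErgmSpec([TermDef("edges")], roster=small_roster)
        with pytest.raises(SeparationError):
            mple(net_from_edges(small_roster, []), spec)
        full = 1 - np.eye(4, dtype=np.uint8)
        complete = ReferralNetwork("testville", "childcare", small_roster.ids, full)
        with pytest.raises(SeparationError):
            mple(complete, spec)

    def test_matches_independent_pseudolikelihood_optimum(self):
        """Newton fit agrees with an independently coded objective."""
        roster = make_roster(["dispensary"] * 4 + ["hospital"])
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 10, (5, 5))
        values = (base + base.T) / 2
        np.fill_diagonal(values, 0)
        distances = DistanceMatrix(roster.ids, values)
        spec = ErgmSpec([TermDef("edges"), TermDef("edgecov", attribute="distance")],
                        roster=roster, distances=distances)
        adj = random_digraph(rng, 5, p=0.4)
        net = ReferralNetwork("testville", "childcare", roster.ids, adj)
        bound = spec.bind(net)

        # oracle: delta from brute-force global differences, then optimize
        def brute_delta(i, j):
            plus = adj.copy(); plus[i, j] = 1
            minus = adj.copy(); minus[i, j] = 0
            return bound.statistics(plus) - bound.statistics(minus)

        dyads = [(i, j) for i in range(5) for j in range(5) if i != j]
        X = np.array([brute_delta(i, j) for i, j in dyads])
        y = np.array([adj[i, j] for i, j in dyads], dtype=float)

        def neg_pl(theta):
            eta = X @ theta
            return -(y @ eta - np.logaddexp(0, eta).sum())

        oracle = minimize(neg_pl, np.zeros(2), method="Nelder-Mead",
                          options={"xatol": 1e-8, "fatol": 1e-12}).x
        fit = mple(net, spec)
        np.testing.assert_allclose(fit.params.to_numpy(), oracle, atol=1e-3)

    def test_quasi_separation_flagged_with_ridge_fallback(self):
        roster = make_roster(["dispensary"] * 4)
        adj = np.zeros((4, 4), np.uint8)
        adj[0, 1] = adj[1, 2] = adj[2, 0] = 1  # node 3 isolated
        net = ReferralNetwork("testville", "childcare", roster.ids, adj)
        spec = ErgmSpec([TermDef("edges"), TermDef("isolates")], roster=roster)
        with pytest.warns(QuasiSeparationWarning):
            fit = mple(net, spec)
        assert fit.flags.get("quasi_separation") and fit.flags.get("ridge") == 1e-4

    def test_results_bookkeeping(self, kilolo_edges_fit):
        net, _, fit = kilolo_edges_fit
        assert fit.k == 1 and fit.nobs == 46 * 45
        assert fit.aic == pytest.approx(-2 * fit.llf + 2)
        assert fit.bic == pytest.approx(-2 * fit.llf + np.log(2070))
        assert "edges" in fit.summary()
        payload = fit.to_dict()
        assert payload["loglik_kind"] == "pseudolikelihood"
        assert payload["coefficients"]["edges"] == pytest.approx(fit.params.iloc[0])


class TestSampler:
    @pytest.mark.parametrize("target", [0.5, 0.2])
    def test_edges_only_stationary_density(self, target):
        roster = make_roster(["dispensary"] * 12)
        net = net_from_edges(roster, [])
        spec = ErgmSpec([TermDef("edges")], roster=roster)
        theta = [float(logit(target))]
        stats = simulate_statistics(net, spec, theta, n_samples=200,
                                    burn_in=20_000, interval=200, seed=9,
                                    init="empty")
        m = net.n_dyads
        mc_se = stats[:, 0].std() / np.sqrt(200)  # correlated, conservative x3
        assert abs(stats[:, 0].mean() / m - target) <= max(3 * mc_se / m, 0.01)

    def test_strongly_negative_edges_gives_near_empty_graphs(self):
        roster = make_roster(["dispensary"] * 20)
        net = net_from_edges(roster, [])
        spec = ErgmSpec([TermDef("edges")], roster=roster)
        stats = simulate_statistics(net, spec, [-10.0], n_samples=100,
                                    burn_in=10_000, interval=100, seed=4)
        assert stats[:, 0].mean() / net.n_dyads < 0.01

    def test_reproducible_from_seed(self, kilolo_childcare):
        roster, _, net = kilolo_childcare
        spec = ErgmSpec([TermDef("edges"), TermDef("isolates")], roster=roster)
        kwargs = dict(n_samples=20, burn_in=2000, interval=50, seed=123)
        a = simulate_statistics(net, spec, [-4.0, 0.5], **kwargs)
        b = simulate_statistics(net, spec, [-4.0, 0.5], **kwargs)
        np.testing.assert_array_equal(a, b)

    def test_incremental_statistics_match_global_recomputation(self, kilolo_childcare):
        roster, _, net = kilolo_childcare
        spec = ErgmSpec([TermDef("edges"), TermDef("isolates"),
                         TermDef("gwidegree", decay=0.7)], roster=roster)
        kwargs = dict(n_samples=10, burn_in=5000, interval=100, seed=31)
        stats = simulate_statistics(net, spec, [-4.0, 0.2, 0.5], **kwargs)
        nets = simulate_ergm(net, spec, [-4.0, 0.2, 0.5], **kwargs)
        bound = spec.bind(net)
        for s, sim in enumerate(nets):
            np.testing.assert_allclose(stats[s], bound.statistics(sim.adjacency),
                                       atol=1e-9)

    def test_non_finite_coefficients_rejected(self, small_roster):
        net = net_from_edges(small_roster, [])
        spec = ErgmSpec([TermDef("edges")], roster=small_roster)
        with pytest.raises(ValueError):
            simulate_statistics(net, spec, [np.inf], n_samples=10,
                                burn_in=10, interval=1, seed=0)


class TestMcmcMle:
    def test_edges_only_recovers_logit_density(self, kilolo_childcare):
        roster, _, net = kilolo_childcare
        spec = ErgmSpec([TermDef("edges")], roster=roster)
        fit = mcmc_mle(net, spec, seed=5, n_samples=400, burn_in=20_000,
                       interval=100, estimate_loglik=False)
        assert abs(fit.params.iloc[0] - logit(33 / 2070)) < 0.05
        assert fit.converged and fit.method == "mcmc_mle"

    def test_edges_only_loglik_matches_closed_form(self, kilolo_childcare):
        roster, _, net = kilolo_childcare
        spec = ErgmSpec([TermDef("edges")], roster=roster)
        fit = mcmc_mle(net, spec, seed=5, n_samples=300, burn_in=20_000,
                       interval=100, bridges=4, bridge_samples=50)
        theta = fit.params.iloc[0]
        exact = theta * 33 - 2070 * np.log1p(np.exp(theta))
        # dyad-independent model: bridge reference is exact
        assert fit.llf == pytest.approx(exact, abs=1e-9)

    def test_matches_exact_enumeration_on_four_nodes(self):
        roster = make_roster(["dispensary"] * 4)
        adj = np.zeros((4, 4), np.uint8)
        adj[0, 1] = adj[2, 0] = adj[1, 2] = 1
        net = ReferralNetwork("testville", "childcare", roster.ids, adj)
        spec = ErgmSpec([TermDef("edges"), TermDef("isolates")], roster=roster)

        # oracle: brute-force statistics of all 2^12 digraphs
        pairs = [(i, j) for i in range(4) for j in range(4) if i != j]
        U = np.empty((2**12, 2))
        for bits in range(2**12):
            a = np.zeros((4, 4))
            for b, (i, j) in enumerate(pairs):
                if bits >> b & 1:
                    a[i, j] = 1
            deg = a.sum(0) + a.sum(1)
            U[bits] = (a.sum(), np.sum(deg == 0))
        u_obs = spec.bind(net).statistics()
        exact = minimize(lambda t: -(t @ u_obs - logsumexp(U @ t)),
                         np.zeros(2), method="BFGS").x

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", QuasiSeparationWarning)
            fit = mcmc_mle(net, spec, seed=11, n_samples=3000, burn_in=20_000,
                           interval=50, tol=0.004, max_iter=60,
                           estimate_loglik=False)
        np.testing.assert_allclose(fit.params.to_numpy(), exact, atol=0.05)

    def test_degenerate_start_raises_with_payload(self, kilolo_childcare):
        roster, _, net = kilolo_childcare
        spec = ErgmSpec([TermDef("edges")], roster=roster)
        with pytest.raises(DegeneracyError) as err:
            mcmc_mle(net, spec, theta0=[-20.0], n_samples=100, burn_in=5000,
                     interval=50, seed=3, estimate_loglik=False)
        assert "observed" in err.value.payload


class TestInformationCriteria:
    def test_published_arithmetic(self):
        aic, _ = information_criteria(-57.59, 15, 930)
        assert aic == pytest.approx(145.18)
        _, bic = information_criteria(-79.33, 14, 2070)
        assert bic == pytest.approx(265.55, abs=0.02)

    def test_zero_parameters(self):
        aic, bic = information_criteria(-10.0, 0, 50)
        assert aic == bic == 20.0

    def test_invalid_sizes(self):
        with pytest.raises(ValidationError):
            information_criteria(-1.0, 1, 0)
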