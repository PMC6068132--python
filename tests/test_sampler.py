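"""Metropolis-Hastings samplers: proposals, acceptance, stationarity."""

import math

import numpy as np
import pytest
from scipy.special import expit

from ergm_ee import (
    Graph,
    ModelSpec,
    StatisticDescriptor,
    acceptance_probability,
    ifd_run,
    ifd_step,
    mh_run,
    propose_basic,
)
from ergm_ee import _kernels
from ergm_ee.model import encode_terms
from ergm_ee.statistics import statistic_vector

from .conftest import enumerate_graphs_n4, exact_expectations_n4, make_er_graph


class TestProposeBasic:
    def test_two_nodes_always_the_single_dyad(self):
        g = Graph(2)
        rng = np.random.default_rng(0)
        assert all(set(propose_basic(g, rng)) == {0, 1} for _ in range(20))

    def test_uniform_over_dyads(self):
        g = Graph(3)
        rng = np.random.default_rng(1)
        counts = {}
        n = 30000
        for _ in range(n):
            d = frozenset(propose_basic(g, rng))
            counts[d] = counts.get(d, 0) + 1
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 0.02
        assert len(counts) == 3

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            propose_basic(Graph(1), np.random.default_rng(0))


class TestAcceptanceProbability:
    def test_zero_theta_always_accepts(self):
        assert acceptance_probability([3.0, -2.0], [0.0, 0.0]) == 1.0

    def test_edge_only_closed_forms(self):
        # adding an edge at theta_L = -ln 2 accepts with probability 1/2
        assert acceptance_probability([1.0], [-math.log(2.0)]) == pytest.approx(0.5)
        # deleting it is always accepted
        assert acceptance_probability([-1.0], [-math.log(2.0)]) == 1.0

    def test_q_ratio_enters_multiplicatively(self):
        assert acceptance_probability([0.0], [1.0], q_ratio=0.25) == pytest.approx(0.25)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            acceptance_probability([1.0, 2.0], [0.5])


class TestMHRun:
    def test_zero_theta_acceptance_rate_is_one(self):
        g = make_er_graph(10, 0.3, seed=3)
        kinds, lams, attrs = encode_terms(g, [StatisticDescriptor("edge")])
        z = np.array([float(g.num_edges)])
        _, accepts = _kernels.mh_basic(g.adj, g.deg, kinds, lams, attrs,
                                       np.zeros(1), z, 5000, 100, 42)
        assert accepts == 5000

    def test_three_node_edge_count_mean(self, edge_model):
        g = Graph(3)
        trace, _ = mh_run(g, edge_model.with_theta([0.0]), 80000, burnin=5000,
                          thin=10, rng=np.random.default_rng(4))
        # 3 independent Bernoulli(1/2) dyads
        assert trace.mean() == pytest.approx(1.5, abs=0.06)

    @pytest.mark.parametrize("theta_L", [-1.5, 0.8])
    def test_bernoulli_density_closed_form(self, edge_model, theta_L):
        g = Graph(25)
        trace, _ = mh_run(g, edge_model.with_theta([theta_L]), 400000,
                          burnin=100000, thin=50, rng=np.random.default_rng(5))
        density = trace.mean() / g.num_dyads
        assert density == pytest.approx(expit(theta_L), abs=0.015)

    def test_trace_means_match_exact_enumeration_n4(self):
        """MH stationary expectations on N=4 agree with exact enumeration
        of all 64 graphs for an edge + alternating-triangle model."""
        terms = [StatisticDescriptor("edge"), StatisticDescriptor("alt_triangle", lam=2.0)]
        theta = np.array([-0.2, 0.4])
        exact, _, _ = exact_expectations_n4(terms, theta)
        g = Graph(4)
        trace, _ = mh_run(g, ModelSpec(terms, theta), 400000, burnin=50000,
                          thin=10, rng=np.random.default_rng(6))
        sim = trace.mean(axis=0)
        np.testing.assert_allclose(sim, exact, atol=0.05)

    def test_stationary_distribution_matches_enumeration(self):
        """Detailed balance: state frequencies across independent short
        chains match the exact Gibbs distribution over the 64 graphs."""
        terms = [StatisticDescriptor("edge"), StatisticDescriptor("alt_triangle", lam=2.0)]
        theta = np.array([-0.3, 0.5])
        _, zs, probs = exact_expectations_n4(terms, theta)
        dyads = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        model = ModelSpec(terms, theta)
        rng = np.random.default_rng(7)
        counts = np.zeros(64)
        n_chains = 4000
        for _ in range(n_chains):
            g = Graph(4)
            mh_run(g, model, 250, rng=rng)
            mask = sum(1 << b for b, (i, j) in enumerate(dyads) if g.adj[i, j])
            counts[mask] += 1
        emp = counts / n_chains
        assert np.abs(emp - probs).max() < 0.025

    def test_steps_burnin_precondition(self, edge_model):
        with pytest.raises(ValueError):
            mh_run(Graph(5), edge_model, steps=10, burnin=20)


class TestIFD:
    def make_graph(self, seed=8, n=40, p=0.15):
        return make_er_graph(n, p, seed=seed)

    def test_delete_then_insert_returns_to_l_obs(self):
        g = self.make_graph()
        L = g.num_edges
        model = ModelSpec([], fixed_density=True)
        rng = np.random.default_rng(9)
        # force acceptance with a huge positive/negative auxiliary parameter
        theta_L = 0.0
        seen = [g.num_edges]
        for _ in range(200):
            out, theta_L = ifd_step(g, model, theta_L, L, rng)
            seen.append(g.num_edges)
        assert set(seen) <= {L, L - 1}

    def test_deletion_proposal_uniform_over_edges(self):
        g = self.make_graph(n=12, p=0.4)
        L = g.num_edges
        model = ModelSpec([], fixed_density=True)
        rng = np.random.default_rng(10)
        counts = {}
        trials = 6000
        for _ in range(trials):
            out, _ = ifd_step(g.copy(), model, 0.0, L, rng)
            d = frozenset(out.dyads[0])
            counts[d] = counts.get(d, 0) + 1
        assert len(counts) == L
        expected = trials / L
        for c in counts.values():
            assert abs(c - expected) < 6 * math.sqrt(expected)

    def test_edge_count_outside_band_rejected(self):
        g = self.make_graph()
        model = ModelSpec([], fixed_density=True)
        with pytest.raises(ValueError, match="edge count"):
            ifd_step(g, model, 0.0, g.num_edges + 5, np.random.default_rng(0))

    def test_adapted_theta_l_recovers_bernoulli_logit(self):
        """Edge-only fixed-density run: the adapted auxiliary parameter
        converges to ln(L / (D - L + 1)) ~ logit of the observed density."""
        g = self.make_graph(n=60, p=0.12)
        L, D = g.num_edges, g.num_dyads
        target = math.log(L / (D - L + 1.0))
        model = ModelSpec([], fixed_density=True)
        _, thL, _ = ifd_run(g, model, steps=300000, rng=np.random.default_rng(11))
        est = thL[len(thL) // 2:].mean()
        assert est == pytest.approx(target, abs=0.1)

    def test_ifd_preserves_statistics_feasibility(self):
        # statistic trace from ifd_run starts at the observed values
        g = self.make_graph()
        g.set_binary_attr("flag", np.random.default_rng(1).integers(0, 2, g.n))
        model = ModelSpec([StatisticDescriptor("activity", attr_name="flag")],
                          fixed_density=True)
        L_obs = g.num_edges
        ztr, thL, g2 = ifd_run(g, model, steps=20000, rng=np.random.default_rng(12))
        assert g2.num_edges in (L_obs, L_obs - 1)  # density constraint held
        g2.validate()
        assert ztr.shape[1] == 1
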