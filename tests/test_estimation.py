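"""CD-1 initialization, EE estimation, step sizes, and the MoM baseline."""

import math

import numpy as np
import pytest
from scipy.special import logit

from ergm_ee import (
    DivergenceError,
    Graph,
    ModelSpec,
    StatisticDescriptor,
    calibrate_K,
    cd1_estimate,
    compute_KA,
    ee_estimate,
    ee_fit,
    ee_update,
    mh_run,
    mom_estimate,
    statistic_vector,
)
from ergm_ee.estimation import MoMSettings

from .conftest import make_er_graph


def bernoulli_se(g: Graph) -> float:
    p = g.density
    return 1.0 / math.sqrt(g.num_dyads * p * (1 - p))


@pytest.fixture(scope="module")
def bern100():
    return make_er_graph(100, 0.25, seed=21)


class TestCD1:
    def test_bernoulli_closed_form(self, bern100, ):
        model = ModelSpec([StatisticDescriptor("edge")])
        theta0 = cd1_estimate(bern100, model, rng=np.random.default_rng(1))
        assert theta0[0] == pytest.approx(logit(bern100.density), abs=0.02)

    def test_dyad_independent_model_matches_mple_oracle(self):
        """For an edge + categorical-mismatch model the CD-1 root agrees
        with an independent logistic-likelihood maximization over dyads."""
        import statsmodels.api as sm

        rng = np.random.default_rng(22)
        g = make_er_graph(40, 0.2, seed=23)
        cls = rng.integers(0, 2, g.n)
        g.set_cat_attr("cls", cls)
        model = ModelSpec([
            StatisticDescriptor("edge"),
            StatisticDescriptor("mismatch", attr_name="cls"),
        ])
        theta0 = cd1_estimate(g, model, rng=rng, iters=400, batch=6000)
        # MPLE oracle: logistic regression of edge indicators on dyad covariates
        rows, ys = [], []
        for i in range(g.n):
            for j in range(i + 1, g.n):
                rows.append([1.0, 1.0 if cls[i] != cls[j] else 0.0])
                ys.append(1.0 if g.adj[i, j] else 0.0)
        fit = sm.Logit(np.array(ys), np.array(rows)).fit(disp=0)
        np.testing.assert_allclose(theta0, fit.params, atol=0.05)

    def test_empty_graph_flags_nonfinite_root(self):
        g = Graph(12)
        model = ModelSpec([StatisticDescriptor("edge")])
        with pytest.warns(UserWarning, match="non-finite"):
            theta0 = cd1_estimate(g, model, rng=np.random.default_rng(2))
        assert theta0[0] <= -20.0  # finite stand-in far below any stable value

    def test_observed_graph_never_modified(self, bern100):
        before = bern100.adj.copy()
        cd1_estimate(bern100, ModelSpec([StatisticDescriptor("edge")]),
                     rng=np.random.default_rng(3), iters=50)
        assert (bern100.adj == before).all()


class TestStepSizes:
    def test_printed_heuristic_matches_enumeration_on_empty_triangle(self):
        """Edge-only on an empty N=3 graph at theta = 0: every proposal
        adds an edge with unit change and acceptance 1, so the window
        derivative is exactly m and K = 1e-4 / m**2."""
        g = Graph(3)
        model = ModelSpec([StatisticDescriptor("edge")])
        K = compute_KA(g, model, [0.0], probe_steps=5000,
                       rng=np.random.default_rng(4), m=1000)
        assert K[0] == pytest.approx(1e-4 / 1000.0**2, rel=1e-12)

    def test_zero_variation_falls_back_to_floor(self, bern100):
        g = bern100.copy()
        g.set_binary_attr("never", np.zeros(g.n, dtype=int))
        model = ModelSpec([
            StatisticDescriptor("edge"),
            StatisticDescriptor("interaction", attr_name="never"),
        ])
        with pytest.warns(UserWarning, match="floor"):
            K = compute_KA(g, model, [0.0, 0.0], rng=np.random.default_rng(5),
                           k_floor=1e-6)
        assert K[1] == 1e-6

    def test_probe_calibration_positive_and_floored(self, bern100):
        g = bern100.copy()
        g.set_binary_attr("never", np.zeros(g.n, dtype=int))
        model = ModelSpec([
            StatisticDescriptor("edge"),
            StatisticDescriptor("interaction", attr_name="never"),
        ])
        with pytest.warns(UserWarning, match="floor"):
            K = calibrate_K(g, model, [logit(g.density), 0.0],
                            rng=np.random.default_rng(6))
        assert K[0] > 0 and K[1] == 1e-6

    @pytest.mark.parametrize(
        "theta,dz,K,expected",
        [(1.0, 2.0, 0.01, 0.96), (0.5, -3.0, 0.1, 1.4), (7.0, 0.0, 5.0, 7.0)],
    )
    def test_ee_update_signed_square(self, theta, dz, K, expected):
        assert ee_update(theta, dz, K) == pytest.approx(expected)

    def test_ee_update_requires_positive_k(self):
        with pytest.raises(ValueError):
            ee_update(0.0, 1.0, 0.0)


class TestEEEstimate:
    def test_k_zero_reduces_to_plain_mh(self, bern100):
        """With K = 0 the parameter trace is constant: the run is MH."""
        model = ModelSpec([StatisticDescriptor("edge")])
        theta0 = np.array([-0.7])
        res = ee_estimate(bern100.copy(), model, theta0, np.zeros(1),
                          M=50000, m=1000, rng=np.random.default_rng(7))
        assert (res.theta_trace == -0.7).all()

    @pytest.mark.parametrize("M", [10000, 50000])
    def test_dz_accumulator_equals_recount(self, er30, all_kind_terms, M):
        """The accumulator dz always equals z(x) - z(x_obs): at the end
        of a run the recorded dz matches a full recount on the final graph."""
        model = ModelSpec(all_kind_terms)
        g = er30.copy()
        z_obs = statistic_vector(g, model)
        theta0 = np.zeros(len(all_kind_terms))
        K = np.full(len(all_kind_terms), 1e-6)
        res = ee_estimate(g, model, theta0, K, M=M, m=1000,
                          rng=np.random.default_rng(8))
        recount = statistic_vector(g, model) - z_obs
        np.testing.assert_allclose(res.dz_trace[-1], recount, atol=1e-6)

    def test_update_direction_rule_exact(self, bern100):
        """Each recorded update moves theta by exactly
        -K*sign(dz)*dz^2 for the dz recorded at that checkpoint."""
        model = ModelSpec([StatisticDescriptor("edge")])
        K = np.array([2e-6])
        theta0 = np.array([logit(bern100.density)])
        res = ee_estimate(bern100.copy(), model, theta0, K, M=30000, m=1000,
                          rng=np.random.default_rng(9))
        prev = theta0[0]
        for k in range(res.theta_trace.shape[0]):
            dz = res.dz_trace[k, 0]
            expected = prev - K[0] * math.copysign(dz * dz, dz) if dz != 0 else prev
            assert res.theta_trace[k, 0] == pytest.approx(expected, rel=1e-12)
            prev = res.theta_trace[k, 0]

    def test_bernoulli_recovery_within_mc_error(self, bern100):
        model = ModelSpec([StatisticDescriptor("edge")])
        res = ee_fit(bern100, model, M=800000, rng=np.random.default_rng(10))
        assert abs(res.theta_hat[0] - logit(bern100.density)) < 3 * bernoulli_se(bern100)
        assert abs(res.tau[0]) < 0.1

    def test_divergence_guard_names_term(self, bern100):
        model = ModelSpec([StatisticDescriptor("edge")])
        with pytest.raises(DivergenceError, match="edge"):
            ee_estimate(bern100.copy(), model, np.array([0.0]), np.array([1.0]),
                        M=50000, m=1000, rng=np.random.default_rng(11))

    def test_k_halving_shrinks_theta_trace_sd(self, bern100):
        """Switching to smaller K late in the run reduces the parameter
        fluctuation without moving its mean beyond Monte Carlo error."""
        model = ModelSpec([StatisticDescriptor("edge")])
        theta0 = np.array([logit(bern100.density)])
        K = calibrate_K(bern100, model, theta0, rng=np.random.default_rng(12))
        M = 600000
        res = ee_estimate(bern100.copy(), model, theta0, K * 4, M=M, m=1000,
                          rng=np.random.default_rng(13), k_half_step=M // 2)
        n = res.theta_trace.shape[0]
        first = res.theta_trace[n // 4: n // 2, 0]   # pre-halving, equilibrated
        second = res.theta_trace[3 * n // 4:, 0]     # post-halving
        assert second.std(ddof=1) < first.std(ddof=1)
        se = first.std(ddof=1) / math.sqrt(len(first) / 4)
        assert abs(second.mean() - first.mean()) < 4 * se

    def test_ifd_sampler_estimation(self):
        g = make_er_graph(60, 0.15, seed=24)
        model = ModelSpec([StatisticDescriptor("alt_star", lam=2.0)],
                          fixed_density=True)
        theta0 = cd1_estimate(g, model, rng=np.random.default_rng(14))
        K = calibrate_K(g, model, theta0, rng=np.random.default_rng(15))
        res = ee_estimate(g.copy(), model, theta0, K, M=200000, m=1000,
                          rng=np.random.default_rng(16), sampler="ifd")
        assert res.theta_L is not None and np.isfinite(res.theta_L)
        assert abs(res.tau[0]) < 0.2  # statistic held near its observed value

    def test_equilibrium_fixed_point_drift_is_zero(self, bern100):
        """At the Bernoulli MLE the expected dz drift vanishes: a plain
        MH run from the observed graph stays centred on z_obs."""
        model = ModelSpec([StatisticDescriptor("edge")],
                          np.array([logit(bern100.density)]))
        g = bern100.copy()
        z_obs = float(bern100.num_edges)
        trace, _ = mh_run(g, model, 400000, burnin=50000, thin=1000,
                          rng=np.random.default_rng(17))
        drift = trace.mean() - z_obs
        assert abs(drift) < 0.6 * trace.std(ddof=1)


class TestMoM:
    def test_bernoulli_closed_form(self):
        g = make_er_graph(60, 0.25, seed=25)
        model = ModelSpec([StatisticDescriptor("edge")])
        theta0 = cd1_estimate(g, model, rng=np.random.default_rng(18))
        res = mom_estimate(g, model, theta0, rng=np.random.default_rng(19))
        assert abs(res.theta_hat[0] - logit(g.density)) < 3 * bernoulli_se(g)

    def test_gain_halving_shrinks_subphase_variance(self):
        g = make_er_graph(50, 0.2, seed=26)
        model = ModelSpec([StatisticDescriptor("edge")])
        s = MoMSettings(subphases=3, iters0=15, max_rounds=1)
        res = mom_estimate(g, model, np.array([logit(g.density)]),
                           rng=np.random.default_rng(20), settings=s)
        tr = res.theta_trace[:, 0]
        v_first = tr[:15].var(ddof=1)
        v_last = tr[-30:].var(ddof=1)
        assert v_last < v_first

    def test_observed_graph_untouched(self):
        g = make_er_graph(40, 0.2, seed=27)
        before = g.adj.copy()
        mom_estimate(g, ModelSpec([StatisticDescriptor("edge")]),
                     np.array([-1.0]), rng=np.random.default_rng(21),
                     settings=MoMSettings(subphases=2, iters0=5, n_check=20,
                                          max_rounds=1))
        assert (g.adj == before).all()
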