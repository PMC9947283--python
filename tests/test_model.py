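import copy
import math

import numpy as np
import pytest
from scipy.linalg import null_space
from scipy.optimize import minimize_scalar

from bstmort import adjacency as adj, model, panel_io
from bstmort import synthetic_data as sd
from bstmort.model import McmcState, ModelConfig


def _path_state(v_scale=0.05):
    """A constraint-satisfying state on the 3-node path graph, T=4."""
    tt = np.array([-1.5, -0.5, 0.5, 1.5])
    Bv = null_space(np.vstack([np.ones(4), tt]))
    return McmcState(
        alpha=2.5, b0=-0.02,
        u=np.array([0.1, -0.02, -0.08]), nu=np.array([0.05, -0.01, 0.03]),
        ub=np.array([0.01, 0.00, -0.01]), nub=np.array([0.002, -0.003, 0.001]),
        v=v_scale * Bv[:, 0],
        sigma_u=0.2, sigma_nu=0.1, sigma_ub=0.05, sigma_nub=0.05,
        sigma_v=0.1, sigma_eps=0.1)


@pytest.fixture()
def path_problem(path_graph):
    rng = np.random.default_rng(0)
    Y = 2.5 + 0.1 * rng.standard_normal((3, 4))
    return Y, path_graph


class TestIcarFullConditional:
    def test_path_graph_hand_value(self, path_graph):
        values = np.array([1.0, 0.0, 3.0])
        mean, var = model.icar_full_conditional(1, values, path_graph,
                                                sigma=math.sqrt(2))
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(1.0)

    def test_equal_neighbours_average_to_constant(self, path_graph):
        mean, _ = model.icar_full_conditional(1, np.array([7.0, 0.0, 7.0]),
                                              path_graph, sigma=1.0)
        assert mean == pytest.approx(7.0)

    def test_variance_vanishes_with_sigma(self, path_graph):
        _, var = model.icar_full_conditional(0, np.zeros(3), path_graph, sigma=1e-8)
        assert var < 1e-15

    def test_isolated_node_errors(self):
        g = adj.from_edges(["A", "B", "C"], [(0, 1)])
        with pytest.raises(ValueError, match="island"):
            model.icar_full_conditional(2, np.zeros(3), g, sigma=1.0)

    def test_matches_joint_precision_oracle(self):
        """Brute force: condition the joint normal with precision Q = (D-W)/s^2."""
        g = sd.make_lattice_graph(2, 3)
        rng = np.random.default_rng(3)
        values = rng.standard_normal(6)
        sigma = 0.7
        Q = g.laplacian() / sigma ** 2
        for node in range(6):
            rest = [j for j in range(6) if j != node]
            mean_o = -Q[node, rest] @ values[rest] / Q[node, node]
            var_o = 1.0 / Q[node, node]
            mean, var = model.icar_full_conditional(node, values, g, sigma)
            assert mean == pytest.approx(mean_o, abs=1e-12)
            assert var == pytest.approx(var_o, abs=1e-12)


class TestLogJointDensity:
    def test_translation_identity(self, path_problem):
        Y, g = path_problem
        cfg = ModelConfig.desk_scale()
        st = _path_state()
        lp1 = model.log_joint_density(st, Y, g, cfg)
        st2 = copy.deepcopy(st)
        st2.alpha += 1.7
        lp2 = model.log_joint_density(st2, Y + 1.7, g, cfg)
        # residuals identical; only the N(0,1000) prior on alpha moves
        prior_shift = (st.alpha ** 2 - st2.alpha ** 2) / (2 * cfg.prior_sd_fixed ** 2)
        assert lp2 - lp1 == pytest.approx(prior_shift, abs=1e-9)

    def test_doubling_sigma_eps_with_zero_residuals(self, path_graph):
        cfg = ModelConfig.desk_scale()
        st = _path_state()
        tt = np.array([-1.5, -0.5, 0.5, 1.5])
        s = st.u + st.nu
        b1 = st.ub + st.nub
        Y = st.alpha + s[:, None] + np.outer(st.b0 + b1, tt) + st.v[None, :]
        lp1 = model.log_joint_density(st, Y, path_graph, cfg)
        st2 = copy.deepcopy(st)
        st2.sigma_eps = 2 * st.sigma_eps
        lp2 = model.log_joint_density(st2, Y, path_graph, cfg)
        # likelihood term drops by N*ln(2); the half-normal prior adds 3s^2/20
        N = Y.size
        prior_shift = 3 * st.sigma_eps ** 2 / (2 * cfg.halfnormal_variance)
        assert lp1 - lp2 == pytest.approx(N * math.log(2) + prior_shift, abs=1e-9)

    def test_constraint_violation_errors(self, path_problem):
        Y, g = path_problem
        st = _path_state()
        st.u = st.u + 0.5  # breaks sum-to-zero
        with pytest.raises(ValueError, match="sum-to-zero"):
            model.log_joint_density(st, Y, g, ModelConfig.desk_scale())
        st = _path_state()
        st.v = st.v + 0.3
        with pytest.raises(ValueError, match="v violates"):
            model.log_joint_density(st, Y, g, ModelConfig.desk_scale())


class _StubRng:
    """Deterministic stand-in: standard normals all equal to z, uniforms 0.5."""

    def __init__(self, z):
        self.z = float(z)

    def standard_normal(self, size=None):
        if size is None:
            return self.z
        return np.full(size, self.z)

    def uniform(self):
        return 0.5


class TestGibbsConditionals:
    """The sampler's Gaussian conditionals vs numerical optimisation of
    log_joint_density in that coordinate (independent oracle)."""

    def _setup(self, path_problem):
        Y, g = path_problem
        cfg = ModelConfig.desk_scale()
        prob = model._Problem(Y, g, [2000, 2001, 2002, 2003])
        return Y, g, cfg, prob

    def test_alpha_conditional_matches_numerical_oracle(self, path_problem):
        Y, g, cfg, prob = self._setup(path_problem)
        start = _path_state()

        st0 = copy.deepcopy(start)
        model._sweep(st0, prob, cfg, _StubRng(0.0))
        cond_mean = st0.alpha
        st1 = copy.deepcopy(start)
        model._sweep(st1, prob, cfg, _StubRng(1.0))
        cond_sd = st1.alpha - cond_mean

        def neg(a):
            s = copy.deepcopy(start)
            s.alpha = a
            return -model.log_joint_density(s, Y, g, cfg)

        opt = minimize_scalar(neg, bounds=(cond_mean - 1, cond_mean + 1),
                              method="bounded", options={"xatol": 1e-10})
        assert cond_mean == pytest.approx(opt.x, abs=1e-6)
        h = 1e-4
        curv = (neg(opt.x + h) - 2 * neg(opt.x) + neg(opt.x - h)) / h ** 2
        assert cond_sd == pytest.approx(1.0 / math.sqrt(curv), rel=1e-6)

    def test_b0_conditional_matches_numerical_oracle(self, path_problem):
        Y, g, cfg, prob = self._setup(path_problem)
        start = _path_state()
        st0 = copy.deepcopy(start)
        model._sweep(st0, prob, cfg, _StubRng(0.0))

        # b0 was drawn after alpha: condition on the updated alpha
        def neg(b):
            s = copy.deepcopy(start)
            s.alpha = st0.alpha
            s.b0 = b
            return -model.log_joint_density(s, Y, g, cfg)

        opt = minimize_scalar(neg, bounds=(st0.b0 - 1, st0.b0 + 1),
                              method="bounded", options={"xatol": 1e-10})
        assert st0.b0 == pytest.approx(opt.x, abs=1e-6)


class TestFit:
    def test_reproducible_given_seeds(self):
        g = sd.make_lattice_graph(2, 2)
        ds = sd.simulate_panel(sd.TrueParams(seed=3), g, range(2000, 2006))
        cfg = ModelConfig(n_iter=300, n_burnin=100, thin=2, seeds=(9, 10))
        a = model.fit(ds.panel, ds.graph, cfg)
        b = model.fit(ds.panel, ds.graph, cfg)
        for name in ("alpha", "b0", "u", "nu", "ub", "nub", "v", "sigma_eps"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_mismatched_graph_errors(self):
        g = sd.make_lattice_graph(2, 2)
        ds = sd.simulate_panel(sd.TrueParams(seed=3), g, range(2000, 2006))
        other = sd.make_lattice_graph(3, 3)
        with pytest.raises(ValueError, match="bind_order"):
            model.fit(ds.panel, other, ModelConfig.desk_scale())

    def test_retained_draw_count(self):
        g = sd.make_lattice_graph(2, 2)
        ds = sd.simulate_panel(sd.TrueParams(seed=3), g, range(2000, 2006))
        cfg = ModelConfig(n_chains=2, n_iter=500, n_burnin=200, thin=3, seeds=(1, 2))
        s = model.fit(ds.panel, ds.graph, cfg)
        assert s.alpha.shape == (2, 100)
        assert np.all(np.isfinite(s.u))

    def test_noiseless_recovery_of_alpha_and_b0(self):
        truth = sd.TrueParams(alpha=3.0, b0=-0.03, sigma_u=1e-4, sigma_nu=1e-4,
                              sigma_ub=1e-4, sigma_nub=1e-4, sigma_v=1e-4,
                              sigma_eps=1e-4, seed=21)
        g = sd.make_lattice_graph(3, 3)
        ds = sd.simulate_panel(truth, g, range(2000, 2010))
        cfg = ModelConfig(n_iter=2000, n_burnin=1000, thin=2, seeds=(3, 4))
        s = model.fit(ds.panel, ds.graph, cfg)
        assert abs(np.median(s.alpha) - 3.0) < 0.005
        assert abs(np.median(s.b0) - (-0.03)) < 0.005

    def test_constraints_preserved_in_retained_draws(self, fitted_world):
        ds, s = fitted_world
        tt = sd.centered_time(s.years)
        # single connected component: plain sums
        assert np.max(np.abs(s.u.sum(axis=-1))) < 1e-9
        assert np.max(np.abs(s.ub.sum(axis=-1))) < 1e-9
        assert np.max(np.abs(s.v.sum(axis=-1))) < 1e-9
        assert np.max(np.abs(s.v @ tt)) < 1e-9


class TestPosteriorSummary:
    def _samples(self, b0, b1, countries=("A",)):
        m, d = 1, len(b0)
        n = len(countries)
        z = np.zeros((m, d, n))
        b1 = np.asarray(b1, dtype=float).reshape(m, d, n)
        return model.PosteriorSamples(
            alpha=np.zeros((m, d)), b0=np.asarray(b0, dtype=float).reshape(m, d),
            u=z.copy(), nu=z.copy(), ub=b1, nub=z.copy(),
            v=np.zeros((m, d, 3)),
            sigma_u=np.ones((m, d)), sigma_nu=np.ones((m, d)),
            sigma_ub=np.ones((m, d)), sigma_nub=np.ones((m, d)),
            sigma_v=np.ones((m, d)), sigma_eps=np.ones((m, d)),
            countries=list(countries), years=[2000, 2001, 2002])

    def test_odd_length_median(self):
        s = self._samples(b0=[0, 0, 0], b1=[-1, 0, 1])
        summary = model.posterior_summary(s)
        assert summary.b1i_median[0] == 0

    def test_median_of_sums_not_sum_of_medians(self):
        s = self._samples(b0=[0, 0, 10], b1=[5, -5, 0])
        summary = model.posterior_summary(s)
        assert summary.b0_plus_b1i_median[0] == 5  # median of [5, -5, 10]
        assert np.median(s.b0) + summary.b1i_median[0] == 0

    def test_single_draw_degenerate(self):
        s = self._samples(b0=[-0.02], b1=[0.01])
        summary = model.posterior_summary(s)
        assert summary.b0_median == -0.02
        assert summary.b1i_median[0] == 0.01
        assert summary.trend_class[0] == "declining_slower_than_global"

    def test_empty_samples_error(self):
        s = self._samples(b0=[0.0], b1=[0.0])
        s.alpha = s.alpha[:, :0]
        with pytest.raises(ValueError):
            model.posterior_summary(s)


def test_save_load_roundtrip(tmp_path, fitted_world):
    _, s = fitted_world
    model.save_samples(s, tmp_path / "samples")
    s2 = model.load_samples(tmp_path / "samples")
    np.testing.assert_array_equal(s.alpha, s2.alpha)
    np.testing.assert_array_equal(s.u, s2.u)
    np.testing.assert_array_equal(s.v, s2.v)
    assert s2.countries == s.countries and s2.years == s.years
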