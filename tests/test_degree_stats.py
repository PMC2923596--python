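"""Degree statistics, the W kernel, smoothing and assortativity."""

import numpy as np
import pytest

import ppinet as pp
from ppinet.degree_stats import smooth_distribution, gaussian_kernel


class TestDegreeDistribution:
    def test_star(self):
        st = pp.degree_distribution(pp.star(3))
        assert st.p == {1: 0.75, 3: 0.25}
        assert st.mean_degree == 1.5

    def test_triangle(self):
        st = pp.degree_distribution(pp.cycle(3))
        assert st.p == {2: 1.0}
        assert st.mean_degree == 2.0
        assert st.joint == {(2, 2): 1.0}

    def test_edgeless(self):
        st = pp.degree_distribution(pp.InteractionNetwork(tuple("abcde"), frozenset()))
        assert st.p == {0: 1.0}
        assert st.mean_degree == 0.0
        assert st.joint == {}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_joint_marginal_identity(self, seed):
        """Sum_k' Pi(k, k') must equal k p(k)/<k> exactly, for every k >= 1."""
        net = pp.erdos_renyi(300, 4.0, seed=seed)
        st = pp.degree_distribution(net)
        marg = {}
        for (k, _), v in st.joint.items():
            marg[k] = marg.get(k, 0.0) + v
        for k, pk in st.p.items():
            if k >= 1:
                assert marg.get(k, 0.0) == pytest.approx(k * pk / st.mean_degree, abs=1e-12)
        assert sum(st.joint.values()) == pytest.approx(1.0, abs=1e-12)


class TestNormalizedDDC:
    def test_single_edge_self_consistency(self):
        st = pp.degree_distribution(pp.perfect_matching(1))
        ddc = pp.normalized_ddc(st)
        assert ddc.value(1, 1) == pytest.approx(1.0)

    def test_star_kernel(self):
        ddc = pp.normalized_ddc(pp.degree_distribution(pp.star(3)))
        assert ddc.value(1, 3) == pytest.approx(2.0)
        assert ddc.value(3, 1) == pytest.approx(2.0)
        assert ddc.value(1, 1) == 0.0
        assert ddc.value(3, 3) == 0.0

    def test_off_support_is_undefined_not_zero(self):
        ddc = pp.normalized_ddc(pp.degree_distribution(pp.star(3)))
        assert np.isnan(ddc.value(2, 2))

    def test_edgeless_error(self):
        st = pp.degree_distribution(pp.InteractionNetwork(("a", "b"), frozenset()))
        with pytest.raises(ValueError):
            pp.normalized_ddc(st)

    def test_weighted_average_is_one(self):
        """Sum u(k) u(k') W(k,k') = 1: the normalisation of Pi."""
        st = pp.degree_distribution(pp.erdos_renyi(400, 5.0, seed=7))
        ddc = pp.normalized_ddc(st)
        kbar = st.mean_degree
        total = sum(
            (k * st.p[k] / kbar) * (kp * st.p[kp] / kbar) * w
            for (k, kp), w in ddc.W.items()
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_uncorrelated_reference_level(self):
        """For a large uniform degree-matched graph, W ~ 1 on well-populated
        bins, within 3 Monte-Carlo standard errors."""
        net = pp.erdos_renyi(5000, 6.0, seed=11)
        st = pp.degree_distribution(net)
        ddc = pp.normalized_ddc(st)
        twoe = 2.0 * st.E
        vals, variances = [], []
        for (k, kp), w in ddc.W.items():
            count = st.joint.get((k, kp), 0.0) * twoe
            if count >= 50:
                vals.append(w)
                variances.append(w * w / count)  # Poisson counting error
        assert len(vals) >= 10
        mean = np.mean(vals)
        se = np.sqrt(np.sum(variances)) / len(vals)
        assert abs(mean - 1.0) < 3 * se


class TestAssortativity:
    def test_star_is_minus_one(self):
        assert pp.assortativity(pp.degree_distribution(pp.star(3))) == pytest.approx(-1.0)

    def test_regular_graph_is_undefined(self):
        assert pp.assortativity(pp.degree_distribution(pp.cycle(4))) is None

    def test_brute_force_pearson_oracle(self):
        # graph {A-B, B-C, C-D, D-E, B-D}
        net = pp.InteractionNetwork.from_pairs(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("B", "D")]
        )
        deg = dict(zip(net.node_ids, net.degree_sequence()))
        xs, ys = [], []
        for a, b in net.edge_names():
            xs += [deg[a], deg[b]]
            ys += [deg[b], deg[a]]
        expected = np.corrcoef(xs, ys)[0, 1]
        got = pp.assortativity(pp.degree_distribution(net))
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pi_route_equals_pw_route(self, seed):
        """Assortativity from Pi and from (p, W) agree to 1e-10 exactly."""
        net = pp.erdos_renyi(200, 4.0, seed=seed)
        st = pp.degree_distribution(net)
        ddc = pp.normalized_ddc(st)
        a1 = pp.assortativity(st)
        a2 = pp.assortativity_from_ddc(st, ddc)
        assert a1 == pytest.approx(a2, abs=1e-10)


class TestSmoothing:
    def test_mass_preserved_and_positive(self):
        p = np.zeros(20)
        p[[2, 7]] = [0.25, 0.75]
        out = smooth_distribution(p, sigma=1.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out > 0)

    def test_small_sigma_limit_recovers_input(self):
        p = np.array([0.1, 0.0, 0.5, 0.4])
        out = smooth_distribution(p, sigma=1e-3)
        assert np.allclose(out, p, atol=1e-10)

    def test_delta_becomes_unimodal_peak(self):
        p = np.zeros(11)
        p[5] = 1.0
        out = smooth_distribution(p, sigma=1.0)
        assert out.argmax() == 5
        assert np.allclose(out[4], out[6], atol=1e-12)  # symmetric around the peak
        assert np.all(np.diff(out[:6]) > 0) and np.all(np.diff(out[5:]) < 0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(5, 0.0)

    def test_profile_smoothing_contract(self):
        net = pp.erdos_renyi(300, 4.0, seed=2)
        prof = pp.characterize(net, sigma=1.0)
        assert prof.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert prof.joint.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(prof.p > 0)
        assert np.all(prof.joint > 0)
        assert np.all(prof.W > 0)
        # weighted average of W under the smoothed edge-end marginal is 1
        u = prof.edge_end_marginal()
        assert float(u @ prof.W @ u) == pytest.approx(1.0, rel=1e-10)
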