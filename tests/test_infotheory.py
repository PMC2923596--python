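"""Complexities, the network distance, and the distance matrix."""

import math

import numpy as np
import pytest

import ppinet as pp


class TestPoissonReference:
    def test_closed_form_values(self):
        pmf, _ = pp.poisson_reference(2.0, 5)
        assert pmf[2] == pytest.approx(2.0 * math.exp(-2.0), rel=1e-12)
        assert pmf[0] == pytest.approx(math.exp(-2.0), rel=1e-12)

    def test_tail_mass_bound(self):
        _, tail = pp.poisson_reference(2.0, 20)
        assert tail < 1e-6
        assert pp.poisson_kmax(2.0, 1e-9) < 40
        _, tail9 = pp.poisson_reference(2.0, pp.poisson_kmax(2.0, 1e-9))
        assert tail9 < 1e-9

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            pp.poisson_reference(0.0, 5)


class TestComplexity:
    def test_large_er_has_vanishing_complexity(self):
        net = pp.erdos_renyi(5000, 6.0, seed=3)
        comp = pp.complexity(pp.characterize(net, sigma=0.0))
        assert comp.degree_complexity_per_node < 0.01
        assert comp.wiring_complexity_per_node < 0.05

    def test_regular_graph_closed_form(self):
        """KL of a point mass at c from Poisson(c) is -ln pi_c(c); c=2."""
        comp = pp.complexity(pp.characterize(pp.cycle(100), sigma=0.0))
        expected = -math.log(2.0 * math.exp(-2.0))
        assert comp.degree_complexity_per_node == pytest.approx(expected, abs=1e-9)
        # a cycle is degree-regular: W == 1 on its single support point
        assert comp.wiring_complexity_per_node == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nonnegativity_and_per_link_identity(self, seed):
        net = pp.planted_correlation(500, 5.0, -0.3, seed=seed)
        comp = pp.complexity(pp.characterize(net, sigma=0.0))
        assert comp.degree_complexity_per_node >= 0
        assert comp.wiring_complexity_per_node >= 0
        half_k = comp.mean_degree / 2.0
        assert comp.degree_complexity_per_link == pytest.approx(
            comp.degree_complexity_per_node / half_k, rel=1e-12)
        assert comp.wiring_complexity_per_link == pytest.approx(
            comp.wiring_complexity_per_node / half_k, rel=1e-12)

    def test_edgeless_error(self):
        net = pp.InteractionNetwork(("a", "b"), frozenset())
        with pytest.raises(ValueError):
            pp.characterize(net, sigma=1.0)


def oracle_distance(net_a, net_b, sigma):
    """Independent term-by-term evaluation of the distance, plain loops."""
    sa = pp.degree_distribution(net_a)
    sb = pp.degree_distribution(net_b)
    kmax = max(max(sa.p), max(sb.p))

    def kernel_col(j, lo, hi):
        raw = {i: math.exp(-((i - j) ** 2) / (2 * sigma**2)) for i in range(lo, hi + 1)}
        z = sum(raw.values())
        return {i: v / z for i, v in raw.items()}

    def smooth_p(stats):
        out = {k: 0.0 for k in range(kmax + 1)}
        for j in range(kmax + 1):
            col = kernel_col(j, 0, kmax)
            for i, w in col.items():
                out[i] += w * stats.p.get(j, 0.0)
        z = sum(out.values())
        return {k: v / z for k, v in out.items()}

    def smooth_joint(stats):
        out = {(k, kp): 0.0 for k in range(1, kmax + 1) for kp in range(1, kmax + 1)}
        cols = {j: kernel_col(j, 1, kmax) for j in range(1, kmax + 1)}
        for (j, jp), v in stats.joint.items():
            for i, w1 in cols[j].items():
                for ip, w2 in cols[jp].items():
                    out[(i, ip)] += w1 * w2 * v
        z = sum(out.values())
        return {k: v / z for k, v in out.items()}

    pa, pb = smooth_p(sa), smooth_p(sb)
    ja, jb = smooth_joint(sa), smooth_joint(sb)
    ka = sum(k * v for k, v in pa.items())
    kb = sum(k * v for k, v in pb.items())

    def W(joint, p, kbar):
        return {
            (k, kp): v * kbar * kbar / (k * p[k] * kp * p[kp])
            for (k, kp), v in joint.items()
        }

    wa, wb = W(ja, pa, ka), W(jb, pb, kb)
    d_p = 0.5 * sum(
        (pa[k] - pb[k]) * (math.log(pa[k]) - math.log(pb[k])) for k in pa
    )
    d_mean = -0.25 * (ka - kb) * math.log(ka / kb)
    d_w = 0.25 * ka * sum(ja[x] * (math.log(wa[x]) - math.log(wb[x])) for x in ja)
    d_w += 0.25 * kb * sum(jb[x] * (math.log(wb[x]) - math.log(wa[x])) for x in jb)
    return d_p + d_mean + d_w, d_p + d_mean


class TestDistance:
    def test_identity(self):
        net = pp.erdos_renyi(200, 4.0, seed=5)
        res = pp.network_distance(net, net, sigma=1.0)
        assert res.full_distance == 0.0
        assert res.degree_only_distance == 0.0

    @pytest.mark.parametrize("seeds", [(0, 1), (2, 3)])
    def test_symmetry(self, seeds):
        a = pp.erdos_renyi(300, 4.0, seed=seeds[0])
        b = pp.planted_correlation(250, 5.0, -0.3, seed=seeds[1])
        d1 = pp.network_distance(a, b, sigma=1.0)
        d2 = pp.network_distance(b, a, sigma=1.0)
        assert d1.full_distance == pytest.approx(d2.full_distance, abs=1e-12)
        assert d1.degree_only_distance == pytest.approx(d2.degree_only_distance, abs=1e-12)

    def test_degree_matched_rewiring_has_zero_degree_distance(self):
        net = pp.planted_correlation(400, 5.0, -0.35, seed=9)
        null = pp.randomise(net, pp.RandomisationConfig(seed=4)).graph
        res = pp.network_distance(net, null, sigma=1.0)
        assert res.degree_only_distance == pytest.approx(0.0, abs=1e-12)
        # the rewiring changed W, so the full distance must see it
        assert res.full_distance > 1e-4

    def test_toy_pair_matches_independent_oracle(self):
        a, b = pp.star(3), pp.cycle(4)
        res = pp.network_distance(a, b, sigma=1.0)
        full, degree_only = oracle_distance(a, b, sigma=1.0)
        assert res.full_distance == pytest.approx(full, abs=1e-9)
        assert res.degree_only_distance == pytest.approx(degree_only, abs=1e-9)
        assert res.ddc_contribution == pytest.approx(full - degree_only, abs=1e-9)

    def test_requires_smoothing(self):
        net = pp.erdos_renyi(100, 3.0, seed=0)
        with pytest.raises(ValueError):
            pp.network_distance(net, net, sigma=0.0)
        a = pp.characterize(net, sigma=1.0)
        b = pp.characterize(net, sigma=0.5)
        with pytest.raises(ValueError):
            pp.profile_distance(a, b)


class TestDistanceMatrix:
    def test_copies_give_zero_matrix(self):
        net = pp.erdos_renyi(150, 4.0, seed=1)
        dm = pp.distance_matrix({"a": net, "b": net, "c": net}, sigma=1.0)
        assert np.allclose(dm.values, 0.0)

    def test_entries_match_pairwise_calls(self):
        nets = {
            "x": pp.erdos_renyi(200, 4.0, seed=1),
            "y": pp.erdos_renyi(200, 6.0, seed=2),
            "z": pp.planted_correlation(200, 5.0, -0.3, seed=3),
        }
        dm = pp.distance_matrix(nets, sigma=1.0)
        kmax = max(int(n.degree_sequence().max()) for n in nets.values())
        for i, li in enumerate(dm.labels):
            for j, lj in enumerate(dm.labels):
                if i < j:
                    ref = pp.network_distance(nets[li], nets[lj], sigma=1.0, kmax=kmax)
                    assert dm.values[i, j] == pytest.approx(ref.full_distance, abs=1e-12)

    def test_permutation_equivariance(self):
        nets = {
            "x": pp.erdos_renyi(120, 4.0, seed=1),
            "y": pp.erdos_renyi(120, 6.0, seed=2),
            "z": pp.erdos_renyi(120, 8.0, seed=3),
        }
        dm1 = pp.distance_matrix(nets, sigma=1.0)
        dm2 = pp.distance_matrix(dict(reversed(list(nets.items()))), sigma=1.0)
        perm = [dm2.labels.index(l) for l in dm1.labels]
        assert np.allclose(dm1.values, dm2.values[np.ix_(perm, perm)], atol=1e-12)

    def test_triangular_tsv(self, tmp_path):
        nets = {"a": pp.erdos_renyi(100, 3.0, seed=1), "b": pp.erdos_renyi(100, 5.0, seed=2)}
        dm = pp.distance_matrix(nets, sigma=1.0)
        out = tmp_path / "dm.tsv"
        dm.to_tsv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["network", "a", "b"]
        assert len(lines[1].split("\t")) == 2  # diagonal only
        assert len(lines[2].split("\t")) == 3

    def test_too_few_networks(self):
        with pytest.raises(ValueError):
            pp.distance_matrix({"a": pp.star(3)})
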