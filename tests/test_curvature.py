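"""Ollivier-Ricci curvature: analytic values, LP oracle, invariances."""

import numpy as np
import pytest

from curvnet.curvature import (
    _transport_lp,
    curvature_result,
    edge_curvature,
    edge_curvatures,
    global_curvature,
    neighbor_measure,
    node_curvature,
    wasserstein1,
)
from curvnet.io import Connectome, ValidationError

from conftest import cycle_weights, make_connectome, make_parcellation, \
    random_connected_weights
from oracles import brute_wasserstein1


class TestNeighborMeasure:
    def test_uniform_on_triangle(self, triangle):
        m = neighbor_measure(triangle, 0, idleness=0.0)
        np.testing.assert_allclose(sorted(m.masses), [0.0, 0.5, 0.5])

    def test_idleness_half_on_triangle(self, triangle):
        m = neighbor_measure(triangle, 0, idleness=0.5)
        assert m.support[0] == 0
        np.testing.assert_allclose(m.masses, [0.5, 0.25, 0.25])

    def test_masses_proportional_to_weights(self):
        conn = make_connectome([[0, 2, 3], [2, 0, 0], [3, 0, 0]])
        m = neighbor_measure(conn, 0, idleness=0.0)
        np.testing.assert_allclose(m.masses[1:], [0.4, 0.6])

    def test_isolated_node_errors(self):
        conn = make_connectome([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        with pytest.raises(ValidationError, match="no incident edges"):
            neighbor_measure(conn, 2)


class TestWasserstein1:
    def test_identity_is_zero(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        s = (np.array([0, 1]), np.array([0.5, 0.5]))
        assert wasserstein1(s, s, D) == 0.0

    def test_point_masses_cost_ground_distance(self):
        D = np.array([[0, 2.5], [2.5, 0]])
        w = wasserstein1((np.array([0]), np.array([1.0])),
                         (np.array([1]), np.array([1.0])), D)
        assert w == 2.5

    def test_half_shift_along_a_line(self):
        # a-b-c collinear; shifting mu={a:1/2,b:1/2} one step to
        # nu={b:1/2,c:1/2} costs (total mass) x (step): the 1-D closed
        # form W1 = integral |F_mu - F_nu|.
        mu = (np.array([0, 1]), np.array([0.5, 0.5]))
        nu = (np.array([1, 2]), np.array([0.5, 0.5]))
        line = np.abs(np.subtract.outer(np.arange(3.0), np.arange(3.0)))
        np.testing.assert_allclose(wasserstein1(mu, nu, line), 1.0)
        # on a line of unit total length (spacing 1/2) the same shift costs 1/2
        np.testing.assert_allclose(wasserstein1(mu, nu, line / 2), 0.5)

    def test_disconnected_supports_error(self):
        D = np.array([[0, np.inf], [np.inf, 0]])
        with pytest.raises(ValidationError, match="disconnected"):
            wasserstein1((np.array([0]), np.array([1.0])),
                         (np.array([1]), np.array([1.0])), D)

    def test_lp_matches_transport_polytope_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            na, nb = int(rng.integers(2, 4)), int(rng.integers(2, 4))
            cost = rng.random((na, nb)) * 3
            a = rng.random(na) + 0.05
            a /= a.sum()
            b = rng.random(nb) + 0.05
            b /= b.sum()
            np.testing.assert_allclose(
                _transport_lp(cost, a, b), brute_wasserstein1(a, b, cost),
                atol=1e-9,
            )

    def test_metric_properties_on_random_instances(self):
        rng = np.random.default_rng(8)
        # ground metric: unit line 0-1-2-3
        D = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        sup = np.arange(4)
        for _ in range(25):
            m1, m2, m3 = (rng.random(4) + 0.01 for _ in range(3))
            m1, m2, m3 = m1 / m1.sum(), m2 / m2.sum(), m3 / m3.sum()
            w12 = wasserstein1((sup, m1), (sup, m2), D)
            w13 = wasserstein1((sup, m1), (sup, m3), D)
            w23 = wasserstein1((sup, m2), (sup, m3), D)
            assert w13 <= w12 + w23 + 1e-9
            assert wasserstein1((sup, m1), (sup, m1), D) <= 1e-12


class TestEdgeCurvature:
    def test_triangle_idleness_zero(self, triangle):
        np.testing.assert_allclose(edge_curvature(triangle, 0, 1, idleness=0.0), 0.5)

    def test_triangle_idleness_half(self, triangle):
        np.testing.assert_allclose(edge_curvature(triangle, 0, 1, idleness=0.5), 0.75)

    def test_hexagon_is_flat(self, hexagon):
        np.testing.assert_allclose(edge_curvature(hexagon, 0, 1, idleness=0.0),
                                   0.0, atol=1e-12)

    def test_no_edge_errors(self, path3):
        with pytest.raises(ValidationError, match="no edge"):
            edge_curvature(path3, 0, 2)

    def test_two_node_graph_idleness_zero(self):
        # measures are point masses at the opposite ends: W1 = d, kappa = 0
        conn = make_connectome([[0, 1], [1, 0]])
        np.testing.assert_allclose(edge_curvature(conn, 0, 1, idleness=0.0), 0.0)

    def test_symmetric_in_edge_orientation(self):
        rng = np.random.default_rng(1)
        conn = make_connectome(random_connected_weights(rng, 6))
        i, j = conn.edge_list()[2][:2]
        np.testing.assert_allclose(edge_curvature(conn, i, j),
                                   edge_curvature(conn, j, i), atol=1e-12)

    def test_kappa_at_most_one(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            conn = make_connectome(random_connected_weights(rng, 7))
            for k in edge_curvatures(conn).values():
                assert k <= 1.0 + 1e-12


class TestSolverEquivalence:
    def test_simplex_matches_lp_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for idl in (0.0, 0.3, 0.5):
            for _ in range(5):
                conn = make_connectome(random_connected_weights(rng, 8))
                ks = edge_curvatures(conn, idleness=idl, solver="simplex")
                kl = edge_curvatures(conn, idleness=idl, solver="lp")
                for e in ks:
                    np.testing.assert_allclose(ks[e], kl[e], atol=1e-9)

    def test_reduction_matches_unreduced_single_edge_lp(self):
        """Common-mass reduction must not change the optimum."""
        rng = np.random.default_rng(22)
        for _ in range(5):
            conn = make_connectome(random_connected_weights(rng, 7))
            ks = edge_curvatures(conn, idleness=0.5)
            for (i, j) in list(ks)[:4]:
                np.testing.assert_allclose(
                    ks[(i, j)], edge_curvature(conn, i, j, idleness=0.5),
                    atol=1e-9,
                )


class TestNodeAndGlobal:
    def test_triangle_node_curvature(self, triangle):
        np.testing.assert_allclose(node_curvature(triangle, idleness=0.0),
                                   [0.5, 0.5, 0.5])

    def test_vertex_transitive_graph_uniform(self, hexagon):
        nk = node_curvature(hexagon, idleness=0.5)
        np.testing.assert_allclose(nk, nk[0])

    def test_isolated_node_is_nan(self):
        conn = make_connectome([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        nk = node_curvature(conn)
        assert np.isnan(nk[2]) and not np.isnan(nk[0])

    def test_global_triangle_and_hexagon(self, triangle, hexagon):
        np.testing.assert_allclose(global_curvature(triangle, idleness=0.0), 0.5)
        np.testing.assert_allclose(global_curvature(hexagon, idleness=0.0),
                                   0.0, atol=1e-12)

    def test_complete_graph_sweep_against_lp_oracle(self):
        for n in range(3, 7):
            conn = make_connectome(1.0 - np.eye(n))
            fast = global_curvature(conn, idleness=0.0)
            ref = global_curvature(conn, idleness=0.0,
                                   edge_kappa=edge_curvatures(conn, idleness=0.0,
                                                              solver="lp"))
            np.testing.assert_allclose(fast, ref, atol=1e-9)
            # K_n edge curvature at idleness 0 is n/(2(n-1)) + (n-2)/(n-1) - 1/2...
            # spot-check monotone growth towards 1 instead of a closed form
            if n > 3:
                prev = global_curvature(make_connectome(1.0 - np.eye(n - 1)),
                                        idleness=0.0)
                assert fast > prev

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValidationError):
            global_curvature(make_connectome(np.zeros((3, 3))))

    def test_hop_metric_scale_invariance(self):
        rng = np.random.default_rng(30)
        W = random_connected_weights(rng, 7)
        a = edge_curvatures(make_connectome(W), ground_metric="hop")
        b = edge_curvatures(make_connectome(10.0 * W), ground_metric="hop")
        for e in a:
            np.testing.assert_allclose(a[e], b[e], atol=1e-10)

    def test_locality_two_hop_neighbourhood(self):
        """Perturbing one edge's weight only moves curvature within two hops."""
        n = 9
        W = cycle_weights(n)  # long cycle: far nodes are > 2 hops away
        conn = make_connectome(W)
        base = node_curvature(conn, idleness=0.5)
        W2 = W.copy()
        W2[0, 1] = W2[1, 0] = 3.0
        pert = node_curvature(make_connectome(W2), idleness=0.5)
        hop = np.minimum(np.arange(n), n - np.arange(n))  # distance to node 0
        hop1 = np.minimum(np.abs(np.arange(n) - 1), n - np.abs(np.arange(n) - 1))
        far = (hop > 2) & (hop1 > 2)
        np.testing.assert_allclose(pert[far], base[far], atol=1e-10)
        assert np.abs(pert[[0, 1]] - base[[0, 1]]).max() > 1e-6

    def test_curvature_result_bundles_consistently(self, triangle):
        res = curvature_result(triangle, idleness=0.0)
        np.testing.assert_allclose(res.global_curvature, 0.5)
        assert res.params["ground_metric"] == "hop"
        assert set(res.edge_curvatures) == {(0, 1), (0, 2), (1, 2)}
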