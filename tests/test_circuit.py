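import numpy as np
import pytest

from keynodes import (
    ConductanceNetwork,
    GROUND,
    SolverError,
    edge_currents,
    solve_directed,
    solve_undirected,
)
from oracles import diode_state_solve, pinv_potentials, random_connected_graph


def kirchhoff_residuals(net, pot):
    """Net signed current imbalance at each node (ground branch included)."""
    flows = edge_currents(net, pot)
    resid = {n: 0.0 for n in net.nodes}
    for (u, v), f in flows.flows.items():
        resid[u] -= f
        resid[v] += f
    for n, f in flows.ground_flows.items():
        resid[n] -= f
    return resid


class TestUndirectedSolver:
    def test_series_resistors(self):
        net = ConductanceNetwork.from_edges([("s", "m"), ("m", "t")])
        pot = solve_undirected(net, "s", "t")
        flows = edge_currents(net, pot)
        assert flows.flow("s", "m") == pytest.approx(1.0, abs=1e-10)
        assert flows.flow("m", "t") == pytest.approx(1.0, abs=1e-10)
        assert pot["s"] - pot["t"] == pytest.approx(2.0, abs=1e-10)

    def test_parallel_paths_split_evenly(self):
        net = ConductanceNetwork.from_edges(
            [("s", "a"), ("a", "t"), ("s", "b"), ("b", "t")]
        )
        pot = solve_undirected(net, "s", "t")
        flows = edge_currents(net, pot)
        assert flows.flow("s", "a") == pytest.approx(0.5, abs=1e-10)
        assert flows.flow("s", "b") == pytest.approx(0.5, abs=1e-10)

    def test_target_is_grounded_and_minimal(self):
        net = ConductanceNetwork.from_edges([("s", "m"), ("m", "t"), ("s", "t")])
        pot = solve_undirected(net, "s", "t")
        assert pot["t"] == 0.0
        assert all(v >= -1e-12 for v in pot.voltages.values())

    @pytest.mark.parametrize("method", ["direct", "jacobi"])
    def test_matches_pseudoinverse_oracle(self, method):
        rng = np.random.default_rng(7)
        for _ in range(10):
            net = random_connected_graph(rng, n_max=6, weighted=True)
            nodes = net.nodes
            s, t = nodes[0], nodes[-1]
            pot = solve_undirected(net, s, t, method=method, tol=1e-12)
            oracle = pinv_potentials(net, s, t)
            for n in nodes:
                assert pot[n] == pytest.approx(oracle[n], abs=1e-8)

    def test_jacobi_and_direct_agree(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            net = random_connected_graph(rng, n_max=6)
            s, t = net.nodes[0], net.nodes[-1]
            a = solve_undirected(net, s, t, method="direct")
            b = solve_undirected(net, s, t, method="jacobi", tol=1e-11)
            for n in net.nodes:
                assert a[n] == pytest.approx(b[n], abs=1e-9)

    def test_different_components_rejected(self):
        net = ConductanceNetwork.from_edges([("a", "b"), ("c", "d")])
        with pytest.raises(SolverError, match="different components"):
            solve_undirected(net, "a", "c")

    def test_source_equals_target_rejected(self):
        net = ConductanceNetwork.from_edges([("a", "b")])
        with pytest.raises(SolverError, match="differ"):
            solve_undirected(net, "a", "a")

    def test_jacobi_nonconvergence_reports_residual(self):
        net = ConductanceNetwork.from_edges([(i, i + 1) for i in range(20)])
        with pytest.raises(SolverError, match="residual"):
            solve_undirected(net, "0", "20", method="jacobi", tol=1e-12, max_iter=5)


class TestEdgeCurrents:
    def test_flows_follow_ohms_law(self):
        net = ConductanceNetwork.from_edges([("s", "m", 2.0), ("m", "t", 2.0)])
        pot = solve_undirected(net, "s", "t")
        flows = edge_currents(net, pot)
        assert flows.flow("s", "m") == pytest.approx(
            2.0 * (pot["s"] - pot["m"]), abs=1e-12
        )

    def test_antisymmetry(self):
        net = ConductanceNetwork.from_edges([("s", "m"), ("m", "t")])
        flows = edge_currents(net, solve_undirected(net, "s", "t"))
        assert flows.flow("m", "s") == -flows.flow("s", "m")

    def test_node_mismatch_rejected(self):
        net = ConductanceNetwork.from_edges([("s", "t")])
        other = ConductanceNetwork.from_edges([("s", "t"), ("t", "u")])
        pot = solve_undirected(net, "s", "t")
        with pytest.raises(ValueError, match="node set"):
            edge_currents(other, pot)


class TestDirectedSolver:
    def test_forward_diode_conducts(self):
        net = ConductanceNetwork.from_edges([("s", "t")], directed=True)
        pot = solve_directed(net, "s")
        flows = edge_currents(net, pot)
        assert flows.flow("s", "t") > 0
        assert 0 < pot["t"] < pot["s"]

    def test_reverse_diode_blocks(self):
        net = ConductanceNetwork.from_edges([("t", "s")], directed=True)
        pot = solve_directed(net, "s")
        flows = edge_currents(net, pot)
        assert flows.flow("t", "s") == 0.0
        # all injected current leaves through the source's ground branch
        assert flows.ground_flows["s"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_diode_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(6):
            n = int(rng.integers(3, 6))
            arcs = set()
            while len(arcs) < min(8, n * (n - 1) // 2 + 2):
                u, v = rng.choice(n, size=2, replace=False)
                arcs.add((f"n{u}", f"n{v}"))
            net = ConductanceNetwork.from_edges(sorted(arcs), directed=True)
            for s in net.nodes:
                pot = solve_directed(net, s)
                oracle = diode_state_solve(net, s)
                for x in net.nodes:
                    assert pot[x] == pytest.approx(oracle[x], abs=1e-8)

    def test_no_negative_arc_flow_ever(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = int(rng.integers(4, 8))
            arcs = {
                (f"n{u}", f"n{v}")
                for u, v in rng.integers(0, n, size=(3 * n, 2))
                if u != v
            }
            net = ConductanceNetwork.from_edges(sorted(arcs), directed=True)
            for s in net.nodes:
                flows = edge_currents(net, solve_directed(net, s))
                assert all(f >= 0 for f in flows.flows.values())

    def test_bad_ground_conductance_rejected(self):
        net = ConductanceNetwork.from_edges([("a", "b")], directed=True)
        with pytest.raises(SolverError, match="ground_conductance"):
            solve_directed(net, "a", ground_conductance=0.0)

    def test_nonconvergence_raises(self):
        net = ConductanceNetwork.from_edges([("a", "b"), ("b", "c")], directed=True)
        with pytest.raises(SolverError, match="converge"):
            solve_directed(net, "a", tol=1e-14, max_iter=2)


class TestCircuitInvariants:
    def test_conservation_undirected(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            net = random_connected_graph(rng, n_max=8, weighted=True)
            s, t = net.nodes[0], net.nodes[-1]
            pot = solve_undirected(net, s, t)
            resid = kirchhoff_residuals(net, pot)
            # interior nodes balance; source sheds +1, target absorbs -1
            for n, r in resid.items():
                expect = {s: -1.0, t: 1.0}.get(n, 0.0)
                assert r == pytest.approx(expect, abs=1e-8)

    def test_conservation_directed_with_ground(self):
        rng = np.random.default_rng(17)
        arcs = {
            (f"n{u}", f"n{v}")
            for u, v in rng.integers(0, 6, size=(14, 2))
            if u != v
        }
        net = ConductanceNetwork.from_edges(sorted(arcs), directed=True)
        for s in net.nodes:
            pot = solve_directed(net, s)
            resid = kirchhoff_residuals(net, pot)
            for n, r in resid.items():
                expect = -1.0 if n == s else 0.0
                assert r == pytest.approx(expect, abs=1e-8)
            # everything injected ends up in the ground
            flows = edge_currents(net, pot)
            assert sum(flows.ground_flows.values()) == pytest.approx(1.0, abs=1e-8)

    def test_grounding_choice_shifts_potentials_by_constant(self):
        net = ConductanceNetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c", 0.5)])
        fwd = solve_undirected(net, "a", "c")
        rev = solve_undirected(net, "c", "a")
        # reversing the roles negates all potential differences
        for x, y in [("a", "b"), ("b", "c")]:
            assert fwd[x] - fwd[y] == pytest.approx(-(rev[x] - rev[y]), abs=1e-10)

    def test_conductance_rescaling_leaves_currents_unchanged(self):
        base = [("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 0.5)]
        k = 7.3
        net1 = ConductanceNetwork.from_edges(base)
        net2 = ConductanceNetwork.from_edges([(u, v, k * c) for u, v, c in base])
        f1 = edge_currents(net1, solve_undirected(net1, "a", "c"))
        f2 = edge_currents(net2, solve_undirected(net2, "a", "c"))
        for key in f1.flows:
            assert f1.flows[key] == pytest.approx(f2.flows[key], abs=1e-10)

    def test_solution_commutes_with_relabeling(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")]
        mapping = {"a": "w", "b": "x", "c": "y", "d": "z"}
        net1 = ConductanceNetwork.from_edges(edges)
        net2 = ConductanceNetwork.from_edges(
            [(mapping[u], mapping[v]) for u, v in edges]
        )
        p1 = solve_undirected(net1, "a", "d")
        p2 = solve_undirected(net2, "w", "z")
        for n, m in mapping.items():
            assert p1[n] == pytest.approx(p2[m], abs=1e-12)
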