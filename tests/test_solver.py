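import numpy as np
import pytest

from trenshsim import (kirchhoff_residuals, make_pressure_set,
                       node_pressures, solve, total_nidal_flow)
from trenshsim.errors import SingularSystemError
from trenshsim.solver import boundary_outflow
from trenshsim.units import MMHG

from conftest import make_toy_network, toy_pressure_set
from oracle_utils import dense_flow_oracle


class TestToyCircuits:
    def test_two_resistors_in_series(self):
        r = 5000.0
        net = make_toy_network(
            [("v1", "A", "M"), ("v2", "M", "B")], [r, r], "v1", "v2")
        sol = solve(net, toy_pressure_set(10.0, 0.0))[0]
        q_expected = 10.0 * MMHG / (2 * r)
        assert sol.flow("v1") == pytest.approx(q_expected, rel=1e-12)
        assert sol.flow("v2") == pytest.approx(q_expected, rel=1e-12)
        assert sol.pressure("M") == pytest.approx(5.0, rel=1e-9)

    def test_no_gradient_means_no_flow(self):
        net = make_toy_network(
            [("v1", "A", "M"), ("v2", "M", "B")], [1000.0, 2000.0],
            "v1", "v2")
        sol = solve(net, toy_pressure_set(25.0, 25.0))[0]
        assert np.abs(sol.q).max() < 1e-14

    def test_series_emf_drives_flow(self):
        # EDV-style source (polarity -1) opposes the nominal direction
        net = make_toy_network(
            [("v1", "A", "M"), ("v2", "M", "B")], [1000.0, 1000.0],
            "v1", "v2", series_emfs=[("EDV1", "v2", -1)])
        sol = solve(net, toy_pressure_set(0.0, 0.0, EDV1=10.0))[0]
        assert sol.flow("v2") == pytest.approx(-10 * MMHG / 2000, rel=1e-12)

    def test_superposition(self):
        edges = [("v1", "A", "M"), ("v2", "M", "B"), ("v3", "A", "B"),
                 ("v4", "M", "C"), ("v5", "C", "B")]
        rs = [1000.0, 2000.0, 3000.0, 1500.0, 2500.0]
        net = make_toy_network(edges, rs, "v1", "v2",
                               series_emfs=[("EDV1", "v5", -1)])
        s_a = solve(net, toy_pressure_set(50.0, 5.0))[0]
        s_b = solve(net, toy_pressure_set(0.0, 0.0, EDV1=20.0))[0]
        s_ab = solve(net, toy_pressure_set(50.0, 5.0, EDV1=20.0))[0]
        assert np.allclose(s_ab.q, s_a.q + s_b.q, rtol=1e-10, atol=1e-15)

    def test_tbo_never_increases_total_inflow(self):
        # two parallel feeders from one source; occluding one cannot raise
        # the total delivered flow
        edges = [("f1", "A", "M"), ("f2", "A", "M"), ("out", "M", "B")]
        net = make_toy_network(edges, [1000.0, 4000.0, 500.0], "f1", "out")
        full = solve(net, toy_pressure_set(40.0))[0].flow("out")
        from trenshsim.solver import _Topology
        cut = _Topology(net, frozenset({"f2"}))
        reduced = cut.solve_sets([toy_pressure_set(40.0)])[0].flow("out")
        assert reduced <= full + 1e-12

    def test_disconnecting_cut_raises(self):
        net = make_toy_network(
            [("v1", "A", "M"), ("v2", "M", "B")], [1000.0, 1000.0],
            "v1", "v2")
        from trenshsim.solver import _Topology
        with pytest.raises(SingularSystemError):
            _Topology(net, frozenset({"v2"}))


class TestDenseOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_networks_match_lstsq_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_nodes = int(rng.integers(6, 16))
        names = [f"n{i}" for i in range(n_nodes)]
        edges, seen = [], set()
        # random spanning tree first, then extra chords (simple graph)
        for i in range(1, n_nodes):
            j = int(rng.integers(0, i))
            edges.append((f"e{len(edges)}", names[j], names[i]))
            seen.add((j, i))
        target_edges = min(50, n_nodes + int(rng.integers(3, 12)))
        while len(edges) < target_edges:
            a, b = sorted(rng.choice(n_nodes, 2, replace=False))
            if (a, b) in seen:
                continue
            seen.add((a, b))
            edges.append((f"e{len(edges)}", names[a], names[b]))
        rs = rng.uniform(200, 2e4, len(edges))
        series = [("EAF1", edges[1][0], 1), ("EDV1", edges[2][0], -1)]
        net = make_toy_network(edges, rs, edges[0][0], edges[-1][0],
                               series_emfs=series)
        pset = toy_pressure_set(60.0, 4.0, EAF1=7.0, EDV1=12.0)
        sol = solve(net, pset)[0]
        oracle = dense_flow_oracle(net, pset)
        scale = max(max(abs(q) for q in oracle.values()), 1e-9)
        for vid, q in oracle.items():
            assert abs(sol.flow(vid) - q) / scale < 1e-8


class TestFullModel:
    def test_template_without_nidus_is_open_circuit(self, template):
        with pytest.raises(SingularSystemError):
            solve(template, make_pressure_set(template.config))

    def test_kirchhoff_residuals(self, network, config):
        for pset in [make_pressure_set(config),
                     make_pressure_set(config, "profound", "high", "AF2",
                                       ("DV2", 30.0))]:
            sol = solve(network, pset)[0]
            res = kirchhoff_residuals(sol)
            assert res.max_node_residual < 1e-9
            assert res.max_cycle_residual < 1e-9
            assert res.n_cycles > 100

    def test_poiseuille_consistency(self, network, config):
        sol = solve(network, make_pressure_set(config, "moderate"))[0]
        c = network.compiled()
        dp = sol.dp_array() * MMHG
        # R_v * Q equals the potential difference plus series EMFs
        assert np.allclose(dp, c["resistance"] * sol.q, rtol=1e-12)

    def test_boundary_conservation(self, network, config):
        sol = solve(network, make_pressure_set(config))[0]
        q_in = total_nidal_flow(sol)
        q_out = boundary_outflow(sol)
        assert q_out == pytest.approx(q_in, rel=1e-9)

    def test_pressure_profile_is_arteriovenous(self, network, config):
        p = node_pressures(solve(network, make_pressure_set(config))[0])
        entries = [p[f"AF{i}t"] for i in range(1, 5)]
        exits = [p[f"DV{i}t"] for i in range(1, 4)]
        assert min(entries) > max(exits)
        assert p["aortic-root"] == pytest.approx(74.0)
        assert p["vc-outlet"] == pytest.approx(6.0)

    def test_batched_and_single_solves_agree(self, network, config):
        sets = [make_pressure_set(config, h) for h in
                ("normo", "mild", "moderate", "profound")]
        batched = solve(network, sets)
        for pset, b in zip(sets, batched):
            single = solve(network, pset)[0]
            assert np.allclose(single.q, b.q, rtol=1e-12, atol=1e-18)

    def test_tbo_changes_topology_but_solves(self, network, config):
        sol = solve(network, make_pressure_set(config, tbo="AF1"))[0]
        assert sol.flow("AF1") == 0.0
        assert total_nidal_flow(sol) > 0
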