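"""Circuit assembly and solve: hand oracles, stamps, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemoshock import circuit as ckt
from oracles import dense_kcl_solve, random_circuit


def make_divider():
    g = ckt.CircuitGraph()
    gnd = g.add_node("gnd", is_ground=True)
    n1 = g.add_node("n1")
    n2 = g.add_node("n2")
    g.add_pressure_source(n1, gnd, 10.0, label="pump")
    g.add_resistor(n1, n2, 1.0)
    g.add_resistor(n2, gnd, 4.0)
    return g, n1, n2


class TestAssembleAndSolve:
    def test_ohms_law_single_resistor(self):
        g = ckt.CircuitGraph()
        gnd = g.add_node("gnd", is_ground=True)
        n1 = g.add_node("n1")
        g.add_pressure_source(n1, gnd, 10.0)
        g.add_resistor(n1, gnd, 2.0)
        sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
        assert sol.pressures[n1] == pytest.approx(10.0)
        assert list(sol.source_flows.values())[0] == pytest.approx(5.0)

    def test_pressure_divider(self):
        g, n1, n2 = make_divider()
        sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
        assert sol.pressures[n1] == pytest.approx(10.0)
        assert sol.pressures[n2] == pytest.approx(8.0)

    def test_zero_sources_zero_pressures(self):
        g = ckt.CircuitGraph()
        gnd = g.add_node("gnd", is_ground=True)
        n1 = g.add_node("n1")
        n2 = g.add_node("n2")
        g.add_resistor(n1, gnd, 2.0)
        g.add_resistor(n1, n2, 1.0)
        g.add_capacitor(n2, gnd, 1.5)  # zero history
        sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
        assert np.allclose(sol.pressures, 0.0)

    def test_resistor_matrix_symmetric(self):
        g, *_ = make_divider()
        sys_ = ckt.assemble_mna(g, 0.05)
        nn = sys_.n_nodes
        G = sys_.matrix[:nn, :nn]
        assert np.allclose(G, G.T)

    def test_no_ground_raises(self):
        g = ckt.CircuitGraph()
        g.add_node("a")
        g.add_node("b")
        g.add_resistor(0, 1, 1.0)
        with pytest.raises(ckt.CircuitError, match="ground"):
            ckt.assemble_mna(g, 0.05)

    def test_nonpositive_resistance_rejected(self):
        g = ckt.CircuitGraph()
        g.add_node("gnd", is_ground=True)
        g.add_node("a")
        with pytest.raises(ckt.CircuitError, match="resistance"):
            g.add_resistor(0, 1, 0.0)

    def test_floating_node_named_in_error(self):
        g = ckt.CircuitGraph()
        g.add_node("gnd", is_ground=True)
        g.add_node("a")
        g.add_node("floaty")
        g.add_resistor(0, 1, 1.0)
        g.add_pressure_source(1, 0, 5.0)
        with pytest.raises(ckt.SingularCircuitError, match="floaty"):
            ckt.solve_step(ckt.assemble_mna(g, 0.05), g)


class TestCapacitorStamp:
    def test_zero_compliance_leaves_system_unchanged(self):
        g, *_ = make_divider()
        ref = ckt.assemble_mna(g, 0.05)
        sys_ = ckt.assemble_mna(g, 0.05)
        cap = ckt.Element(ckt.ElementKind.CAPACITOR, 1, 2, compliance=0.0)
        ckt.stamp_capacitor(sys_, cap, 0.05)
        assert np.array_equal(sys_.matrix, ref.matrix)
        assert np.array_equal(sys_.rhs, ref.rhs)

    def test_conductance_is_c_over_dt(self):
        g, n1, n2 = make_divider()
        before = ckt.assemble_mna(g, 0.05).matrix.copy()
        sys_ = ckt.assemble_mna(g, 0.05)
        cap = ckt.Element(ckt.ElementKind.CAPACITOR, n1, n2, compliance=2.0)
        ckt.stamp_capacitor(sys_, cap, 0.05)
        delta = sys_.matrix - before
        i, j = sys_.node_index[n1], sys_.node_index[n2]
        assert delta[i, i] == pytest.approx(40.0)
        assert delta[j, j] == pytest.approx(40.0)
        assert delta[i, j] == pytest.approx(-40.0)
        assert delta[j, i] == pytest.approx(-40.0)

    def test_constant_equal_endpoint_pressures_no_flow(self):
        g = ckt.CircuitGraph()
        gnd = g.add_node("gnd", is_ground=True)
        n1 = g.add_node("n1")
        n2 = g.add_node("n2")
        g.add_pressure_source(n1, gnd, 5.0)
        g.add_resistor(n1, n2, 1e6)  # isolate; holds both nodes at 5
        g.add_pressure_source(n2, gnd, 5.0)
        cap = g.add_capacitor(n1, n2, 2.0)
        cap.previous_pressures = (5.0, 5.0)
        sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
        assert ckt.element_flow(cap, sol.pressures, 0.05) == pytest.approx(0.0)

    def test_dt_must_be_positive(self):
        sys_ = ckt.assemble_mna(make_divider()[0], 0.05)
        cap = ckt.Element(ckt.ElementKind.CAPACITOR, 1, 2, compliance=1.0)
        with pytest.raises(ckt.CircuitError):
            ckt.stamp_capacitor(sys_, cap, 0.0)

    def test_rc_discharge_backward_euler_closed_form(self):
        """One backward-Euler step of RC discharge: V' = (C/dt)/((C/dt)+1/R)·V."""
        g = ckt.CircuitGraph()
        gnd = g.add_node("gnd", is_ground=True)
        n1 = g.add_node("n1", pressure=1.0)
        g.add_capacitor(n1, gnd, 1.0)
        g.add_resistor(n1, gnd, 1.0)
        sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
        assert sol.pressures[n1] == pytest.approx(20.0 / 21.0, rel=1e-12)

    @given(r=st.floats(0.01, 100.0), c=st.floats(0.01, 100.0),
           dt=st.floats(0.001, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_discharge_gain_strictly_inside_unit_interval(self, r, c, dt):
        """Backward-Euler stability: the RC discharge map contracts for any R, C."""
        g = ckt.CircuitGraph()
        gnd = g.add_node("gnd", is_ground=True)
        n1 = g.add_node("n1", pressure=1.0)
        g.add_capacitor(n1, gnd, c)
        g.add_resistor(n1, gnd, r)
        sol = ckt.solve_step(ckt.assemble_mna(g, dt), g)
        assert 0.0 < sol.pressures[n1] < 1.0


class TestOracleEquivalence:
    def test_matches_dense_kcl_solve_on_random_small_circuits(self):
        """MNA equals an independent raw-KCL dense solve on <=6-node circuits."""
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(2, 7))
            g = random_circuit(rng, n)
            sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
            expected = dense_kcl_solve(g, 0.05)
            scale = max(1.0, np.max(np.abs(expected)))
            assert np.max(np.abs(sol.pressures - expected)) < 1e-8 * scale

    def test_flow_conservation_at_every_node(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            g = random_circuit(rng, int(rng.integers(3, 7)))
            sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
            flows = np.zeros(len(g.nodes))
            for k, e in enumerate(g.elements):
                if e.kind is ckt.ElementKind.PRESSURE_SOURCE:
                    q = sol.source_flows[k]
                    flows[e.node_a] += q
                    flows[e.node_b] -= q
                else:
                    q = ckt.element_flow(e, sol.pressures, 0.05)
                    flows[e.node_a] -= q
                    flows[e.node_b] += q
            biggest = max(np.max(np.abs(flows)), 1.0)
            for node in g.nodes:
                if not node.is_ground:
                    assert abs(flows[node.id]) < 1e-8 * biggest


class TestVolumes:
    def _loop(self):
        """Two-compartment closed loop with unequal initial pressures."""
        g = ckt.CircuitGraph()
        gnd = g.add_node("gnd", is_ground=True)
        a = g.add_node("a", pressure=10.0)
        b = g.add_node("b", pressure=2.0)
        ca = g.add_capacitor(a, gnd, 20.0)
        cb = g.add_capacitor(b, gnd, 30.0)
        g.add_resistor(a, b, 1.0)
        g.add_resistor(b, a, 5.0)
        return g, ca, cb

    def test_closed_loop_conserves_total_volume(self):
        g, *_ = self._loop()
        total0 = g.total_stored_volume()
        for _ in range(500):
            sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
            ckt.update_volumes(g, sol, 0.05)
        assert g.total_stored_volume() == pytest.approx(total0, abs=1e-9)

    def test_closed_loop_relaxes_to_uniform_pressure(self):
        g, ca, cb = self._loop()
        for _ in range(4000):
            sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
            ckt.update_volumes(g, sol, 0.05)
        assert g.nodes[1].pressure == pytest.approx(g.nodes[2].pressure, abs=1e-6)

    def test_sink_removes_rate_times_time(self):
        """100 mL/min sink for 60 s drains exactly 100 mL."""
        g, ca, cb = self._loop()
        g.add_flow_source(1, 0, 100.0 / 60.0)  # out of node a to ground
        total0 = g.total_stored_volume()
        for _ in range(1200):  # 60 s at dt = 0.05
            sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
            ckt.update_volumes(g, sol, 0.05)
        assert total0 - g.total_stored_volume() == pytest.approx(100.0, rel=1e-9)

    def test_zero_flows_leave_volumes_unchanged(self):
        g = ckt.CircuitGraph()
        gnd = g.add_node("gnd", is_ground=True)
        a = g.add_node("a", pressure=5.0)
        b = g.add_node("b", pressure=5.0)
        ca = g.add_capacitor(a, gnd, 2.0)
        cb = g.add_capacitor(b, gnd, 3.0)
        g.add_resistor(a, b, 1.0)
        v0 = (ca.stored_volume, cb.stored_volume)
        sol = ckt.solve_step(ckt.assemble_mna(g, 0.05), g)
        ckt.update_volumes(g, sol, 0.05)
        assert (ca.stored_volume, cb.stored_volume) == pytest.approx(v0)
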