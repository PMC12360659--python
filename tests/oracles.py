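"""Independent brute-force oracles used by the test suite.

These re-derive the same physics from first principles along a different
code path than the package (no stamping, no Brent bracketing) so that
agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

from hemoshock.circuit import CircuitGraph, ElementKind


def dense_kcl_solve(graph: CircuitGraph, dt: float) -> np.ndarray:
    """Solve the circuit by writing raw KCL/KVL equations per node.

    Unknowns: every node pressure (ground included) plus one flow per
    pressure source.  Equations: P_ground = 0; flow balance at each
    non-ground node with element flows written inline (resistor Ohm's law,
    capacitor backward Euler, constant flow sources); one pressure
    constraint per source.  Solved as a dense linear system.
    """
    n = len(graph.nodes)
    sources = [e for e in graph.elements
               if e.kind is ElementKind.PRESSURE_SOURCE]
    dim = n + len(sources)
    A = np.zeros((dim, dim))
    b = np.zeros(dim)
    rows = []

    # ground reference
    grow = np.zeros(dim)
    grow[graph.ground.id] = 1.0
    rows.append((grow, 0.0))

    # KCL at each non-ground node: total inflow = 0
    for node in graph.nodes:
        if node.is_ground:
            continue
        row = np.zeros(dim)
        rhs = 0.0
        for k, e in enumerate(graph.elements):
            a_id, b_id = e.node_a, e.node_b
            if e.kind in (ElementKind.RESISTOR, ElementKind.VALVE):
                g = 1.0 / e.effective_resistance
                if a_id == node.id:
                    row[a_id] += g
                    row[b_id] -= g
                elif b_id == node.id:
                    row[b_id] += g
                    row[a_id] -= g
            elif e.kind is ElementKind.CAPACITOR:
                c_old = (e.previous_compliance if e.previous_compliance
                         is not None else e.compliance)
                gc = e.compliance / dt
                hist = (c_old / dt) * (e.previous_pressures[0]
                                       - e.previous_pressures[1])
                if a_id == node.id:
                    row[a_id] += gc
                    row[b_id] -= gc
                    rhs += hist
                elif b_id == node.id:
                    row[b_id] += gc
                    row[a_id] -= gc
                    rhs -= hist
            elif e.kind is ElementKind.FLOW_SOURCE:
                if a_id == node.id:
                    rhs -= e.source_value
                elif b_id == node.id:
                    rhs += e.source_value
        for si, e in enumerate(sources):
            # source flow unknown q: +q delivered into node_a, -q into node_b
            if e.node_a == node.id:
                row[n + si] -= 1.0
            elif e.node_b == node.id:
                row[n + si] += 1.0
        rows.append((row, rhs))

    # pressure constraints
    for si, e in enumerate(sources):
        row = np.zeros(dim)
        row[e.node_a] = 1.0
        row[e.node_b] = -1.0
        rows.append((row, e.source_value))

    for i, (row, rhs) in enumerate(rows):
        A[i] = row
        b[i] = rhs
    return np.linalg.solve(A, b)[:n]


def bisect_ph(sid: float, t_co2: float, c_a: float, c_po4: float, c_hb: float,
              alpha: float = 0.03, iters: int = 200) -> float:
    """Plain bisection for the acid-base pH root on [6, 8].

    The residual is rewritten from the governing equations directly
    (charge balance -> bicarbonate, Henderson-Hasselbalch -> P_CO2,
    rectangular-hyperbola carbamino binding) without reusing package code.
    """
    def residual(ph: float) -> float:
        hco3 = (sid - c_a * (0.123 * ph - 0.631)
                - c_po4 * (0.309 * ph - 0.469))
        if hco3 <= 0.0:
            return t_co2
        pco2 = hco3 / (alpha * 10.0 ** (ph - 6.1))
        carbamino = 4.0 * (pco2 / (pco2 + 300.0)) * c_hb
        return t_co2 - alpha * pco2 - hco3 - carbamino

    lo, hi = 6.0, 8.0
    f_lo = residual(lo)
    if f_lo * residual(hi) > 0:
        raise ValueError("no sign change on [6, 8]")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f_lo * residual(mid) <= 0:
            hi = mid
        else:
            lo = mid
            f_lo = residual(lo)
    return 0.5 * (lo + hi)


def random_circuit(rng: np.random.Generator, n_nodes: int,
                   dt: float = 0.05) -> CircuitGraph:
    """Random connected circuit: tree resistors + extra edges + capacitors.

    One pressure source between ground and a random node guarantees
    excitation; capacitors carry random pressure history.
    """
    g = CircuitGraph()
    g.add_node("gnd", is_ground=True)
    for i in range(1, n_nodes):
        g.add_node(f"n{i}")
    # spanning tree over all nodes
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        g.add_resistor(i, j, float(rng.uniform(0.5, 5.0)))
    # extra chords
    for _ in range(int(rng.integers(0, n_nodes))):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        g.add_resistor(int(a), int(b), float(rng.uniform(0.5, 5.0)))
    # grounded capacitors with history
    for i in range(1, n_nodes):
        if rng.random() < 0.6:
            cap = g.add_capacitor(i, 0, float(rng.uniform(0.1, 3.0)))
            p_prev = float(rng.uniform(-5.0, 5.0))
            cap.previous_pressures = (p_prev, 0.0)
    target = int(rng.integers(1, n_nodes))
    g.add_pressure_source(target, 0, float(rng.uniform(1.0, 20.0)))
    if rng.random() < 0.5:
        a, b = rng.choice(n_nodes, size=2, replace=False)
        g.add_flow_source(int(a), int(b), float(rng.uniform(-2.0, 2.0)))
    return g
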