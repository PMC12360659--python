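"""Lumped-parameter (0D) hydraulic circuit solved by modified nodal analysis.

The circulation is represented as an electrical-circuit analog: pressure is
voltage (mmHg), flow is current (mL/s), vascular resistance is electrical
resistance (mmHg·s/mL) and vessel compliance is capacitance (mL/mmHg).
Each timestep the network is assembled into the block system

    [[G, B], [C, D]] · [V_n; I_m] = [I_s + Z; V_s]

where ``G`` holds resistor conductances and backward-Euler capacitor
conductances C/dt, ``B``/``C``/``D`` couple pressure sources, ``Z`` carries
the capacitor pressure history, and the unknowns are the non-ground node
pressures ``V_n`` and the pressure-source flows ``I_m``.  The dense system
(≲ 15 unknowns for the reduced closed loop) is solved by LU factorization.

Compliances may be time-varying (ventricular elastance).  The stamp then
uses the *new* compliance in ``G`` and the *old* compliance in the history
term, so that stored volume q = C(t)·ΔP is advanced exactly and total blood
volume is conserved to machine precision in a closed loop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "CircuitError",
    "SingularCircuitError",
    "ElementKind",
    "CircuitNode",
    "Element",
    "CircuitGraph",
    "MnaSystem",
    "MnaSolution",
    "assemble_mna",
    "stamp_capacitor",
    "solve_step",
    "update_volumes",
]

log = logging.getLogger(__name__)


class CircuitError(ValueError):
    """Configuration error in the circuit description."""


class SingularCircuitError(CircuitError):
    """The assembled system is singular (e.g. a floating node)."""


class ElementKind(Enum):
    RESISTOR = "resistor"
    CAPACITOR = "capacitor"
    PRESSURE_SOURCE = "pressure_source"
    FLOW_SOURCE = "flow_source"
    VALVE = "valve"


@dataclass
class CircuitNode:
    """A pressure node.  Exactly one node per circuit is ground (0 mmHg)."""

    id: int
    label: str
    pressure: float = 0.0  # mmHg, absolute vs ground
    is_ground: bool = False


@dataclass(eq=False)
class Element:
    """A two-terminal circuit element.

    Sign convention: positive flow runs from ``node_a`` to ``node_b``.
    Valves are two-state resistors whose state (open/closed) is chosen from
    the sign of the pressure gradient at the previous solved step.
    """

    kind: ElementKind
    node_a: int
    node_b: int
    label: str = ""
    resistance: float = 0.0          # mmHg·s/mL (resistor; valve: forward)
    reverse_resistance: float = 0.0  # mmHg·s/mL (valve: closed state)
    compliance: float = 0.0          # mL/mmHg (capacitor; may vary in time)
    previous_compliance: float | None = None  # capacitor C at previous step
    source_value: float = 0.0        # mmHg (pressure src) or mL/s (flow src)
    stored_volume: float = 0.0       # mL (capacitor, incl. unstressed)
    unstressed_volume: float = 0.0   # mL (capacitor volume at zero pressure)
    previous_pressures: tuple[float, float] = (0.0, 0.0)  # mmHg at (a, b)
    valve_open: bool = True
    last_flow: float = 0.0           # mL/s, a→b, from the last solved step

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise CircuitError(f"element {self.label!r}: endpoints must be distinct")
        if self.kind in (ElementKind.RESISTOR, ElementKind.VALVE):
            if not self.resistance > 0:
                raise CircuitError(
                    f"element {self.label!r}: resistance must be > 0, got {self.resistance}"
                )
        if self.kind is ElementKind.VALVE and not self.reverse_resistance > 0:
            raise CircuitError(
                f"valve {self.label!r}: reverse_resistance must be > 0"
            )
        if self.kind is ElementKind.CAPACITOR:
            if self.compliance < 0:
                raise CircuitError(
                    f"capacitor {self.label!r}: compliance must be >= 0"
                )
            if self.previous_compliance is None:
                self.previous_compliance = self.compliance

    @property
    def effective_resistance(self) -> float:
        if self.kind is ElementKind.VALVE:
            return self.resistance if self.valve_open else self.reverse_resistance
        return self.resistance


class CircuitGraph:
    """Container for nodes, elements and per-compartment blood volumes."""

    def __init__(self) -> None:
        self.nodes: list[CircuitNode] = []
        self.elements: list[Element] = []
        self._labels: dict[str, int] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, label: str, *, pressure: float = 0.0, is_ground: bool = False) -> int:
        if label in self._labels:
            raise CircuitError(f"duplicate node label {label!r}")
        if is_ground and any(n.is_ground for n in self.nodes):
            raise CircuitError("circuit already has a ground node")
        node = CircuitNode(id=len(self.nodes), label=label,
                           pressure=0.0 if is_ground else pressure,
                           is_ground=is_ground)
        self.nodes.append(node)
        self._labels[label] = node.id
        return node.id

    def node_id(self, label: str) -> int:
        return self._labels[label]

    def _add(self, element: Element) -> Element:
        self.elements.append(element)
        return element

    def add_resistor(self, a: int, b: int, resistance: float, label: str = "") -> Element:
        return self._add(Element(ElementKind.RESISTOR, a, b, label=label,
                                 resistance=resistance))

    def add_valve(self, a: int, b: int, forward: float, reverse: float,
                  label: str = "") -> Element:
        return self._add(Element(ElementKind.VALVE, a, b, label=label,
                                 resistance=forward, reverse_resistance=reverse))

    def add_capacitor(self, a: int, b: int, compliance: float, *, label: str = "",
                      unstressed_volume: float = 0.0) -> Element:
        pa = self.nodes[a].pressure
        pb = self.nodes[b].pressure
        elem = Element(ElementKind.CAPACITOR, a, b, label=label,
                       compliance=compliance,
                       unstressed_volume=unstressed_volume,
                       previous_pressures=(pa, pb))
        elem.stored_volume = unstressed_volume + compliance * (pa - pb)
        return self._add(elem)

    def add_pressure_source(self, a: int, b: int, value: float, label: str = "") -> Element:
        return self._add(Element(ElementKind.PRESSURE_SOURCE, a, b, label=label,
                                 source_value=value))

    def add_flow_source(self, a: int, b: int, value: float, label: str = "") -> Element:
        """Flow source driving ``value`` mL/s from node ``a`` into node ``b``."""
        return self._add(Element(ElementKind.FLOW_SOURCE, a, b, label=label,
                                 source_value=value))

    # -- queries ----------------------------------------------------------
    @property
    def ground(self) -> CircuitNode:
        grounds = [n for n in self.nodes if n.is_ground]
        if len(grounds) != 1:
            raise CircuitError(f"circuit must have exactly one ground node, has {len(grounds)}")
        return grounds[0]

    def capacitors(self) -> Iterable[Element]:
        return (e for e in self.elements if e.kind is ElementKind.CAPACITOR)

    def total_stored_volume(self) -> float:
        """Total blood volume (mL) stored on compliant compartments."""
        return sum(e.stored_volume for e in self.capacitors())

    def pressures(self) -> dict[str, float]:
        return {n.label: n.pressure for n in self.nodes}


@dataclass
class MnaSystem:
    """Assembled modified-nodal-analysis system for one backward-Euler step."""

    matrix: np.ndarray               # dense square block [[G,B],[C,D]]
    rhs: np.ndarray                  # [I_s + Z; V_s]
    node_index: dict[int, int]       # graph node id -> matrix row (non-ground)
    source_index: dict[int, int]     # element index -> source row
    unknown_labels: list[str]
    dt: float

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)


@dataclass
class MnaSolution:
    """Node pressures and pressure-source flows from one solved step."""

    pressures: np.ndarray            # per graph node id (ground included, 0)
    source_flows: dict[int, float]   # element index -> flow delivered into the
                                     # source's first (positive) node, mL/s
    system: MnaSystem


def stamp_capacitor(system: MnaSystem, cap: Element, dt: float) -> MnaSystem:
    """Stamp one capacitor into ``system`` via the backward-Euler scheme.

    G gains C_new/dt on the endpoint diagonals (subtracted off-diagonal);
    the RHS gains ±(C_old/dt)·(previous endpoint pressure difference).  With
    constant compliance this is the classic G_C = C/Δt update; the C_old /
    C_new split keeps stored volume q = C(t)·ΔP exact under time-varying
    elastance.
    """
    if dt <= 0:
        raise CircuitError(f"dt must be > 0, got {dt}")
    if cap.kind is not ElementKind.CAPACITOR:
        raise CircuitError("stamp_capacitor expects a capacitor element")
    if cap.compliance == 0 and (cap.previous_compliance or 0.0) == 0:
        return system

    gc_new = cap.compliance / dt
    c_old = cap.previous_compliance if cap.previous_compliance is not None else cap.compliance
    pa, pb = cap.previous_pressures
    hist = (c_old / dt) * (pa - pb)

    idx = system.node_index
    ia = idx.get(cap.node_a)
    ib = idx.get(cap.node_b)
    A, z = system.matrix, system.rhs
    if ia is not None:
        A[ia, ia] += gc_new
        z[ia] += hist
    if ib is not None:
        A[ib, ib] += gc_new
        z[ib] -= hist
    if ia is not None and ib is not None:
        A[ia, ib] -= gc_new
        A[ib, ia] -= gc_new
    return system


def assemble_mna(graph: CircuitGraph, dt: float) -> MnaSystem:
    """Assemble the MNA matrix and RHS for one timestep of length ``dt``."""
    if dt <= 0:
        raise CircuitError(f"dt must be > 0, got {dt}")
    ground = graph.ground  # raises unless exactly one

    node_index: dict[int, int] = {}
    labels: list[str] = []
    for n in graph.nodes:
        if not n.is_ground:
            node_index[n.id] = len(node_index)
            labels.append(f"P[{n.label}]")
    nn = len(node_index)

    sources = [i for i, e in enumerate(graph.elements)
               if e.kind is ElementKind.PRESSURE_SOURCE]
    source_index = {ei: nn + k for k, ei in enumerate(sources)}
    labels += [f"Q[{graph.elements[ei].label or ei}]" for ei in sources]

    dim = nn + len(sources)
    A = np.zeros((dim, dim))
    z = np.zeros(dim)
    system = MnaSystem(matrix=A, rhs=z, node_index=node_index,
                       source_index=source_index, unknown_labels=labels, dt=dt)

    for ei, e in enumerate(graph.elements):
        ia = node_index.get(e.node_a)
        ib = node_index.get(e.node_b)
        if e.kind in (ElementKind.RESISTOR, ElementKind.VALVE):
            r = e.effective_resistance
            if not r > 0:
                raise CircuitError(f"element {e.label!r}: non-positive resistance")
            g = 1.0 / r
            if ia is not None:
                A[ia, ia] += g
            if ib is not None:
                A[ib, ib] += g
            if ia is not None and ib is not None:
                A[ia, ib] -= g
                A[ib, ia] -= g
        elif e.kind is ElementKind.CAPACITOR:
            stamp_capacitor(system, e, dt)
        elif e.kind is ElementKind.PRESSURE_SOURCE:
            k = source_index[ei]
            # I_m is the flow a→b delivered through the source into node b.
            if ia is not None:
                A[ia, k] -= 1.0
                A[k, ia] += 1.0
            if ib is not None:
                A[ib, k] += 1.0
                A[k, ib] -= 1.0
            z[k] = e.source_value
        elif e.kind is ElementKind.FLOW_SOURCE:
            if ia is not None:
                z[ia] -= e.source_value
            if ib is not None:
                z[ib] += e.source_value

    return system


def solve_step(system: MnaSystem, graph: CircuitGraph | None = None) -> MnaSolution:
    """LU-solve the assembled system for node pressures and source flows.

    If ``graph`` is given the solution is expanded onto graph node ids and a
    KCL residual check is performed at every non-ground node.
    """
    A, z = system.matrix, system.rhs
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            x = np.linalg.solve(A, z)
    except (np.linalg.LinAlgError, RuntimeWarning) as exc:
        culprit = _locate_singular_row(system)
        raise SingularCircuitError(
            f"singular MNA matrix (floating node or redundant source) near unknown "
            f"{culprit!r}"
        ) from exc
    if not np.all(np.isfinite(x)):
        culprit = _locate_singular_row(system)
        raise SingularCircuitError(
            f"non-finite MNA solution near unknown {culprit!r}")

    n_total = max(system.node_index.keys(), default=-1) + 1
    if graph is not None:
        n_total = len(graph.nodes)
    pressures = np.zeros(n_total)
    for nid, row in system.node_index.items():
        pressures[nid] = x[row]

    source_flows = {ei: x[row] for ei, row in system.source_index.items()}

    # KCL residual: A·x − z restricted to node rows must vanish.
    resid = A @ x - z
    node_rows = list(system.node_index.values())
    if node_rows:
        scale = max(1.0, float(np.max(np.abs(A @ x))))
        worst = float(np.max(np.abs(resid[node_rows])))
        if worst > 1e-8 * scale:
            raise SingularCircuitError(
                f"KCL residual {worst:.3e} exceeds tolerance after solve")
    return MnaSolution(pressures=pressures, source_flows=source_flows, system=system)


def _locate_singular_row(system: MnaSystem) -> str:
    A = system.matrix
    for i in range(A.shape[0]):
        if not np.any(A[i] != 0.0):
            return system.unknown_labels[i]
    # fall back to the smallest pivot direction
    try:
        _, s, vt = np.linalg.svd(A)
        j = int(np.argmax(np.abs(vt[-1])))
        return system.unknown_labels[j]
    except Exception:  # pragma: no cover
        return "unknown"


def element_flow(e: Element, pressures: np.ndarray, dt: float) -> float:
    """Flow a→b through element ``e`` given the freshly solved pressures."""
    pa = pressures[e.node_a]
    pb = pressures[e.node_b]
    if e.kind in (ElementKind.RESISTOR, ElementKind.VALVE):
        return (pa - pb) / e.effective_resistance
    if e.kind is ElementKind.CAPACITOR:
        c_old = e.previous_compliance if e.previous_compliance is not None else e.compliance
        q_old = c_old * (e.previous_pressures[0] - e.previous_pressures[1])
        q_new = e.compliance * (pa - pb)
        return (q_new - q_old) / dt
    if e.kind is ElementKind.FLOW_SOURCE:
        return e.source_value
    raise CircuitError("pressure-source flow comes from the MNA solution")


def update_volumes(graph: CircuitGraph, solution: MnaSolution, dt: float) -> CircuitGraph:
    """Push solved pressures onto the graph and advance capacitor volumes.

    Each capacitor's stored volume is advanced by its net inflow·dt, which
    with the exact time-varying stamp equals the change of C·ΔP; valve states
    are refreshed from the new pressure gradient for the next step.
    """
    p = solution.pressures
    for n in graph.nodes:
        if not n.is_ground:
            n.pressure = float(p[n.id])
    for ei, e in enumerate(graph.elements):
        pa = float(p[e.node_a])
        pb = float(p[e.node_b])
        if e.kind is ElementKind.CAPACITOR:
            inflow = element_flow(e, p, dt)
            e.stored_volume += inflow * dt
            if e.stored_volume < 0.0:
                log.warning("capacitor %r stored volume clamped to 0 (was %.3g mL)",
                            e.label, e.stored_volume)
                e.stored_volume = 0.0
            e.previous_pressures = (pa, pb)
            e.previous_compliance = e.compliance
            e.last_flow = inflow
        elif e.kind is ElementKind.VALVE:
            e.last_flow = element_flow(e, p, dt)
            e.valve_open = pa > pb
        elif e.kind is ElementKind.RESISTOR:
            e.last_flow = element_flow(e, p, dt)
        elif e.kind is ElementKind.FLOW_SOURCE:
            e.last_flow = e.source_value
        elif e.kind is ElementKind.PRESSURE_SOURCE:
            e.last_flow = solution.source_flows.get(ei, 0.0)
    return graph
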