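"""Lumped hydraulic model of the S-stage bifurcated trap-array device.

The device splits an inlet channel in two at each of S bifurcation stages;
after the last stage each of the 2^S channels feeds four terminal traps, so
the trap count is N = 4 * 2^S.  Flow is driven either by the hydrostatic
pressure of a liquid column at the inlet (pipette mode, fixed pressure) or by
a syringe pump (fixed flow).  Each channel segment is a rectangular duct with
Hagen-Poiseuille resistance; a captured cell multiplies its trap's resistance,
which diverts flow toward unoccupied traps under fixed pressure but forces the
inlet pressure up under fixed flow.  The network is a tree solved exactly by
nodal analysis (sparse linear solve); no finite-element or transient solving.

Units are SI throughout; microlitre-per-minute conversions only at the I/O
boundary (1 m^3/s = 6e10 uL/min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

__all__ = [
    "STANDARD_GRAVITY",
    "LEGACY_GRAVITY",
    "MEASURED_DEVICE_RESISTANCE",
    "TrapArrayDesign",
    "HydraulicNetwork",
    "FlowSolution",
    "hydrostatic_pressure",
    "total_flow",
    "ul_per_min",
    "branch_flow",
    "segment_resistance",
    "wall_shear",
    "loading_time",
    "build_network",
    "solve_flow",
]

STANDARD_GRAVITY = 9.80665  # m/s^2
#: Compatibility constant: the device datasheet computes rho*g*h = 998 Pa for
#: rho = 998 kg/m^3 and h = 0.10 m, which corresponds to g = 10.0 m/s^2.
LEGACY_GRAVITY = 10.0
#: Experimentally measured aggregate resistance of the empty 1024-trap device.
MEASURED_DEVICE_RESISTANCE = 1.48e13  # Pa s m^-3

_UM = 1e-6
_UL_MIN_PER_M3_S = 6e10


@dataclass(frozen=True)
class TrapArrayDesign:
    """Geometry and topology of the bifurcated trap-array device.

    The main-channel design height is 40 um but the fabricated height measures
    ~35 um; resistance calculations use ``channel_height_measured_um`` while
    both are exposed.  Filter cross-sections are smaller than the cell
    diameter so that cells are retained while fluid passes.
    """

    stages: int = 8
    channel_height_um: float = 40.0
    channel_height_measured_um: float = 35.0
    channel_width_um: float = 30.0
    filter_height_um: float = 4.0
    filter_width_um: float = 2.0
    filters_per_trap: int = 2
    trap_pitch_um: float = 60.0  # 30 um trap + 30 um gap
    array_span_mm: float = 61.44
    trap_channel_length_um: float = 100.0
    filter_length_um: float = 20.0
    viscosity_pa_s: float = 1.0e-3
    density_kg_m3: float = 998.0
    cell_diameter_um: float = 14.0

    def __post_init__(self) -> None:
        if self.stages < 0:
            raise ValueError("stages must be non-negative")
        if self.filters_per_trap not in (2, 3):
            raise ValueError("filters_per_trap must be 2 or 3")
        if not (
            self.filter_height_um < self.channel_height_um
            and self.filter_width_um < self.channel_width_um
        ):
            raise ValueError("filter cross-section must be smaller than the channel")
        if self.filter_height_um >= self.cell_diameter_um:
            raise ValueError("filter height must be below the cell diameter")

    @property
    def n_traps(self) -> int:
        """N = 4 * 2^S terminal traps."""
        return 4 * 2 ** self.stages

    @property
    def n_last_channels(self) -> int:
        return 2 ** self.stages

    def stage_length_m(self, level: int) -> float:
        """Per-stage channel length (m): the array span halves per bifurcation.

        The chip does not document individual segment lengths; lengths only
        set the *relative* resistance profile because the network is
        calibrated to the measured aggregate resistance afterwards.
        """
        span_m = self.array_span_mm * 1e-3
        return span_m / 2 ** (level + 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrapArrayDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def hydrostatic_pressure(
    density: float, gravity: float = STANDARD_GRAVITY, column_height: float = 0.10
) -> float:
    """Inlet pressure P = rho * g * h of the liquid column (Pa)."""
    if density < 0 or gravity < 0 or column_height < 0:
        raise ValueError("density, gravity and column height must be non-negative")
    return density * gravity * column_height


def total_flow(pressure: float, resistance: float) -> float:
    """Lumped Hagen-Poiseuille relation Q = P / R (m^3/s)."""
    if resistance <= 0:
        raise ValueError("resistance must be positive")
    return pressure / resistance


def ul_per_min(flow_m3_s: float) -> float:
    """Convert m^3/s to uL/min."""
    return flow_m3_s * _UL_MIN_PER_M3_S


def branch_flow(total_ul_min: float, design: TrapArrayDesign) -> float:
    """Per-last-stage-channel flow: total divided by the 2^S channels."""
    if total_ul_min < 0:
        raise ValueError("flow must be non-negative")
    return total_ul_min / design.n_last_channels


def segment_resistance(length: float, width: float, height: float, viscosity: float) -> float:
    """Rectangular-duct resistance 12*mu*L / (w*h^3*(1 - 0.63 h/w)), h <= w.

    First-order series approximation for laminar flow in a rectangular
    channel; the orientation convention swaps the dimensions so that the cube
    applies to the smaller one.
    """
    if length <= 0 or width <= 0 or height <= 0 or viscosity <= 0:
        raise ValueError("dimensions and viscosity must be positive")
    if height > width:
        width, height = height, width
    return 12 * viscosity * length / (width * height**3 * (1 - 0.63 * height / width))


def wall_shear(flow: float, width: float, height: float, viscosity: float) -> float:
    """Wall shear estimate tau = 6 * mu * Q / (w * h^2) for a rectangular duct."""
    if width <= 0 or height <= 0 or viscosity <= 0:
        raise ValueError("dimensions and viscosity must be positive")
    if flow < 0:
        raise ValueError("flow must be non-negative")
    return 6 * viscosity * flow / (width * height**2)


def loading_time(sample_volume_ul: float, total_flow_ul_min: float) -> float:
    """Minutes to drive a sample volume through the device at the given flow."""
    if sample_volume_ul < 0:
        raise ValueError("volume must be non-negative")
    if sample_volume_ul == 0:
        return 0.0
    if total_flow_ul_min <= 0:
        raise ValueError("flow must be positive")
    return sample_volume_ul / total_flow_ul_min


@dataclass
class HydraulicNetwork:
    """Tree-topology resistance network of the device.

    Nodes: ``"inlet"``, ``"outlet"`` and integer junction ids; edges carry a
    ``resistance`` attribute (Pa s m^-3).  ``trap_edges[i]`` is the terminal
    edge of trap ``i`` whose resistance is scaled by
    ``occupancy_multiplier**cells`` when occupied.
    """

    graph: nx.DiGraph
    trap_edges: list[tuple[object, object]]
    design: TrapArrayDesign
    occupancy_multiplier: float = 10.0
    inlet: object = "inlet"
    outlet: object = "outlet"
    calibration_scale: float = 1.0

    @property
    def n_traps(self) -> int:
        return len(self.trap_edges)


@dataclass
class FlowSolution:
    """Solved per-edge flows and node pressures for one occupancy state."""

    node_pressures: dict
    edge_flows: dict
    trap_flows: np.ndarray  # m^3/s, per trap
    trap_shear: np.ndarray  # Pa, per filter wall
    total_flow: float  # m^3/s through the inlet edge
    inlet_pressure: float  # Pa

    @property
    def total_flow_ul_min(self) -> float:
        return ul_per_min(self.total_flow)

    def conservation_residual(self) -> float:
        """Max |sum inflow - sum outflow| over internal nodes (m^3/s)."""
        balance: dict = {}
        for (u, v), q in self.edge_flows.items():
            balance[u] = balance.get(u, 0.0) - q
            balance[v] = balance.get(v, 0.0) + q
        internal = [n for n in balance if n not in ("inlet", "outlet")]
        return max((abs(balance[n]) for n in internal), default=0.0)


def build_network(
    design: TrapArrayDesign,
    target_resistance: float | None = MEASURED_DEVICE_RESISTANCE,
    occupancy_multiplier: float = 10.0,
) -> HydraulicNetwork:
    """Construct the bifurcation tree and calibrate its aggregate resistance.

    Channel-segment resistances come from the rectangular-duct formula with
    the design's measured channel height; the per-trap terminal edge lumps the
    trap sub-channel in series with the parallel filter constrictions.  If
    ``target_resistance`` is given, every edge is scaled by one global factor
    so that the empty-device aggregate equals it (calibration to the measured
    value; pass ``None`` to keep the raw geometric estimate).
    """
    mu = design.viscosity_pa_s
    w_c = design.channel_width_um * _UM
    h_c = design.channel_height_measured_um * _UM

    g = nx.DiGraph()
    root = 0
    next_id = 1
    g.add_edge(
        "inlet",
        root,
        resistance=segment_resistance(design.stage_length_m(0), w_c, h_c, mu),
    )
    frontier = [root]
    for level in range(1, design.stages + 1):
        length = design.stage_length_m(level)
        r_seg = segment_resistance(length, w_c, h_c, mu)
        new_frontier = []
        for node in frontier:
            for _ in range(2):
                child = next_id
                next_id += 1
                g.add_edge(node, child, resistance=r_seg)
                new_frontier.append(child)
        frontier = new_frontier

    # terminal trap edges: sub-channel in series with parallel filters
    r_sub = segment_resistance(
        design.trap_channel_length_um * _UM, w_c, h_c, mu
    )
    r_filter = segment_resistance(
        design.filter_length_um * _UM,
        design.filter_width_um * _UM,
        design.filter_height_um * _UM,
        mu,
    )
    r_trap = r_sub + r_filter / design.filters_per_trap
    # each trap gets its own terminal node (a DiGraph would collapse four
    # parallel leaf->outlet edges into one); the stub to the outlet carries a
    # negligible series resistance
    trap_edges: list[tuple[object, object]] = []
    trap_idx = 0
    for leaf in frontier:
        for _ in range(4):
            tnode = f"trap{trap_idx}"
            g.add_edge(leaf, tnode, resistance=r_trap)
            g.add_edge(tnode, "outlet", resistance=r_trap * 1e-9)  # negligible stub
            trap_edges.append((leaf, tnode))
            trap_idx += 1

    net = HydraulicNetwork(
        graph=g,
        trap_edges=trap_edges,
        design=design,
        occupancy_multiplier=occupancy_multiplier,
    )
    if target_resistance is not None:
        sol = solve_flow(net, pressure=1.0)
        r_eq = 1.0 / sol.total_flow
        scale = target_resistance / r_eq
        for _, _, attrs in g.edges(data=True):
            attrs["resistance"] *= scale
        net.calibration_scale = scale
    return net


def _effective_resistances(
    network: HydraulicNetwork, occupancy: np.ndarray | None
) -> dict:
    res = {
        (u, v): attrs["resistance"]
        for u, v, attrs in network.graph.edges(data=True)
    }
    if occupancy is not None:
        occupancy = np.asarray(occupancy)
        if occupancy.ndim == 2:  # (n_traps, populations) -> total cells
            occupancy = occupancy.sum(axis=1)
        if len(occupancy) != network.n_traps:
            raise ValueError("occupancy length must equal the trap count")
        for i, edge in enumerate(network.trap_edges):
            k = int(occupancy[i])
            if k > 0:
                res[edge] = res[edge] * network.occupancy_multiplier**k
    return res


def solve_flow(
    network: HydraulicNetwork,
    pressure: float | None = None,
    flow: float | None = None,
    occupancy: np.ndarray | None = None,
) -> FlowSolution:
    """Solve the linear network for one boundary condition and occupancy state.

    Exactly one of ``pressure`` (fixed inlet pressure, pipette mode, Pa) or
    ``flow`` (fixed inlet flow, pump mode, m^3/s) must be given.  The outlet
    is grounded at 0 Pa.  Occupied traps have their terminal-edge resistance
    scaled by ``occupancy_multiplier**cells``.
    """
    if (pressure is None) == (flow is None):
        raise ValueError("specify exactly one of pressure= or flow=")
    g = network.graph
    res = _effective_resistances(network, occupancy)
    nodes = [n for n in g.nodes if n != network.outlet]
    index = {n: i for i, n in enumerate(nodes)}
    fixed: dict = {}
    if pressure is not None:
        fixed[network.inlet] = pressure

    rows, cols, vals = [], [], []
    rhs = np.zeros(len(nodes))

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for (u, v), r in res.items():
        cond = 1.0 / r
        for a, b in ((u, v), (v, u)):
            if a == network.outlet or a in fixed:
                continue
            ia = index[a]
            add(ia, ia, cond)
            if b == network.outlet:
                continue
            if b in fixed:
                rhs[ia] += cond * fixed[b]
            else:
                add(ia, index[b], -cond)

    for n, p in fixed.items():
        i = index[n]
        add(i, i, 1.0)
        rhs[i] = p
    if flow is not None:
        rhs[index[network.inlet]] += flow

    n = len(nodes)
    matrix = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    try:
        solution = spsolve(matrix, rhs)
    except Exception as exc:  # pragma: no cover - singular network
        raise ValueError("singular hydraulic network") from exc
    if not np.all(np.isfinite(solution)):
        raise ValueError("singular hydraulic network")

    pressures = {n: float(solution[index[n]]) for n in nodes}
    pressures[network.outlet] = 0.0
    edge_flows = {
        (u, v): (pressures[u] - pressures[v]) / r for (u, v), r in res.items()
    }
    trap_flows = np.array([edge_flows[e] for e in network.trap_edges])

    d = network.design
    per_filter = trap_flows / d.filters_per_trap
    shear = np.array(
        [
            wall_shear(
                max(q, 0.0),
                d.filter_width_um * _UM,
                d.filter_height_um * _UM,
                d.viscosity_pa_s,
            )
            for q in per_filter
        ]
    )
    inlet_edge = next(iter(g.out_edges(network.inlet)))
    return FlowSolution(
        node_pressures=pressures,
        edge_flows=edge_flows,
        trap_flows=trap_flows,
        trap_shear=shear,
        total_flow=float(edge_flows[inlet_edge]),
        inlet_pressure=float(pressures[network.inlet]),
    )


def equivalent_resistance(
    network: HydraulicNetwork, occupancy: np.ndarray | None = None
) -> float:
    """Aggregate inlet-to-outlet resistance for a given occupancy state."""
    sol = solve_flow(network, pressure=1.0, occupancy=occupancy)
    return 1.0 / sol.total_flow


def flow_solution_frame(sol: FlowSolution) -> "pd.DataFrame":
    """Per-edge CSV-ready table (edge, resistance-free flow, end pressures)."""
    import pandas as pd

    rows = [
        {
            "edge_from": str(u),
            "edge_to": str(v),
            "flow_m3_s": q,
            "pressure_from_pa": sol.node_pressures[u],
            "pressure_to_pa": sol.node_pressures[v],
        }
        for (u, v), q in sol.edge_flows.items()
    ]
    return pd.DataFrame(rows)
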