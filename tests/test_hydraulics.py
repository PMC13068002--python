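"""Lumped resistance-network model of the bifurcated device."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celltrap.hydraulics import (
    LEGACY_GRAVITY,
    MEASURED_DEVICE_RESISTANCE,
    STANDARD_GRAVITY,
    TrapArrayDesign,
    branch_flow,
    build_network,
    equivalent_resistance,
    hydrostatic_pressure,
    loading_time,
    segment_resistance,
    solve_flow,
    total_flow,
    ul_per_min,
    wall_shear,
)


class TestClosedForms:
    def test_hydrostatic_pressure_legacy_gravity(self):
        # the 998 Pa device figure corresponds to g = 10 m/s^2
        assert hydrostatic_pressure(998.0, LEGACY_GRAVITY, 0.10) == pytest.approx(998.0)

    def test_hydrostatic_pressure_standard_gravity(self):
        assert hydrostatic_pressure(998.0, 9.81, 0.10) == pytest.approx(979.04, abs=0.01)

    def test_hydrostatic_pressure_zero_column(self):
        assert hydrostatic_pressure(998.0, STANDARD_GRAVITY, 0.0) == 0.0
        with pytest.raises(ValueError):
            hydrostatic_pressure(-1.0, STANDARD_GRAVITY, 0.1)

    def test_total_flow_measured_chain(self):
        q = total_flow(998.0, MEASURED_DEVICE_RESISTANCE)
        assert q == pytest.approx(6.74e-11, rel=1e-3)
        assert ul_per_min(q) == pytest.approx(4.04, abs=0.01)

    def test_total_flow_linearity(self):
        assert total_flow(0.0, 1e13) == 0.0
        assert total_flow(200.0, 1e13) == pytest.approx(2 * total_flow(100.0, 1e13))
        with pytest.raises(ValueError):
            total_flow(100.0, 0.0)

    def test_branch_flow_divides_by_last_stage_channels(self):
        design = TrapArrayDesign(stages=8)
        assert branch_flow(4.04, design) == pytest.approx(0.0158, abs=5e-5)
        assert branch_flow(5.0, design) == pytest.approx(0.0195, abs=5e-5)
        assert branch_flow(0.0, design) == 0.0

    def test_segment_resistance_value(self):
        # independent evaluation of 12 mu L / (w h^3 (1 - 0.63 h/w))
        r = segment_resistance(100e-6, 35e-6, 30e-6, 1e-3)
        assert r == pytest.approx(2.7605e12, rel=1e-4)

    def test_segment_resistance_orientation_swap(self):
        a = segment_resistance(100e-6, 35e-6, 30e-6, 1e-3)
        b = segment_resistance(100e-6, 30e-6, 35e-6, 1e-3)
        assert a == b

    def test_segment_resistance_wide_channel_limit(self):
        w, h = 3e-3, 10e-6
        r = segment_resistance(1e-3, w, h, 1e-3)
        plates = 12 * 1e-3 * 1e-3 / (w * h**3)
        assert r == pytest.approx(plates, rel=0.01)

    @given(scale=st.floats(1.1, 10.0))
    @settings(derandomize=True, max_examples=25)
    def test_segment_resistance_linear_in_length(self, scale):
        base = segment_resistance(1e-4, 30e-6, 30e-6, 1e-3)
        assert segment_resistance(scale * 1e-4, 30e-6, 30e-6, 1e-3) == pytest.approx(
            scale * base, rel=1e-12
        )

    def test_wall_shear(self):
        assert wall_shear(0.0, 30e-6, 4e-6, 1e-3) == 0.0
        tau1 = wall_shear(1e-12, 30e-6, 4e-6, 1e-3)
        assert wall_shear(2e-12, 30e-6, 4e-6, 1e-3) == pytest.approx(2 * tau1)

    def test_loading_time(self):
        assert loading_time(10.0, 4.04) == pytest.approx(2.48, abs=0.01)
        assert loading_time(20.0, 4.04) == pytest.approx(4.95, abs=0.01)
        assert loading_time(0.0, 4.04) == 0.0
        with pytest.raises(ValueError):
            loading_time(10.0, 0.0)


class TestDesign:
    def test_trap_count_design_equation(self):
        assert TrapArrayDesign(stages=8).n_traps == 1024
        assert TrapArrayDesign(stages=3).n_traps == 32

    def test_filter_smaller_than_channel_enforced(self):
        with pytest.raises(ValueError):
            TrapArrayDesign(filter_height_um=50.0)

    def test_yaml_round_trip(self, tmp_path):
        design = TrapArrayDesign(stages=5, filters_per_trap=3)
        path = tmp_path / "device.yaml"
        design.to_yaml(path)
        assert TrapArrayDesign.from_yaml(path) == design


class TestNetworkSolve:
    def test_calibrated_network_reproduces_lumped_flow(self):
        design = TrapArrayDesign(stages=8)
        net = build_network(design)
        sol = solve_flow(net, pressure=998.0)
        assert sol.total_flow == pytest.approx(998.0 / MEASURED_DEVICE_RESISTANCE, rel=1e-9)
        assert sol.total_flow_ul_min == pytest.approx(4.046, abs=5e-3)

    def test_flow_conservation(self):
        design = TrapArrayDesign(stages=4)
        net = build_network(design)
        occupancy = np.zeros(design.n_traps, int)
        occupancy[::3] = 2
        sol = solve_flow(net, pressure=998.0, occupancy=occupancy)
        assert sol.conservation_residual() < 1e-9 * abs(sol.total_flow)

    def test_empty_symmetric_split(self):
        design = TrapArrayDesign(stages=4)
        sol = solve_flow(build_network(design), pressure=500.0)
        flows = sol.trap_flows
        assert np.ptp(flows) / flows.mean() < 1e-10
        assert flows.sum() == pytest.approx(sol.total_flow, rel=1e-9)

    def _toy_oracle(self, occupancy_multiplier_on_trap0):
        """Independent dense nodal solve of the S=1 toy (8 traps)."""
        design = TrapArrayDesign(stages=1)
        net = build_network(design, target_resistance=None)
        res = {
            (u, v): d["resistance"] for u, v, d in net.graph.edges(data=True)
        }
        res[net.trap_edges[0]] *= occupancy_multiplier_on_trap0
        nodes = [n for n in net.graph.nodes if n not in ("inlet", "outlet")]
        idx = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        A = np.zeros((n, n))
        b = np.zeros(n)
        p_in = 100.0
        for (u, v), r in res.items():
            g = 1.0 / r
            for a, other in ((u, v), (v, u)):
                if a in ("inlet", "outlet"):
                    continue
                A[idx[a], idx[a]] += g
                if other == "outlet":
                    continue
                elif other == "inlet":
                    b[idx[a]] += g * p_in
                else:
                    A[idx[a], idx[other]] -= g
        p = np.linalg.solve(A, b)
        pressures = {n_: p[idx[n_]] for n_ in nodes}
        pressures["inlet"], pressures["outlet"] = p_in, 0.0
        return np.array(
            [(pressures[u] - pressures[v]) / res[(u, v)] for (u, v) in net.trap_edges]
        )

    def test_toy_occupied_trap_diversion_vs_oracle(self):
        design = TrapArrayDesign(stages=1)
        net = build_network(design, target_resistance=None)
        occ = np.zeros(8, int)
        occ[0] = 1
        net.occupancy_multiplier = 10.0
        sol = solve_flow(net, pressure=100.0, occupancy=occ)
        oracle = self._toy_oracle(10.0)
        assert sol.trap_flows == pytest.approx(oracle, rel=1e-9)
        empty = solve_flow(net, pressure=100.0)
        assert sol.trap_flows[0] < empty.trap_flows[0]
        assert sol.total_flow < empty.total_flow
        # siblings gain flow when a trap clogs
        assert np.all(sol.trap_flows[1:] > empty.trap_flows[1:])

    def test_toy_fixed_flow_raises_pressure(self):
        design = TrapArrayDesign(stages=1)
        net = build_network(design, target_resistance=None)
        occ = np.zeros(8, int)
        occ[0] = 1
        empty = solve_flow(net, pressure=100.0)
        pump = solve_flow(net, flow=empty.total_flow, occupancy=occ)
        assert pump.total_flow == pytest.approx(empty.total_flow, rel=1e-9)
        assert pump.inlet_pressure > 100.0

    def test_pump_shear_exceeds_pipette_shear_on_occupied_trap(self):
        design = TrapArrayDesign(stages=2)
        net = build_network(design, target_resistance=None)
        occ = np.zeros(design.n_traps, int)
        occ[3] = 1
        empty = solve_flow(net, pressure=998.0)
        pipette = solve_flow(net, pressure=998.0, occupancy=occ)
        pump = solve_flow(net, flow=empty.total_flow, occupancy=occ)
        assert pump.trap_shear[3] > pipette.trap_shear[3]

    def test_monotone_diversion_in_multiplier(self):
        design = TrapArrayDesign(stages=2)
        net = build_network(design, target_resistance=None)
        occ = np.zeros(design.n_traps, int)
        occ[5] = 1
        flows = []
        for mult in (1.0, 3.0, 10.0, 30.0, 100.0):
            net.occupancy_multiplier = mult
            flows.append(solve_flow(net, pressure=998.0, occupancy=occ).trap_flows[5])
        assert all(a >= b for a, b in zip(flows, flows[1:]))

    def test_fixed_flow_pressure_dominates_fixed_pressure(self):
        design = TrapArrayDesign(stages=2)
        net = build_network(design, target_resistance=None)
        empty = solve_flow(net, pressure=998.0)
        rng = np.random.default_rng(0)
        occ = rng.integers(0, 3, design.n_traps)
        pipette = solve_flow(net, pressure=998.0, occupancy=occ)
        pump = solve_flow(net, flow=empty.total_flow, occupancy=occ)
        assert pump.inlet_pressure >= pipette.inlet_pressure

    def test_equivalent_resistance_increases_with_occupancy(self):
        design = TrapArrayDesign(stages=3)
        net = build_network(design)
        r_empty = equivalent_resistance(net)
        occ = np.ones(design.n_traps, int)
        assert equivalent_resistance(net, occ) > r_empty

    def test_boundary_condition_validation(self):
        net = build_network(TrapArrayDesign(stages=1), target_resistance=None)
        with pytest.raises(ValueError):
            solve_flow(net)
        with pytest.raises(ValueError):
            solve_flow(net, pressure=1.0, flow=1.0)
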