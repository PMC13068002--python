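"""Ground-truthed synthetic data generator."""

import numpy as np
import pytest

from celltrap.hydraulics import TrapArrayDesign
from celltrap.loading import CellLot, SimConfig, simulate_loading
from celltrap.occupancy import LoadingRate, OccupancyTable
from celltrap.synth import (
    CellTruth,
    GroundTruth,
    ImageStack,
    ScenarioConfig,
    generate_calcium_traces,
    generate_ground_truth,
    render_timelapse,
)

from conftest import make_scenario


class TestGroundTruth:
    def test_no_death_when_probabilities_zero(self):
        scenario = make_scenario(
            death_prob={"1:1": 0.0, "1:2": 0.0, "2:1": 0.0, "multiplet": 0.0},
            spontaneous_death=(0.0, 0.0),
        )
        truth = generate_ground_truth(scenario)
        assert all(c.death_h is None for c in truth.cells)

    def test_singlet_death_fraction_matches_probability(self):
        # 213 singlet traps at p = 0.215, averaged over seeds
        fracs = []
        for seed in range(50):
            scenario = ScenarioConfig(
                design=TrapArrayDesign(stages=6),
                occupancy=[(1, 1)] * 213 + [(0, 0)] * 43,
                death_prob={"1:1": 0.215},
                spontaneous_death=(0.0, 0.0),
                seed=seed,
            )
            fracs.append(generate_ground_truth(scenario).target_death_fraction((1, 1)))
        se = np.sqrt(0.215 * 0.785 / (213 * 50))
        assert np.mean(fracs) == pytest.approx(0.215, abs=3 * se)

    def test_control_spontaneous_death_rates(self):
        scenario = ScenarioConfig(
            design=TrapArrayDesign(stages=6),
            occupancy=[(0, 1)] * 256,
            death_prob={},
            spontaneous_death=(0.01, 0.044),
            seed=3,
        )
        truth = generate_ground_truth(scenario)
        frac = truth.target_death_fraction()
        # viability well above the 93% baseline floor
        assert 1.0 - frac > 0.93

    def test_contact_dependence(self):
        """Cohort death probabilities never touch single-population traps."""
        scenario = make_scenario(
            occupancy=[(1, 0)] * 16 + [(0, 1)] * 16,
            death_prob={"1:1": 1.0, "multiplet": 1.0, "1:2": 1.0, "2:1": 1.0},
            spontaneous_death=(0.0, 0.0),
        )
        truth = generate_ground_truth(scenario)
        assert all(c.death_h is None for c in truth.cells)

    def test_event_times_on_frame_grid(self):
        scenario = make_scenario(division_rate=0.2, escape_rate=0.2, seed=5)
        truth = generate_ground_truth(scenario)
        grid = set(np.round(truth.frame_times_h, 9))
        for cell in truth.cells:
            for t in (cell.death_h, cell.division_h, cell.escape_h):
                assert t is None or round(t, 9) in grid

    def test_dead_cells_never_divide_afterwards(self):
        scenario = make_scenario(division_rate=0.5, seed=9)
        truth = generate_ground_truth(scenario)
        for cell in truth.cells:
            if cell.death_h is not None and cell.division_h is not None:
                assert cell.division_h < cell.death_h

    def test_determinism(self):
        a = generate_ground_truth(make_scenario(seed=21))
        b = generate_ground_truth(make_scenario(seed=21))
        assert a.to_json() == b.to_json()

    def test_json_round_trip(self, tmp_path):
        truth = generate_ground_truth(make_scenario(seed=2, division_rate=0.1))
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.trap_occupancy == truth.trap_occupancy
        assert back.to_json() == truth.to_json()

    def test_unknown_cohort_warns_and_is_zero(self):
        scenario = make_scenario(occupancy=[(2, 2)] * 32, death_prob={"1:1": 0.5})
        with pytest.warns(UserWarning):
            truth = generate_ground_truth(scenario)
        assert all(c.death_h is None for c in truth.cells)

    @pytest.mark.parametrize("source", ["rate", "table", "sim"])
    def test_occupancy_sources(self, source):
        design = TrapArrayDesign(stages=4)
        if source == "rate":
            occ = LoadingRate(0.5, 0.5)
        elif source == "table":
            occ = OccupancyTable.from_pairs([(1, 1)] * 30 + [(0, 0)] * 34)
        else:
            occ = simulate_loading(
                design, [CellLot(1, 30), CellLot(2, 30)], SimConfig(seed=0)
            )
        scenario = ScenarioConfig(design=design, occupancy=occ, seed=1)
        truth = generate_ground_truth(scenario)
        assert truth.n_traps == design.n_traps


class TestRender:
    def test_determinism(self):
        scenario = make_scenario(seed=13)
        a = render_timelapse(generate_ground_truth(scenario), scenario)
        b = render_timelapse(generate_ground_truth(scenario), scenario)
        assert np.array_equal(a.data, b.data)

    def test_empty_trap_is_background_only(self, mixed_fixture):
        stack = mixed_fixture["stack"]
        truth = mixed_fixture["truth"]
        scenario = mixed_fixture["scenario"]
        trap = truth.trap_occupancy.index((0, 0))
        x0 = int(stack.meta["trap_centers_x_px"][trap])
        roi = stack.data[0, stack.channels["green"], :, x0 - 10 : x0 + 10]
        noise = scenario.noise["green"]
        assert abs(roi.mean() - noise.background) < 3 * noise.sd

    def test_death_renders_red_blue_overlap_and_green_decay(self):
        truth = GroundTruth(
            n_traps=32,
            trap_occupancy=[(0, 1)] + [(0, 0)] * 31,
            cells=[CellTruth(trap=0, cell_id=0, population=2, x_um=0, y_um=0, death_h=8.0)],
            frame_times_h=list(np.arange(0, 15, 2.0)),
        )
        scenario = make_scenario(occupancy=[(0, 1)] + [(0, 0)] * 31)
        stack = render_timelapse(truth, scenario)
        x0 = int(stack.meta["trap_centers_x_px"][0])
        sl = np.s_[:, x0 - 8 : x0 + 8]
        bg_r = scenario.noise["red"].background
        bg_g = scenario.noise["green"].background
        red = stack.data[:, stack.channels["red"]][(slice(None),) + sl].astype(float) - bg_r
        blue = stack.data[:, stack.channels["blue"]][(slice(None),) + sl].astype(float)
        green = stack.data[:, stack.channels["green"]][(slice(None),) + sl].astype(float) - bg_g
        thr = 500.0
        for t_idx, t in enumerate(truth.frame_times_h):
            red_mask = red[t_idx] > thr
            blue_mask = blue[t_idx] > thr
            if t < 8.0:
                assert red_mask.sum() == 0
            else:
                # PI fills the tracer-positive cell: >= 50% overlap
                assert (red_mask & blue_mask).sum() >= 0.5 * blue_mask.sum() > 0
        # green decays with a 4 h half-life after the 8 h death
        assert green[-1].max() < 0.5 * green[0].max()
        # the stable blue tracer persists post-lysis
        assert blue[-1].max() > thr

    def test_no_bleach_no_death_green_flat(self):
        scenario = make_scenario(
            occupancy=[(0, 1)] * 32,
            death_prob={},
            spontaneous_death=(0.0, 0.0),
            photobleach_rate=0.0,
            seed=3,
        )
        truth = generate_ground_truth(scenario)
        stack = render_timelapse(truth, scenario)
        green = stack.channel("green").astype(float)
        per_frame_max = green.reshape(green.shape[0], -1).max(axis=1)
        assert np.ptp(per_frame_max) / per_frame_max.mean() < 0.1

    def test_photobleach_decreases_intensity(self):
        scenario = make_scenario(
            occupancy=[(0, 1)] * 32,
            death_prob={},
            spontaneous_death=(0.0, 0.0),
            photobleach_rate=0.15,
            seed=3,
        )
        stack = render_timelapse(generate_ground_truth(scenario), scenario)
        green = stack.channel("green").astype(float)
        assert green[-1].max() < 0.5 * green[0].max()

    def test_pixel_budget_enforced(self):
        scenario = make_scenario(max_pixels=1000)
        truth = generate_ground_truth(scenario)
        with pytest.raises(ValueError):
            render_timelapse(truth, scenario)

    def test_tiff_sidecar_round_trip(self, tmp_path, mixed_fixture):
        stack = mixed_fixture["stack"]
        path = tmp_path / "stack.tif"
        stack.write(path)
        back = ImageStack.read(path)
        assert np.array_equal(back.data, stack.data)
        assert back.channels == stack.channels
        assert back.um_per_pixel == stack.um_per_pixel
        assert back.meta["n_traps"] == stack.meta["n_traps"]


class TestCalciumGenerator:
    def test_pure_archetype_mix(self):
        traces, labels = generate_calcium_traces(
            ScenarioConfig(seed=1), n_traces=30, mix=(0.0, 1.0, 0.0)
        )
        assert (labels.label == "non_responder").all()
        assert traces.time_s.max() < 30 * 60

    def test_grid_spacing(self):
        scenario = ScenarioConfig(seed=0)
        traces, _ = generate_calcium_traces(scenario, n_traces=3)
        one = traces[traces.trap == 0]
        assert np.allclose(np.diff(one.time_s), 10.0)

    def test_mix_proportions(self):
        _, labels = generate_calcium_traces(
            ScenarioConfig(seed=2), n_traces=200, mix=(0.5, 0.4, 0.1)
        )
        counts = labels.label.value_counts()
        assert counts["responder"] == 100
        assert counts["non_responder"] == 80
        assert counts["death_signature"] == 20

    def test_determinism(self):
        a, _ = generate_calcium_traces(ScenarioConfig(seed=5), n_traces=20)
        b, _ = generate_calcium_traces(ScenarioConfig(seed=5), n_traces=20)
        assert np.array_equal(a.intensity.to_numpy(), b.intensity.to_numpy())

    def test_zero_amplitude_responder_degenerates_to_flat(self):
        traces, labels = generate_calcium_traces(
            ScenarioConfig(seed=4),
            n_traces=20,
            mix=(1.0, 0.0, 0.0),
            responder_amplitude=(0.0, 1e-9),
        )
        from celltrap.calcium import classify_frame

        classified = classify_frame(traces)
        assert (classified.label == "non_responder").all()
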