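"""Ground-truthed synthetic data for the trap-array assays.

Emulates the two imaging regimes of the platform so every downstream stage can
be exercised without real microscopy data:

* a 14-hour time-lapse (one multi-channel frame every 2 h) of the linear trap
  array, with contact-dependent target death, spontaneous control death,
  division, escape and photobleaching.  Channel semantics follow the
  dual-fluorescence death-discrimination scheme: targets carry a green (GFP)
  label that decays after lysis plus a stable blue tracer retained post-lysis;
  propidium iodide (PI, red) in the medium marks any dead cell with a
  step-like signal, so target death is the colocalization of red and blue
  while red without blue is effector death.  Effectors are unlabelled and only
  visible in a brightfield-proxy channel.
* a 30-minute calcium assay (one sample every 10 s) with three trace
  archetypes: physiological transient responders, flat non-responders, and
  the sustained-high "death signature" of compromised effectors.

The brightfield channel is a synthetic proxy (dim trap outlines plus cell
blobs), not a model of real phase contrast.  Cells render as Gaussian blobs;
no optical PSF, drift or defocus modelling.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import rotate as _sk_rotate

from .hydraulics import TrapArrayDesign
from .loading import SimResult
from .occupancy import Cohort, CohortLabel, LoadingRate, OccupancyTable, classify_cohort

__all__ = [
    "ChannelNoise",
    "ScenarioConfig",
    "CellTruth",
    "GroundTruth",
    "ImageStack",
    "generate_ground_truth",
    "render_timelapse",
    "generate_calcium_traces",
]

CHANNELS = ("green", "blue", "red", "brightfield")


@dataclass(frozen=True)
class ChannelNoise:
    background: float = 200.0
    sd: float = 20.0


def _default_noise() -> dict:
    return {c: ChannelNoise() for c in CHANNELS}


def _default_death_prob() -> dict:
    # per-target death probabilities over the 14 h window by E:T cohort,
    # matching the platform's U87/NK92 study conditions
    return {"1:1": 0.215, "1:2": 0.126, "2:1": 0.267, "multiplet": 0.215}


def _default_death_time_weights() -> dict:
    # lysis observed mostly between 4 and 12 h on the 2 h frame grid
    return {2.0: 0.05, 4.0: 0.20, 6.0: 0.20, 8.0: 0.25, 10.0: 0.15, 12.0: 0.10, 14.0: 0.05}


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic experiment.

    ``occupancy`` may be an explicit per-trap list of (k1, k2) pairs, an
    `OccupancyTable` (expanded and shuffled), a `LoadingRate` (fresh Poisson
    draws per trap) or a `SimResult`.  Population 1 is the effector, 2 the
    target.  ``spontaneous_death`` is the per-cell baseline probability for
    (effector, target) cells outside contact traps, defaulting to the
    platform's ~1% / ~4.4% control rates.
    """

    design: TrapArrayDesign = field(default_factory=lambda: TrapArrayDesign(stages=3))
    occupancy: object = None  # defaults to LoadingRate(0.5, 0.5)
    death_prob: dict = field(default_factory=_default_death_prob)
    death_time_weights: dict = field(default_factory=_default_death_time_weights)
    spontaneous_death: tuple[float, float] = (0.01, 0.044)
    division_rate: float = 0.0
    escape_rate: float = 0.0
    gfp_decay_halflife_h: float = 4.0
    photobleach_rate: float = 0.0  # fractional loss per frame
    noise: dict = field(default_factory=_default_noise)
    um_per_pixel: float = 2.0
    cell_diameter_um: float = 14.0
    cell_amplitude: float = 3000.0
    brightfield_amplitude: float = 1500.0
    trap_outline_amplitude: float = 300.0
    frame_interval_h: float = 2.0
    duration_h: float = 14.0
    rotation_deg: float = 0.0
    ca_interval_s: float = 10.0
    ca_duration_min: float = 30.0
    max_pixels: int = 150_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("division_rate", "escape_rate", "photobleach_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        for v in self.spontaneous_death:
            if not 0.0 <= v <= 1.0:
                raise ValueError("spontaneous_death entries must be probabilities")
        for v in self.death_prob.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("death_prob entries must be probabilities")
        if self.frame_interval_h <= 0 or self.ca_interval_s <= 0:
            raise ValueError("sampling intervals must be positive")

    @property
    def frame_times_h(self) -> np.ndarray:
        n = int(round(self.duration_h / self.frame_interval_h)) + 1
        return np.arange(n) * self.frame_interval_h

    @property
    def ca_times_s(self) -> np.ndarray:
        n = int(round(self.ca_duration_min * 60 / self.ca_interval_s))
        return np.arange(n) * self.ca_interval_s


@dataclass
class CellTruth:
    trap: int
    cell_id: int
    population: int  # 1 = effector, 2 = target
    x_um: float  # offset from trap centre, along the array axis
    y_um: float  # offset from trap centre, across the array
    death_h: float | None = None
    division_h: float | None = None
    escape_h: float | None = None


@dataclass
class GroundTruth:
    """Per-trap occupancy and per-cell event times for one scenario."""

    n_traps: int
    trap_occupancy: list[tuple[int, int]]
    cells: list[CellTruth]
    frame_times_h: list[float]
    channel_identities: dict = field(
        default_factory=lambda: {
            "green": "GFP (target, decays post-death)",
            "blue": "tracer (target, stable post-lysis)",
            "red": "PI (any dead cell, step at death)",
            "brightfield": "synthetic brightfield proxy",
        }
    )
    seed: int = 0

    @property
    def cohorts(self) -> list[CohortLabel]:
        return [classify_cohort(k1, k2) for k1, k2 in self.trap_occupancy]

    def cells_in_trap(self, trap: int) -> list[CellTruth]:
        return [c for c in self.cells if c.trap == trap]

    def target_death_fraction(self, cohort_ratio: tuple[int, int] | None = None) -> float:
        """Realized fraction of dead targets, optionally within one cohort."""
        sel = [
            c
            for c in self.cells
            if c.population == 2
            and (cohort_ratio is None or self.trap_occupancy[c.trap] == cohort_ratio)
        ]
        if not sel:
            return float("nan")
        return sum(c.death_h is not None for c in sel) / len(sel)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_traps": self.n_traps,
            "trap_occupancy": [list(p) for p in self.trap_occupancy],
            "frame_times_h": list(map(float, self.frame_times_h)),
            "channel_identities": self.channel_identities,
            "seed": self.seed,
            "cells": [dataclasses.asdict(c) for c in self.cells],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        if isinstance(source, Path) or (len(str(source)) < 4096 and Path(str(source)).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        return cls(
            n_traps=payload["n_traps"],
            trap_occupancy=[tuple(p) for p in payload["trap_occupancy"]],
            cells=[CellTruth(**c) for c in payload["cells"]],
            frame_times_h=payload["frame_times_h"],
            channel_identities=payload["channel_identities"],
            seed=payload["seed"],
        )


# cell slot positions inside a trap (um offsets from the trap centre); six
# slots at >= 14 um spacing so rendered blobs stay resolvable up to capacity
_SLOTS_UM = [
    (-7.5, -12.0),
    (7.5, -12.0),
    (-7.5, 2.0),
    (7.5, 2.0),
    (-7.5, 15.0),
    (7.5, 15.0),
]


def _resolve_occupancy(
    scenario: ScenarioConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    occ = scenario.occupancy
    n_traps = scenario.design.n_traps
    if occ is None:
        occ = LoadingRate(0.5, 0.5)
    if isinstance(occ, LoadingRate):
        k1 = rng.poisson(occ.lambda1, n_traps)
        k2 = rng.poisson(occ.lambda2, n_traps)
        return list(zip(k1.tolist(), k2.tolist()))
    if isinstance(occ, SimResult):
        if len(occ.trap_counts) != n_traps:
            raise ValueError("SimResult trap count does not match the design")
        return [tuple(map(int, row)) for row in occ.trap_counts]
    if isinstance(occ, OccupancyTable):
        pairs = []
        for (k1, k2), n in np.ndenumerate(occ.counts):
            pairs.extend([(int(k1), int(k2))] * int(n))
        if len(pairs) != n_traps:
            raise ValueError("OccupancyTable N_t does not match the design")
        rng.shuffle(pairs)
        return [tuple(p) for p in pairs]
    pairs = [tuple(map(int, p)) for p in occ]
    if len(pairs) != n_traps:
        raise ValueError("explicit occupancy length must equal the trap count")
    return pairs


def _lookup_death_prob(scenario: ScenarioConfig, label: CohortLabel) -> float:
    ratio_key = str(label)
    if ratio_key in scenario.death_prob:
        return scenario.death_prob[ratio_key]
    if label.category.value in scenario.death_prob:
        return scenario.death_prob[label.category.value]
    warnings.warn(
        f"no death probability configured for cohort {ratio_key}; treating as 0",
        stacklevel=2,
    )
    return 0.0


def generate_ground_truth(scenario: ScenarioConfig) -> GroundTruth:
    """Draw per-trap occupancies and per-cell event times.

    Contact-dependent death applies only to targets in traps holding at least
    one effector and one target (probability by cohort); cells in
    single-population control traps die only at the spontaneous baseline
    rates.  All event times land on the frame grid; a cell that dies never
    divides afterwards, and competing division/escape draws keep whichever
    event comes first.  Deterministic for a given scenario (seed included).
    """
    rng = np.random.default_rng(scenario.seed)
    occupancy = _resolve_occupancy(scenario, rng)
    frame_times = scenario.frame_times_h
    event_times = frame_times[1:] if len(frame_times) > 1 else frame_times

    dt_times = np.array(sorted(scenario.death_time_weights))
    dt_weights = np.array([scenario.death_time_weights[t] for t in dt_times], dtype=float)
    dt_weights = dt_weights / dt_weights.sum()
    on_grid = np.isin(dt_times, np.round(frame_times, 9))
    if not on_grid.all():
        raise ValueError("death_time_weights support must lie on the frame grid")

    cells: list[CellTruth] = []
    cell_id = 0
    for trap, (k1, k2) in enumerate(occupancy):
        label = classify_cohort(k1, k2)
        contact = k1 >= 1 and k2 >= 1
        p_target = (
            _lookup_death_prob(scenario, label) if contact else scenario.spontaneous_death[1]
        )
        p_effector = scenario.spontaneous_death[0]
        total = k1 + k2
        slot_order = rng.permutation(len(_SLOTS_UM))[:total]
        populations = [1] * k1 + [2] * k2
        for j, pop in enumerate(populations):
            sx, sy = _SLOTS_UM[slot_order[j]]
            jx, jy = rng.uniform(-2.0, 2.0, size=2)
            p_death = p_target if pop == 2 else p_effector
            death_h = (
                float(rng.choice(dt_times, p=dt_weights)) if rng.random() < p_death else None
            )
            division_h = None
            if rng.random() < scenario.division_rate:
                division_h = float(rng.choice(event_times))
            escape_h = None
            if rng.random() < scenario.escape_rate:
                escape_h = float(rng.choice(event_times))
            # dead cells never divide afterwards; earliest competing event wins
            if death_h is not None and division_h is not None and division_h >= death_h:
                division_h = None
            if death_h is not None and escape_h is not None and escape_h >= death_h:
                escape_h = None
            if division_h is not None and escape_h is not None:
                if escape_h <= division_h:
                    division_h = None
                else:
                    escape_h = None
            cells.append(
                CellTruth(
                    trap=trap,
                    cell_id=cell_id,
                    population=pop,
                    x_um=sx + jx,
                    y_um=sy + jy,
                    death_h=death_h,
                    division_h=division_h,
                    escape_h=escape_h,
                )
            )
            cell_id += 1
    return GroundTruth(
        n_traps=len(occupancy),
        trap_occupancy=occupancy,
        cells=cells,
        frame_times_h=list(map(float, frame_times)),
        seed=scenario.seed,
    )


@dataclass
class ImageStack:
    """Multi-channel time-lapse stack with trap-grid metadata.

    ``data`` is (time, channel, row, column) uint16; ``meta`` carries the
    trap pitch, per-trap centre coordinates (pre-rotation), rotation and
    seed — the JSON sidecar written next to the TIFF.
    """

    data: np.ndarray
    channels: dict
    um_per_pixel: float
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels[name]]

    def write(self, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        tiff_path = Path(tiff_path)
        tifffile.imwrite(
            tiff_path, self.data, photometric="minisblack", metadata={"axes": "TCYX"}
        )
        sidecar = (
            Path(sidecar_path)
            if sidecar_path is not None
            else tiff_path.with_suffix(".json")
        )
        payload = {
            "channels": self.channels,
            "um_per_pixel": self.um_per_pixel,
            "meta": _jsonable(self.meta),
        }
        sidecar.write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> "ImageStack":
        tiff_path = Path(tiff_path)
        data = tifffile.imread(tiff_path)
        if data.ndim == 3:  # single channel stored without channel axis
            data = data[:, None]
        sidecar = (
            Path(sidecar_path)
            if sidecar_path is not None
            else tiff_path.with_suffix(".json")
        )
        payload = json.loads(sidecar.read_text())
        return cls(
            data=data,
            channels={k: int(v) for k, v in payload["channels"].items()},
            um_per_pixel=payload["um_per_pixel"],
            meta=payload.get("meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _add_blob(img: np.ndarray, cx: float, cy: float, sigma_px: float, amplitude: float) -> None:
    """Add a Gaussian blob at (cx, cy) in place (x = column, y = row)."""
    h, w = img.shape
    r = int(math.ceil(4 * sigma_px))
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma_px**2)
    )


def _trap_outline(img: np.ndarray, cx: float, cy: float, half_w: int, half_h: int, amp: float) -> None:
    h, w = img.shape
    x0, x1 = int(cx - half_w), int(cx + half_w)
    y0, y1 = int(cy - half_h), int(cy + half_h)
    x0, x1 = max(x0, 0), min(x1, w - 1)
    y0, y1 = max(y0, 0), min(y1, h - 1)
    img[y0 : y1 + 1, x0] += amp
    img[y0 : y1 + 1, x1] += amp
    img[y0, x0 : x1 + 1] += amp
    img[y1, x0 : x1 + 1] += amp


def render_timelapse(truth: GroundTruth, scenario: ScenarioConfig) -> ImageStack:
    """Render a ground truth into a multi-channel uint16 time-lapse stack.

    Per frame: live targets carry stable green + blue; from its death frame a
    target gains a red PI step, keeps blue (debris is retained by the filters)
    and its green decays exponentially with the configured half-life.  Dead
    effectors gain red only.  All cells render in the brightfield proxy.
    Escaping cells shift out of the trap over two frames then disappear;
    division spawns an adjacent equal-intensity blob.  Photobleaching applies
    a per-frame multiplicative loss to the fluorescence channels, and Gaussian
    background noise is added everywhere.
    """
    design = scenario.design
    upp = scenario.um_per_pixel
    pitch_px = design.trap_pitch_um / upp
    margin_px = int(round(24.0 / upp))
    chamber_h_px = int(round(44.0 / upp))
    width = int(round(truth.n_traps * pitch_px)) + 2 * margin_px
    height = chamber_h_px + 2 * margin_px
    frame_times = np.asarray(truth.frame_times_h)
    n_frames = len(frame_times)
    n_px = n_frames * len(CHANNELS) * width * height
    if n_px > scenario.max_pixels:
        raise ValueError(
            f"scene of {n_px} pixels exceeds the configured budget {scenario.max_pixels}"
        )

    centers_x = margin_px + (np.arange(truth.n_traps) + 0.5) * pitch_px
    center_y = height / 2.0
    sigma_px = scenario.cell_diameter_um / 4.0 / upp
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0xC311]))

    stack = np.zeros((n_frames, len(CHANNELS), height, width), dtype=np.float64)
    ch = {name: i for i, name in enumerate(CHANNELS)}

    # static trap outlines on the brightfield proxy
    outline = np.zeros((height, width))
    half_w = int(round(15.0 / upp))
    half_h = int(round(22.0 / upp))
    for cx in centers_x:
        _trap_outline(outline, cx, center_y, half_w, half_h, scenario.trap_outline_amplitude)

    for t_idx, t in enumerate(frame_times):
        bleach = (1.0 - scenario.photobleach_rate) ** t_idx
        planes = stack[t_idx]
        planes[ch["brightfield"]] += outline
        for cell in truth.cells:
            cx = centers_x[cell.trap] + cell.x_um / upp
            cy = center_y + cell.y_um / upp
            # escape: move out of the ROI over 2 frames, then gone
            if cell.escape_h is not None and t >= cell.escape_h:
                frames_since = (t - cell.escape_h) / scenario.frame_interval_h
                if frames_since >= 1:
                    continue
                cy += (height / 2.0) * (0.5 + 0.5 * frames_since)
            dead = cell.death_h is not None and t >= cell.death_h
            amp = scenario.cell_amplitude
            positions = [(cx, cy)]
            if cell.division_h is not None and t >= cell.division_h:
                positions.append((cx + 10.0 / upp, cy + 4.0 / upp))
            for px, py in positions:
                if cell.population == 2:  # target: green + blue (+ red after death)
                    green_amp = amp * bleach
                    if dead:
                        green_amp *= 0.5 ** ((t - cell.death_h) / scenario.gfp_decay_halflife_h)
                        _add_blob(planes[ch["red"]], px, py, sigma_px, amp * bleach)
                    _add_blob(planes[ch["green"]], px, py, sigma_px, green_amp)
                    _add_blob(planes[ch["blue"]], px, py, sigma_px, amp * bleach)
                else:  # effector: brightfield only, red after its own death
                    if dead:
                        _add_blob(planes[ch["red"]], px, py, sigma_px, amp * bleach)
                _add_blob(
                    planes[ch["brightfield"]], px, py, sigma_px, scenario.brightfield_amplitude
                )

    for name, idx in ch.items():
        noise = scenario.noise.get(name, ChannelNoise())
        stack[:, idx] += rng.normal(noise.background, noise.sd, size=stack[:, idx].shape)

    if abs(scenario.rotation_deg) > 1e-9:
        rotated = []
        for t_idx in range(n_frames):
            per_channel = []
            for c_idx in range(len(CHANNELS)):
                name = CHANNELS[c_idx]
                bg = scenario.noise.get(name, ChannelNoise()).background
                per_channel.append(
                    _sk_rotate(
                        stack[t_idx, c_idx],
                        scenario.rotation_deg,
                        resize=True,
                        preserve_range=True,
                        cval=bg,
                    )
                )
            rotated.append(np.stack(per_channel))
        stack = np.stack(rotated)

    stack = np.clip(stack, 0, 65535).astype(np.uint16)
    meta = {
        "pitch_um": design.trap_pitch_um,
        "pitch_px": pitch_px,
        "n_traps": truth.n_traps,
        "trap_centers_x_px": centers_x,
        "trap_center_y_px": center_y,
        "rotation_deg": scenario.rotation_deg,
        "frame_times_h": frame_times,
        "seed": scenario.seed,
        "margin_px": margin_px,
    }
    return ImageStack(
        data=stack, channels=ch, um_per_pixel=upp, meta=meta
    )


def _gamma_pulse(t: np.ndarray, onset: float, tau: float, amplitude: float) -> np.ndarray:
    """Gamma-shaped transient: rises over ~tau, decays back to baseline."""
    x = np.clip((t - onset) / tau, 0, None)
    return amplitude * x * np.exp(1.0 - x)


def generate_calcium_traces(
    scenario: ScenarioConfig,
    n_traces: int = 300,
    mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    baseline: float = 100.0,
    noise_sd: float = 3.0,
    responder_amplitude: tuple[float, float] = (150.0, 300.0),
    plateau_level: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesise labelled calcium traces of the three archetypes.

    ``mix`` gives the (responder, non_responder, death_signature) proportions.
    Responders carry 1-3 gamma-shaped transients on baseline noise;
    non-responders are flat noise; the death signature steps early to a
    sustained plateau at ``plateau_level`` times baseline with no return.
    Returns (long-form traces, labels): traces have columns
    (trap, cell, time_s, intensity); labels have (trap, cell, label, ...).
    """
    if abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError("mix must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0xCA]))
    t = scenario.ca_times_s
    labels = ["responder", "non_responder", "death_signature"]
    counts = np.floor(np.asarray(mix) * n_traces).astype(int)
    while counts.sum() < n_traces:
        counts[int(np.argmax(np.asarray(mix) * n_traces - counts))] += 1
    assignment = rng.permutation(np.repeat(np.arange(3), counts))

    trace_rows, label_rows = [], []
    for i, which in enumerate(assignment):
        label = labels[which]
        y = baseline + rng.normal(0, noise_sd, size=len(t))
        truth: dict = {"trap": i, "cell": 0, "label": label}
        if label == "responder":
            n_pulses = int(rng.integers(1, 4))
            onsets = np.sort(rng.uniform(60, t[-1] - 300, size=n_pulses))
            amps, taus = [], []
            for onset in onsets:
                amp = float(rng.uniform(*responder_amplitude))
                tau = float(rng.uniform(40, 90))
                y += _gamma_pulse(t, onset, tau, amp)
                amps.append(amp)
                taus.append(tau)
            truth.update(
                {
                    "n_pulses": n_pulses,
                    "onset_s": float(onsets[0]),
                    "peak_s": float(onsets[int(np.argmax(amps))] + taus[int(np.argmax(amps))]),
                    "amplitude": float(max(amps)),
                }
            )
        elif label == "death_signature":
            # compromised shortly after loading, but after the F0 baseline
            # window so the step is visible in the recorded trace
            step_at = float(rng.uniform(60, 300))
            rise = 30.0
            level = baseline * plateau_level
            y += (level - baseline) / (1.0 + np.exp(-(t - step_at) / (rise / 4)))
            truth.update({"onset_s": step_at, "amplitude": level - baseline})
        trace_rows.append(
            pd.DataFrame({"trap": i, "cell": 0, "time_s": t, "intensity": y})
        )
        label_rows.append(truth)
    traces = pd.concat(trace_rows, ignore_index=True)
    return traces, pd.DataFrame(label_rows)
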