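"""Trap-array time-lapse quantification pipeline.

Takes a stitched multi-channel stack of the linear trap array and produces
per-cohort cytotoxicity statistics: straighten and crop the array band, split
it into per-trap ROIs on the fitted periodic grid, count cells and extract
background-subtracted intensity traces per trap, call deaths by the
colocalization of the blue tracer with the red PI signal (red without blue is
effector death; GFP loss alone never suffices), exclude traps whose E:T ratio
is corrupted by division or escape, and compare cohorts with the
normality-gated ANOVA/Tukey or Kruskal-Wallis/Dunn procedure.

Pixel conventions: 0-based row-major indices, origin top-left; ROI boxes are
half-open ``[r0, r1) x [c0, c1)`` intervals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.feature import peak_local_max
from skimage.morphology import dilation, disk, opening
from skimage.transform import rotate as sk_rotate

from .hydraulics import TrapArrayDesign
from .occupancy import Cohort, CohortLabel, classify_cohort
from .synth import CHANNELS, ImageStack

__all__ = [
    "PipelineConfig",
    "TrapROIMap",
    "TrapTimeSeries",
    "DeathEvent",
    "ExclusionFlags",
    "CytotoxicityResult",
    "straighten_and_crop",
    "split_traps",
    "count_cells",
    "extract_traces",
    "call_death",
    "apply_exclusions",
    "summarize_cytotoxicity",
    "compare_cohorts",
    "analyze_stack",
    "significance_stars",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the quantification pipeline.

    ``mask_k_mad`` sets the low floor (background median + k * robust sd) used
    for the tracer/PI masks and as the Otsu floor when counting;
    ``overlap_threshold`` is the PI-on-tracer overlap fraction that calls a
    target death.  The cell diameter window filters segmented components.
    """

    cell_diameter_um: tuple[float, float] = (7.0, 25.0)
    mask_k_mad: float = 6.0
    overlap_threshold: float = 0.5
    min_rotation_deg: float = 0.2
    max_rotation_deg: float = 5.0
    pitch_tolerance: float = 0.10
    saturation_level: int = 65535
    saturation_fraction: float = 0.05
    smooth_sigma_px: float = 1.0


@dataclass
class TrapROIMap:
    """Per-trap bounding boxes on the aligned stack."""

    boxes: list[tuple[int, int, int, int]]  # (r0, r1, c0, c1), half-open
    pitch_px: float
    phase_px: float
    rotation_deg: float

    @property
    def n(self) -> int:
        return len(self.boxes)

    def centers(self) -> np.ndarray:
        return np.array([(b[2] + b[3]) / 2.0 for b in self.boxes])


@dataclass
class DeathEvent:
    time_h: float
    population: int  # 1 = effector, 2 = target


@dataclass
class TrapTimeSeries:
    """Per-trap traces, counts and death observables over the window."""

    trap: int
    times_h: np.ndarray
    intensity: dict  # channel -> background-subtracted mean, per frame
    counts_eff: np.ndarray
    counts_tgt: np.ndarray
    n_dead_targets: np.ndarray  # tracer components colocalized with PI
    n_dead_effectors: np.ndarray  # PI components lacking tracer
    ambiguous: np.ndarray  # per-frame saturation flags
    events: list[DeathEvent] = field(default_factory=list)

    @property
    def cohort0(self) -> CohortLabel:
        return classify_cohort(int(self.counts_eff[0]), int(self.counts_tgt[0]))


@dataclass
class ExclusionFlags:
    excluded: bool
    reasons: frozenset

    def __post_init__(self) -> None:
        assert self.excluded == bool(self.reasons)


@dataclass
class CytotoxicityResult:
    """Per-cohort death fractions, viability and exclusion accounting."""

    cohort_table: pd.DataFrame
    per_trap: pd.DataFrame
    significance: pd.DataFrame | None = None

    def death_fraction(self, cohort: str) -> float:
        row = self.cohort_table.loc[self.cohort_table.cohort == cohort]
        if row.empty:
            return float("nan")
        return float(row.target_death_pct.iloc[0])

    def viability(self, cohort: str) -> float:
        row = self.cohort_table.loc[self.cohort_table.cohort == cohort]
        if row.empty:
            return float("nan")
        return float(row.viability_pct.iloc[0])


def _reference_image(stack: ImageStack) -> np.ndarray:
    """Time-mean, channel-sum image used for geometry estimation."""
    return stack.data.astype(np.float64).mean(axis=0).sum(axis=0)


def straighten_and_crop(
    stack: ImageStack, config: PipelineConfig = PipelineConfig()
) -> tuple[ImageStack, float]:
    """Rotate the array band to the horizontal axis and crop to its extent.

    The global rotation is the principal-axis angle of the thresholded
    foreground mask (second image moments).  Returns the aligned stack and the
    rotation that was applied (degrees, counter-clockwise positive).  Raises
    if no foreground band is detectable.
    """
    ref = _reference_image(stack)
    # low robust threshold: the orientation estimate needs the full array band
    # (trap walls included), not just the brightest cells
    med = float(np.median(ref))
    mad_sd = 1.4826 * float(np.median(np.abs(ref - med)))
    thr = med + 6.0 * max(mad_sd, 1e-6)
    mask = ref > thr
    if mask.sum() < 100 or mask.mean() > 0.9:
        raise ValueError("no detectable array band in the stack")
    rows, cols = np.nonzero(mask)
    r_c, c_c = rows.mean(), cols.mean()
    mu20 = np.mean((cols - c_c) ** 2)
    mu02 = np.mean((rows - r_c) ** 2)
    mu11 = np.mean((cols - c_c) * (rows - r_c))
    # principal-axis angle of the band relative to the column axis; rows grow
    # downward so a counter-clockwise scene rotation gives negative mu11
    angle = 0.5 * math.degrees(math.atan2(-2 * mu11, mu20 - mu02))
    if abs(angle) > config.max_rotation_deg:
        raise ValueError(
            f"estimated rotation {angle:.2f} deg exceeds the {config.max_rotation_deg} deg limit"
        )

    data = stack.data.astype(np.float64)
    if abs(angle) >= config.min_rotation_deg:
        rotated = np.empty_like(data)
        for t in range(data.shape[0]):
            for c in range(data.shape[1]):
                bg = float(np.median(data[t, c]))
                rotated[t, c] = sk_rotate(
                    data[t, c], -angle, resize=False, preserve_range=True, cval=bg
                )
        data = rotated
    else:
        angle = 0.0

    ref2 = data.mean(axis=0).sum(axis=0)
    med2 = float(np.median(ref2))
    mad2 = 1.4826 * float(np.median(np.abs(ref2 - med2)))
    mask2 = ref2 > med2 + 6.0 * max(mad2, 1e-6)
    row_any = np.nonzero(mask2.any(axis=1))[0]
    pad = max(3, int(0.2 * (row_any[-1] - row_any[0] + 1)))
    r0 = max(row_any[0] - pad, 0)
    r1 = min(row_any[-1] + pad + 1, data.shape[2])
    col_any = np.nonzero(mask2.any(axis=0))[0]
    # wider column pad: an outer trap's cell can sit half a pitch beyond the
    # outermost detected foreground
    pad_c = max(pad, int(0.3 * (r1 - r0)))
    c0 = max(col_any[0] - pad_c, 0)
    c1 = min(col_any[-1] + pad_c + 1, data.shape[3])
    cropped = np.clip(data[:, :, r0:r1, c0:c1], 0, 65535).astype(np.uint16)

    meta = dict(stack.meta)
    meta.update({"straighten_rotation_deg": -angle, "crop_origin": [int(r0), int(c0)]})
    return (
        ImageStack(cropped, dict(stack.channels), stack.um_per_pixel, meta),
        -angle,
    )


def split_traps(
    aligned: ImageStack,
    design: TrapArrayDesign,
    config: PipelineConfig = PipelineConfig(),
) -> TrapROIMap:
    """Fit the periodic trap grid and emit exactly N per-trap ROIs.

    The pitch comes from the design and the pixel size; the grid phase is the
    comb offset maximising the summed column profile (robust to empty traps).
    The pitch is cross-checked against the autocorrelation of the profile and
    must agree with the design within ``pitch_tolerance``.
    """
    ref = _reference_image(aligned)
    profile = ref.sum(axis=0)
    profile = profile - np.median(profile)
    pitch = design.trap_pitch_um / aligned.um_per_pixel
    n = design.n_traps

    # pitch sanity check: dominant spatial frequency of the detrended profile
    detrended = profile - ndimage.uniform_filter1d(profile, int(2 * pitch))
    spectrum = np.abs(np.fft.rfft(detrended * np.hanning(len(detrended)))) ** 2
    freqs = np.fft.rfftfreq(len(detrended))
    band = (freqs >= 1.0 / (1.5 * pitch)) & (freqs <= 1.0 / (0.6 * pitch))
    if band.sum() > 2 and spectrum[band].max() > 0:
        f_peak = freqs[band][int(np.argmax(spectrum[band]))]
        fitted = 1.0 / f_peak
        if abs(fitted - pitch) / pitch > config.pitch_tolerance:
            raise ValueError(
                f"fitted pitch {fitted:.1f} px deviates more than "
                f"{config.pitch_tolerance:.0%} from the design pitch {pitch:.1f} px"
            )

    width = len(profile)
    # score the foreground mass inside a trap-interior window around each comb
    # tooth, not single columns, so the phase centres traps rather than
    # locking onto individual cells
    win = max(3, int(round(0.6 * pitch)) | 1)
    windowed = np.convolve(np.clip(profile, 0, None), np.ones(win), mode="same")
    lo_off = min(-pitch, width - n * pitch - pitch)
    offsets = np.arange(lo_off, pitch, 0.25)
    scores = np.empty(len(offsets))
    for i, phase in enumerate(offsets):
        centers = phase + pitch * (np.arange(n) + 0.5)
        idx = np.round(centers).astype(int)
        valid = (idx >= 0) & (idx < width)
        scores[i] = windowed[idx[valid]].sum()
    phase = float(offsets[int(np.argmax(scores))])
    if width < 0.5 * n * pitch:
        raise ValueError(
            f"aligned stack ({width} px) cannot hold {n} traps at pitch {pitch:.1f} px"
        )

    # boxes on the fitted grid; traps whose region the crop removed (only
    # empty stretches can be cropped) collapse to minimal edge stubs
    boxes = []
    h = aligned.data.shape[2]
    for i in range(n):
        c0 = int(round(phase + i * pitch))
        c1 = int(round(phase + (i + 1) * pitch))
        c0 = max(0, min(c0, width - 2))
        c1 = max(c0 + 2, min(c1, width))
        boxes.append((0, h, c0, c1))
    return TrapROIMap(
        boxes=boxes,
        pitch_px=pitch,
        phase_px=phase,
        rotation_deg=float(aligned.meta.get("straighten_rotation_deg", 0.0)),
    )


def _robust_background(roi: np.ndarray, ring: int = 3) -> tuple[float, float]:
    """Median and MAD-based sd of the ROI border ring."""
    border = np.concatenate(
        [
            roi[:ring].ravel(),
            roi[-ring:].ravel(),
            roi[:, :ring].ravel(),
            roi[:, -ring:].ravel(),
        ]
    )
    med = float(np.median(border))
    sd = float(1.4826 * np.median(np.abs(border - med))) or 1.0
    return med, sd


def _area_window_px(config: PipelineConfig, um_per_pixel: float) -> tuple[float, float]:
    lo, hi = config.cell_diameter_um
    to_px = lambda d: math.pi * (d / 2.0 / um_per_pixel) ** 2
    return to_px(lo), to_px(hi)


def _component_mask(
    img: np.ndarray, threshold: float, area_lo: float, area_hi: float
) -> np.ndarray:
    """Label image of threshold components inside the area window.

    A binary opening removes thin structures (trap walls, debris streaks)
    that are far narrower than a cell before components are labelled.
    """
    mask = opening(img > threshold, disk(1))
    lab = sk_label(mask)
    if lab.max() == 0:
        return lab
    areas = np.bincount(lab.ravel())
    bad = np.nonzero((areas < area_lo) | (areas > area_hi * 6))[0]  # *6: merged blobs pass
    lab[np.isin(lab, bad[bad > 0])] = 0
    return sk_label(lab > 0)


def _count_peaks(
    img: np.ndarray, components: np.ndarray, min_distance_px: int, threshold: float
) -> tuple[int, list[tuple[float, float]]]:
    """Count cells as smoothed local maxima within labelled components."""
    if components.max() == 0:
        return 0, []
    smooth = gaussian(img, sigma=1.5, preserve_range=True)
    peaks = peak_local_max(
        smooth,
        min_distance=min_distance_px,
        threshold_abs=threshold,
        labels=components,
        exclude_border=False,
    )
    count = 0
    centroids: list[tuple[float, float]] = []
    for comp in range(1, components.max() + 1):
        in_comp = peaks[components[peaks[:, 0], peaks[:, 1]] == comp]
        if len(in_comp) > 1:
            # a genuine second cell peaks near the first one's height; noise
            # bumps on a blob's rim do not
            heights = smooth[in_comp[:, 0], in_comp[:, 1]]
            in_comp = in_comp[heights >= 0.35 * heights.max()]
        k = max(1, len(in_comp))
        count += k
        if len(in_comp):
            centroids.extend([(float(r), float(c)) for r, c in in_comp])
        else:
            rr, cc = np.nonzero(components == comp)
            centroids.append((float(rr.mean()), float(cc.mean())))
    return count, centroids


@dataclass
class CountResult:
    n_effectors: int
    n_targets: int
    target_centroids: list
    effector_centroids: list
    per_cell_intensity: dict
    ambiguous: bool


def count_cells(
    roi_channels: dict,
    um_per_pixel: float,
    config: PipelineConfig = PipelineConfig(),
) -> CountResult:
    """Count targets (green | blue) and effectors (brightfield, not target).

    Threshold is Otsu with a floor at background median + k * MAD, followed by
    connected components, an area filter over the cell-diameter window, and
    local-maximum splitting of merged blobs.  A heavily saturated ROI is
    flagged ambiguous.
    """
    area_lo, area_hi = _area_window_px(config, um_per_pixel)
    min_dist = max(2, int(round(0.5 * config.cell_diameter_um[0] / um_per_pixel)))

    def mask_for(img: np.ndarray) -> tuple[np.ndarray, float]:
        med, sd = _robust_background(img)
        floor = med + config.mask_k_mad * sd
        thr = floor
        if (img > floor).mean() > 0.3:
            # background structure dominates the floor; fall back to Otsu
            try:
                thr = max(floor, threshold_otsu(img))
            except ValueError:
                thr = floor
        return _component_mask(img, thr, area_lo, area_hi), thr

    green = roi_channels.get("green")
    blue = roi_channels.get("blue")
    bf = roi_channels.get("brightfield")

    target_img = None
    for img in (green, blue):
        if img is None:
            continue
        med, _ = _robust_background(img)
        shifted = img.astype(np.float64) - med
        target_img = shifted if target_img is None else np.maximum(target_img, shifted)
    ambiguous = False
    n_tgt, tgt_centroids, tgt_intens = 0, [], []
    target_mask = None
    if target_img is not None:
        comp, thr = mask_for(target_img)
        n_tgt, tgt_centroids = _count_peaks(target_img, comp, min_dist, thr)
        target_mask = comp > 0
        for r, c in tgt_centroids:
            tgt_intens.append(float(target_img[int(r), int(c)]))

    n_eff, eff_centroids, eff_intens = 0, [], []
    if bf is not None:
        sat = False
        for img in (bf, green, blue):
            if img is not None:
                sat = sat or (
                    (img >= config.saturation_level).mean() > config.saturation_fraction
                )
        ambiguous = bool(sat)
        # remove the trap-wall grid: walls span whole rows/columns of the ROI
        # while cells are compact, so sequential row- and column-median
        # subtraction flattens the walls and keeps the blobs
        bf_f = bf.astype(np.float64)
        bf_f = bf_f - np.median(bf_f, axis=1, keepdims=True)
        bf_f = bf_f - np.median(bf_f, axis=0, keepdims=True)
        comp, thr = mask_for(bf_f)
        if target_mask is not None and comp.max() > 0:
            # effectors are brightfield objects not explained by the target
            # fluorescence; subtracting the (dilated) target mask also splits
            # touching effector/target blobs
            residue = (comp > 0) & ~dilation(target_mask, disk(1))
            residue = opening(residue, disk(1))
            keep = sk_label(residue)
            if keep.max() > 0:
                areas = np.bincount(keep.ravel())
                bad = np.nonzero(areas < 0.5 * area_lo)[0]
                keep[np.isin(keep, bad[bad > 0])] = 0
                keep = sk_label(keep > 0)
            n_eff, eff_centroids = _count_peaks(bf_f, keep, min_dist, thr)
        else:
            n_eff, eff_centroids = _count_peaks(bf_f, comp, min_dist, thr)
        for r, c in eff_centroids:
            eff_intens.append(float(bf_f[int(r), int(c)]))

    return CountResult(
        n_effectors=n_eff,
        n_targets=n_tgt,
        target_centroids=tgt_centroids,
        effector_centroids=eff_centroids,
        per_cell_intensity={"target": tgt_intens, "effector": eff_intens},
        ambiguous=ambiguous,
    )


def _death_observables(
    roi_channels: dict, um_per_pixel: float, config: PipelineConfig
) -> tuple[int, int]:
    """(tracer components colocalized with PI, PI components lacking tracer)."""
    blue = roi_channels.get("blue")
    red = roi_channels.get("red")
    if red is None:
        raise ValueError("PI (red) channel is required for death calling")
    area_lo, _ = _area_window_px(config, um_per_pixel)

    def low_mask(img: np.ndarray) -> np.ndarray:
        med, sd = _robust_background(img)
        return img.astype(np.float64) - med > config.mask_k_mad * sd

    pi_mask = low_mask(red)
    tracer_mask = low_mask(blue) if blue is not None else np.zeros_like(pi_mask)

    n_dead_tgt = 0
    tracer_lab = sk_label(tracer_mask)
    for comp in range(1, tracer_lab.max() + 1):
        sel = tracer_lab == comp
        if sel.sum() < area_lo:
            continue
        if (pi_mask & sel).sum() / sel.sum() >= config.overlap_threshold:
            n_dead_tgt += 1

    n_dead_eff = 0
    pi_only = pi_mask & ~dilation(tracer_mask, disk(2))
    pi_lab = sk_label(pi_only)
    for comp in range(1, pi_lab.max() + 1):
        if (pi_lab == comp).sum() >= area_lo:
            n_dead_eff += 1
    return n_dead_tgt, n_dead_eff


def extract_traces(
    aligned: ImageStack,
    roimap: TrapROIMap,
    config: PipelineConfig = PipelineConfig(),
) -> list[TrapTimeSeries]:
    """Per-trap, per-channel intensity traces plus counts and death observables.

    Intensity is the interior mean minus the ROI border-ring median (local
    background), per channel and frame.
    """
    times = np.asarray(
        aligned.meta.get("frame_times_h", np.arange(aligned.n_frames)), dtype=float
    )
    series: list[TrapTimeSeries] = []
    names = list(aligned.channels)
    for trap, (r0, r1, c0, c1) in enumerate(roimap.boxes):
        n_frames = aligned.n_frames
        intensity = {name: np.zeros(n_frames) for name in names}
        counts_eff = np.zeros(n_frames, dtype=int)
        counts_tgt = np.zeros(n_frames, dtype=int)
        dead_tgt = np.zeros(n_frames, dtype=int)
        dead_eff = np.zeros(n_frames, dtype=int)
        ambiguous = np.zeros(n_frames, dtype=bool)
        for t in range(n_frames):
            rois = {
                name: aligned.data[t, aligned.channels[name], r0:r1, c0:c1]
                for name in names
            }
            for name, roi in rois.items():
                med, _ = _robust_background(roi)
                interior = roi[3:-3, 3:-3] if min(roi.shape) > 8 else roi
                intensity[name][t] = float(interior.mean()) - med
            res = count_cells(rois, aligned.um_per_pixel, config)
            counts_eff[t] = res.n_effectors
            counts_tgt[t] = res.n_targets
            ambiguous[t] = res.ambiguous
            dt, de = _death_observables(rois, aligned.um_per_pixel, config)
            dead_tgt[t] = dt
            dead_eff[t] = de
        series.append(
            TrapTimeSeries(
                trap=trap,
                times_h=times,
                intensity=intensity,
                counts_eff=counts_eff,
                counts_tgt=counts_tgt,
                n_dead_targets=dead_tgt,
                n_dead_effectors=dead_eff,
                ambiguous=ambiguous,
            )
        )
    return series


def call_death(series: TrapTimeSeries) -> list[DeathEvent]:
    """Death events from the colocalization observables.

    A target death is an increment of the (monotonized) count of tracer
    components overlapping PI; a PI component without tracer is an effector
    death.  Intensity loss alone never calls a death.  Events are attached to
    the series and returned.
    """
    events: list[DeathEvent] = []
    for counts, pop in ((series.n_dead_targets, 2), (series.n_dead_effectors, 1)):
        running = np.maximum.accumulate(counts)
        prev = 0
        for t, value in enumerate(running):
            for _ in range(value - prev):
                events.append(DeathEvent(time_h=float(series.times_h[t]), population=pop))
            prev = value
    series.events = events
    return events


def apply_exclusions(series: TrapTimeSeries) -> ExclusionFlags:
    """Flag traps whose E:T ratio integrity is broken.

    ``division``: a population count rises above its initial value for at
    least two consecutive frames (persistence rejects segmentation flicker).
    ``escape``: a count falls below its initial value with no matching death
    in the window — debris is retained in the traps, so death never lowers a
    count.  ``preloaded_dead``: PI-positive at frame 0.  ``ambiguous_count``:
    any saturated frame.  Flags compose.
    """
    def sustained(flags: np.ndarray) -> bool:
        return any(flags[i] and flags[i + 1] for i in range(len(flags) - 1))

    reasons: set[str] = set()
    for counts in (series.counts_eff, series.counts_tgt):
        baseline = counts[0]
        above = counts > baseline
        below = counts < baseline
        if sustained(above):
            reasons.add("division")
        # a drop on the final frame cannot show persistence but still breaks
        # the ratio; deaths never lower counts (debris is retained)
        if sustained(below) or (len(counts) > 1 and below[-1]):
            reasons.add("escape")
    if series.n_dead_targets[0] > 0 or series.n_dead_effectors[0] > 0:
        reasons.add("preloaded_dead")
    if series.ambiguous.any():
        reasons.add("ambiguous_count")
    return ExclusionFlags(excluded=bool(reasons), reasons=frozenset(reasons))


def _cohort_key(label: CohortLabel) -> str:
    if label.category in (Cohort.SINGLET,):
        return "1:1"
    if label.category is Cohort.MULTIPLET and label.ratio in ((1, 2), (2, 1)):
        return f"{label.ratio[0]}:{label.ratio[1]}"
    if label.category is Cohort.MULTIPLET:
        return "multiplet"
    if label.category is Cohort.EFFECTOR_ONLY:
        return "effector_only"
    if label.category is Cohort.TARGET_ONLY:
        return "target_only"
    return "empty"


def summarize_cytotoxicity(
    series_list: list[TrapTimeSeries],
    flags: list[ExclusionFlags] | None = None,
    intensity_channel: str = "green",
) -> CytotoxicityResult:
    """Per-cohort target/effector death fractions over retained traps.

    Cohorts are assigned from the frame-0 counts.  Control cohorts report
    spontaneous death and viability; every cohort reports mean +/- sd of the
    per-trap normalized endpoint intensity (endpoint / initial).  The
    accounting identity retained + excluded = assigned holds per cohort.
    """
    if flags is None:
        flags = [apply_exclusions(s) for s in series_list]
    rows = []
    for s, f in zip(series_list, flags):
        if not s.events:
            call_death(s)
        tgt_deaths = sum(e.population == 2 for e in s.events)
        eff_deaths = sum(e.population == 1 for e in s.events)
        init = s.intensity[intensity_channel][0]
        endpoint = s.intensity[intensity_channel][-1]
        has_carrier = s.counts_tgt[0] > 0  # green/tracer live on targets only
        rows.append(
            {
                "trap": s.trap,
                "cohort": _cohort_key(s.cohort0),
                "n_eff0": int(s.counts_eff[0]),
                "n_tgt0": int(s.counts_tgt[0]),
                "excluded": f.excluded,
                "reasons": ";".join(sorted(f.reasons)),
                "target_deaths": min(tgt_deaths, int(s.counts_tgt[0])),
                "effector_deaths": min(eff_deaths, int(s.counts_eff[0])),
                "normalized_endpoint": endpoint / init if has_carrier and init > 0 else np.nan,
                "intensity_drop_abs": (init - endpoint),
            }
        )
    per_trap = pd.DataFrame(rows)

    cohort_rows = []
    for cohort, grp in per_trap.groupby("cohort"):
        retained = grp.loc[~grp.excluded]
        n_tgt = retained.n_tgt0.sum()
        n_eff = retained.n_eff0.sum()
        tgt_pct = 100.0 * retained.target_deaths.sum() / n_tgt if n_tgt else np.nan
        eff_pct = 100.0 * retained.effector_deaths.sum() / n_eff if n_eff else np.nan
        if cohort == "target_only":
            viability = 100.0 - tgt_pct if n_tgt else np.nan
        elif cohort == "effector_only":
            viability = 100.0 - eff_pct if n_eff else np.nan
        else:
            viability = 100.0 - tgt_pct if n_tgt else np.nan
        cohort_rows.append(
            {
                "cohort": cohort,
                "n_assigned": len(grp),
                "n_retained": len(retained),
                "n_excluded": int(grp.excluded.sum()),
                "target_death_pct": tgt_pct,
                "effector_death_pct": eff_pct,
                "viability_pct": viability,
                "normalized_endpoint_mean": retained.normalized_endpoint.mean(),
                "normalized_endpoint_sd": retained.normalized_endpoint.std(ddof=0),
            }
        )
    cohort_table = pd.DataFrame(cohort_rows)
    return CytotoxicityResult(cohort_table=cohort_table, per_trap=per_trap)


def significance_stars(p: float) -> str:
    """Map a p-value to the platform's significance tiers."""
    if p < 0.0001:
        return "****"
    if p < 0.0002:
        return "***"
    if p < 0.0021:
        return "**"
    if p < 0.0332:
        return "*"
    return "ns"


def _dunn_test(groups: dict) -> pd.DataFrame:
    """Dunn's post-hoc rank comparison after Kruskal-Wallis, Holm-adjusted."""
    names = list(groups)
    values = np.concatenate([np.asarray(groups[n], dtype=float) for n in names])
    sizes = np.array([len(groups[n]) for n in names])
    ranks = stats.rankdata(values)
    big_n = len(values)
    mean_ranks, start = {}, 0
    for n, size in zip(names, sizes):
        mean_ranks[n] = ranks[start : start + size].mean()
        start += size
    # tie correction to the rank variance
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (big_n - 1))
    var_base = big_n * (big_n + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = math.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "statistic": z, "p_raw": p})
    df = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    df["p_value"] = multipletests(df.p_raw, method="holm")[1]
    return df


def compare_cohorts(
    per_trap_values: dict, shapiro_alpha: float = 0.05, min_n: int = 3
) -> pd.DataFrame:
    """Pairwise cohort comparison with the normality-gated procedure.

    Shapiro tests gate between one-way ANOVA + Tukey HSD (all groups normal)
    and Kruskal-Wallis + Dunn's multiple-comparison test.  Cohorts with fewer
    than ``min_n`` traps are skipped with a notice column.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in per_trap_values.items() if len(v) >= min_n}
    skipped = sorted(set(per_trap_values) - set(usable))
    if len(usable) < 2:
        raise ValueError("need at least two cohorts with enough traps")

    normal = True
    for vals in usable.values():
        if np.ptp(vals) == 0:  # degenerate: constant group, Shapiro undefined
            normal = False
            break
        if stats.shapiro(vals).pvalue < shapiro_alpha:
            normal = False
            break

    if normal:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        names = list(usable)
        data = np.concatenate([usable[n] for n in names])
        labels = np.concatenate([[n] * len(usable[n]) for n in names])
        tk = pairwise_tukeyhsd(data, labels, alpha=0.05)
        df = pd.DataFrame(
            tk.summary().data[1:], columns=[c.strip() for c in tk.summary().data[0]]
        )
        out = pd.DataFrame(
            {
                "group1": df.group1,
                "group2": df.group2,
                "statistic": df.meandiff.astype(float),
                "p_value": df["p-adj"].astype(float),
            }
        )
        out["procedure"] = "anova_tukey"
    else:
        out = _dunn_test(usable)[["group1", "group2", "statistic", "p_value"]]
        out["procedure"] = "kruskal_dunn"
    out["stars"] = out.p_value.map(significance_stars)
    out["significant"] = out.p_value < 0.0332
    out.attrs["skipped_cohorts"] = skipped
    return out


def analyze_stack(
    stack: ImageStack,
    design: TrapArrayDesign,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[TrapTimeSeries], list[ExclusionFlags], CytotoxicityResult]:
    """Full pipeline: straighten, split, extract, call deaths, summarize."""
    aligned, _ = straighten_and_crop(stack, config)
    roimap = split_traps(aligned, design, config)
    series = extract_traces(aligned, roimap, config)
    for s in series:
        call_death(s)
    flags = [apply_exclusions(s) for s in series]
    result = summarize_cytotoxicity(series, flags)
    return series, flags, result
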