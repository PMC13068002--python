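# Methods

## Occupancy model

Trap loading is modelled as independent Poisson capture per population:
`P(λ, k) = λ^k e^(−λ)/k!` with `λ = N_p/N_t` estimated from trapped cells
only (flow-through cells are not observable in an occupancy table). The joint
distribution is the product of the marginals; the empirical dual frequency is
likewise the product `f(k1)·f(k2)`, i.e. independence is assumed with no
covariance correction. Analytic tables aggregate `k ≥ max_k` (default 5) into
one tail bin so expected cohort counts conserve the trap total exactly.

Goodness of fit uses Pearson's chi-square against `Poisson(λ̂)` with sparse
bins (expected < 5) merged upward and `dof = bins − 2` because λ̂ is
estimated from the same data. Calibration on seeded Poisson draws gives the
nominal ~5% rejection rate at α = 0.05.

The λ design helper maximises (or achieves) a cohort probability using
closed-form cohort probabilities (e.g. singlet `λ1 e^(−λ1) λ2 e^(−λ2)`, whose
symmetric argmax is λ = 1 with value `e^(−2)`), a deterministic coarse grid,
and bounded golden-section/Nelder–Mead refinement — the objective is smooth
and at most 2-D, so no stochastic search is used. For "achieve" targets the
smaller root is returned (fewer cells for the same yield).

## Hydraulic network

The device is a binary bifurcation tree: one inlet channel, S uniform splits,
and four terminal traps per last-stage channel. Each segment is a rectangular
duct with resistance `12 µL/(w h³ (1 − 0.63 h/w))` (h ≤ w), each trap a
sub-channel in series with 2–3 parallel filter constrictions. Per-stage
segment lengths are not documented for the chip, so defaults halve the
61.44 mm array span per stage; because the whole network is then rescaled by
a single factor so that the empty-device aggregate resistance equals the
measured `1.48e13 Pa·s·m⁻³`, only the relative length profile matters.
Resistances use the fabricated channel height (~35 µm) rather than the 40 µm
design height; both are config fields.

Flows solve by nodal analysis (sparse conductance matrix, outlet grounded)
under either a fixed inlet pressure (pipette/hydrostatic mode) or a fixed
inlet flow (syringe-pump mode). A captured cell multiplies its trap's
resistance by `occupancy_multiplier` (default 10 per cell) — the platform
reports flow diversion qualitatively, not a blockage coefficient, so the
multiplier is a config-exposed model parameter. Under fixed pressure an
occupied trap's flow and filter shear drop and siblings gain; under fixed
flow the inlet pressure rises instead, which is why the pump boundary always
yields at least the pipette boundary's shear on occupied traps. Wall shear is
the rectangular-duct estimate `6 µQ/(w h²)`.

Gravity defaults to 9.80665 m/s²; a `LEGACY_GRAVITY = 10.0` constant
reproduces the device datasheet's `ρgh = 998 Pa` for ρ = 998 kg/m³ and
h = 0.10 m, which is not attainable with standard gravity (979 Pa). Units are
SI internally; µL/min appears only at I/O (1 m³/s = 6e10 µL/min).

## Loading simulator

Cells arrive one at a time (premixed lots interleaved by a seeded
permutation, sequential lots as blocks) and choose a branch at every junction
with probability proportional to the branch flow. Uncoupled mode uses equal
splits — equivalent to a uniform trap draw, vectorised accordingly — and
converges to `Binomial(N_p, 1/N_t) ≈ Poisson(λ)` occupancy. Coupled mode
maintains bottom-up equivalent conductances on the tree, which reproduces the
nodal solve's flow splits exactly for a tree topology at O(S) cost per
capture, and is re-evaluated after every capture. Any cell reaching a
non-full trap is captured with probability 1 (the filter is smaller than the
cell); a cell reaching a full trap (capacity default 6) is tallied as
overflow and removed rather than re-circulated or stacked upstream — a
modelling choice recorded in the result metadata. One root seed drives
everything; replicate streams are spawned deterministically.

## Synthetic data

The generator emulates the two imaging regimes so the pipeline is testable
without microscopy data.

*Time-lapse (default one frame per 2 h for 14 h).* Occupancy comes from an
explicit per-trap list, an occupancy table, loading rates, or a simulator
result. Targets in contact traps (≥1 effector and ≥1 target) die with a
per-cohort probability (defaults: 21.5% at 1:1, 12.6% at 1:2, 26.7% at 2:1 —
the platform's U87/NK92 study conditions); cells in single-population
control traps die only at the spontaneous baselines (1% effectors, 4.4%
targets). Death times are drawn from a discrete distribution on the frame
grid weighted toward 4–12 h. Cells render as Gaussian blobs
(diameter ≈ 14 µm, σ = d/4) at ≥13 µm slot spacing, 2 µm/px by default.
Channel semantics: live targets carry stable green (GFP) and blue (tracer);
from the death frame red (PI) steps on, blue persists (debris is retained by
the filters), and green decays exponentially (half-life default 4 h). Dead
effectors gain red only. Brightfield is a *synthetic proxy* — dim trap
outlines plus cell blobs — not a model of real phase contrast. Escapes move
out of the trap over two frames; divisions spawn an adjacent equal blob;
photobleaching is a per-frame multiplicative loss; background is Gaussian
per channel (mean 200, sd 20, 16-bit).

*Calcium (one sample per 10 s for 30 min).* Three labelled archetypes:
responders (1–3 gamma-shaped transients, amplitude 1.5–3× baseline, τ
40–90 s), flat non-responders, and the death signature (logistic step at
60–300 s to a sustained 3× plateau). The step is drawn after the 50 s F0
baseline window because a cell already compromised before imaging has no
observable baseline of its own (see pipeline note below).

What the generator does **not** emulate: optical PSFs, focus drift, uneven
illumination, segmentation-hostile clumping, brightfield morphology, or
correlated loading. Passing closed-loop tests therefore demonstrates the
pipeline's logic (geometry fitting, counting, colocalization calls,
exclusion accounting) — not robustness to real-microscopy artefacts.

## Image pipeline

Geometry: global rotation is estimated from the second moments of a robustly
thresholded (median + 6·MAD) foreground mask and corrected when ≥ 0.2° —
smaller tilts displace a trap band by less than its ROI height while
interpolation would smear 1 px structures, so they are left alone. The
per-trap grid uses the design pitch; its phase maximises the windowed
foreground mass under an N-tooth comb (robust to empty traps), and the pitch
is cross-checked against the dominant spatial frequency of the detrended
column profile (±10%).

Counting thresholds at background median + 6·MAD per ROI (Otsu replaces the
floor only when >30% of the ROI exceeds it), opens with a 1 px disk to
remove thin trap-wall structures, filters components by the 7–25 µm
cell-diameter window, and splits merged blobs by smoothed local maxima with
a 0.35 relative-height guard against noise bumps. Effectors are brightfield
objects remaining after subtraction of the (dilated) target-fluorescence
mask; the brightfield ROI is first flattened by sequential row/column median
subtraction to cancel the wall grid. Intensity traces are interior means
minus the ROI border-ring median.

Death calling is strictly dual-fluorescence: a target death is a tracer
component whose PI overlap reaches 0.5 (config-exposed); a PI component
without tracer is an effector death; GFP loss alone never calls a death.
Exclusions: division = a count above its frame-0 value for ≥2 consecutive
frames (persistence rejects flicker); escape = a sustained (or final-frame)
drop below frame-0 — deaths never lower counts because debris is retained;
plus preloaded-dead (PI at frame 0) and saturated-ROI flags. Retained +
excluded = assigned holds per cohort by construction. Cohort death fractions
are dead targets over targets in retained traps; controls report viability
as 100 − death%. Normalized endpoint intensity is per-trap endpoint/initial;
both absolute and relative intensity drops are exported because the original
"a.u." scaling is ambiguous.

Cohort comparison follows the platform's procedure: Shapiro gate at α = 0.05
(constant groups route nonparametric), then one-way ANOVA + Tukey HSD or
Kruskal–Wallis + Dunn's rank test (hand-implemented z statistics with Holm
adjustment; no installed package provides Dunn), with significance tiers
\*p<0.0332, \*\*p<0.0021, \*\*\*p<0.0002, \*\*\*\*p<0.0001.

## Calcium analysis

F0 is the median of the first five frames (the convention is not documented;
50 s is long enough to average noise and short enough to precede most
events). Baseline segments are linearly detrended (conservative bleaching
correction) before `scipy.signal.find_peaks` with prominence
max(0.2 F/F0, 2× baseline sd) — a sustained step has no return and yields no
transient. Classification: death signature when ≥50% of the window sits at
≥2× baseline with no return by the end; responder when ≥1 transient; else
non-responder. Death-signature traces are excluded from responder-fraction
denominators. When a batch is classified together, traces whose own F0
exceeds 1.5× the cohort-median F0 are re-anchored to the cohort baseline:
these are cells already compromised before imaging, whose self-normalization
would hide the plateau. Classification is invariant to uniform gain, and the
threshold defaults were chosen so the three generator archetypes separate at
the default SNR — no claim is made that they match any manual criteria.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as the smallest that
leave the statistical checks well-powered: the 32-trap (S = 3) array for
pipeline unit tests, 256 traps (S = 6) with the full 213-trap 1:1 cohort for
cytotoxicity recovery, 512 traps (S = 7) with 160 traps per control cohort
for viability, 200 replicates of the 1024-trap simulator, and 300-trace
calcium fixtures.

## Known limitations

- The hydraulic model is steady-state and lumped: no FEM, no transients, no
  cell deformation, no trap-to-trap diffusive crosstalk.
- The simulator routes cells instantaneously and independently; no size
  dispersity or cell–cell interactions.
- Within-trap cell identity uses component/peak association only; the
  pipeline is not a general tracker and multi-target traps share one ROI
  average.
- Synthetic brightfield is a stand-in; effector counting on real data would
  need a morphology-aware segmenter.
- The Poisson model ignores sub-Poisson deterministic pairing designs;
  no Bayesian occupancy inference is attempted.
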