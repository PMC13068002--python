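# celltrap

Statistics, simulation and image quantification for microfluidic trap-array
experiments that pair immune effector cells with tumour target cells at
stochastically generated effector-to-target (E:T) ratios.

The platform this package models is a bifurcated microchannel with
`N = 4·2^S` terminal traps (1024 for `S = 8` stages), loaded by hydrostatic
pressure from a pipette tip. Because cells arrive stochastically, the number
of cells of each population captured per trap is Poisson:

```
P(λ, k) = λ^k e^(−λ) / k!,        λ = N_p / N_t
```

and, with two independently loaded populations, the joint occupancy follows a
double Poisson `P(k1:k2) = P(k1)·P(k2)`. A single seeding step therefore
yields 1:1 singlet traps for cytotoxicity readout *and* matched on-chip
controls (effector-only, target-only, empty) whose proportions are tunable
through λ. The package implements:

- **`celltrap.occupancy`** — the Poisson/double-Poisson model, empirical
  estimators (`f(k) = n_t(k)/N_t`, `λ̂ = Σ k·n_t(k)/N_t`), the cohort
  taxonomy (empty / controls / 1:1 singlet / multiplet), chi-square
  goodness-of-fit with merged sparse bins, and a λ design helper.
- **`celltrap.hydraulics`** — a lumped Hagen–Poiseuille resistance network of
  the bifurcation tree (`Q = P/R`), calibrated to the measured aggregate
  device resistance `1.48e13 Pa·s·m⁻³`, solving flows, pressures and filter
  shear under fixed-pressure (pipette) or fixed-flow (pump) boundaries with
  occupancy-dependent flow diversion.
- **`celltrap.loading`** — a seeded Monte-Carlo simulator routing cells
  through the tree by instantaneous flow fractions (or uniformly when
  uncoupled), reproducing Poisson occupancy in the well-mixed limit.
- **`celltrap.synth`** — a ground-truthed generator of multi-channel
  time-lapse stacks (GFP targets with a stable blue tracer, PI death marker,
  brightfield-proxy effectors; death, division, escape, photobleaching) and
  of the three calcium-trace archetypes.
- **`celltrap.pipeline`** — the quantification pipeline: straighten/crop the
  stitched array, split it into per-trap ROIs, count cells, extract intensity
  traces, call target death strictly by tracer+PI colocalization, apply
  division/escape exclusion rules, and compare cohorts with the
  normality-gated ANOVA/Tukey or Kruskal–Wallis/Dunn procedure.
- **`celltrap.calcium`** — F/F0 normalization, transient detection, and the
  responder / non-responder / death-signature trace taxonomy.

## Worked example

Expected cohort yields at λ₁ = λ₂ = 0.5 on 1024 traps, and the hydrostatic
flow chain:

```python
from celltrap.occupancy import LoadingRate, expected_cohort_counts, cohort_totals
from celltrap.hydraulics import (TrapArrayDesign, hydrostatic_pressure,
                                 total_flow, ul_per_min, branch_flow,
                                 loading_time, LEGACY_GRAVITY,
                                 MEASURED_DEVICE_RESISTANCE)

print(cohort_totals(expected_cohort_counts(LoadingRate(0.5, 0.5), 1024)).round(1))
P = hydrostatic_pressure(998, LEGACY_GRAVITY, 0.10)
Q = ul_per_min(total_flow(P, MEASURED_DEVICE_RESISTANCE))
d = TrapArrayDesign(stages=8)
print(f"P = {P:.0f} Pa, Q = {Q:.2f} uL/min, "
      f"branch = {branch_flow(Q, d):.4f} uL/min, "
      f"10 uL loads in {loading_time(10, Q):.1f} min")
```

prints

```
cohort
effector_only_control    244.4
empty                    376.7
multiplet                 64.4
singlet_1to1              94.2
target_only_control      244.4
Name: expected, dtype: float64

P = 998 Pa, Q = 4.05 uL/min, branch = 0.0158 uL/min, 10 uL loads in 2.5 min
```

i.e. ~94 of 1024 traps hold exactly one cell of each type (the 9.2% double
Poisson singlet probability), controls come for free, and a 10 µL sample
loads in ~2–3 minutes under a 10 cm liquid column.

The same computations are scriptable from the shell:

```
celltrap design --lambda1 0.5 --lambda2 0.5 --traps 1024
celltrap flow --legacy-gravity --column-height 0.10
celltrap simulate --stages 8 --cells1 512 --cells2 512 --seed 7 --replicates 200
celltrap analyze --stack stack.tif --stages 8 --out results/
celltrap calcium --traces traces.csv --out ca/
```

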