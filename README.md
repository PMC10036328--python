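# woundrepair

Quantification of **single-cell wound repair dynamics** from fluorescence
time-lapse microscopy, built around the *Drosophila* syncytial-embryo
laser-wounding assay: after ablation the wound first expands, an
actomyosin ring assembles at the wound periphery (with a dimmer actin
halo outside it), and the ring translocates inward to close the breach.

The package is aimed at cell-biology labs quantifying this assay (or any
radially organized wound/closure process) who want the manual Fiji/Prism
workflow as reproducible, tested code — plus a synthetic movie generator
with exact ground truth to validate every estimator closed-loop.

## What it measures

Given a pixel-calibrated, timestamped stack *I(x, y, t)*:

- **Wound trajectory** — per-frame wound mask, area *A(t)* (μm²) and
  centroid, by automated sub-background segmentation (`segment_wound`) or
  from user-supplied masks (`accept_masks`).
- **Kinetics** (`dynamics`): fold expansion *E = A_max / A₀*; closure
  rate *R = (A(t_max) − A(t_half)) / (t_half − t_max)* in μm²/s, where
  *t_max* is the time of maximum area and *t_half* the first frame at
  ≤ 50% of the maximum; reporter **recruitment onset** = first of ≥ 2
  consecutive frames whose wound-edge annulus mean exceeds the far-field
  background by 2 SD.
- **Radial lineplots** (`profiles`): mean ± 95% CI intensity over 51
  diameter lines (default 301 px) through the wound center, per frame.
- **Ring morphometry** (`ring`): FWHM-delineated ring edges on the mean
  radial curve; width *W = (D_out − D_in)/2* from the edge Feret
  diameters; mean ring intensity *(I_out − I_in)/(S_out − S_in)* and its
  ratio to an unwounded reference (50 × 50-px center box).
- **Kymographs** (`kymo`): 5.3 × 94.9 μm ROI across the wound, one row
  per frame.
- **Cortical flow** (`piv`): windowed normalized-cross-correlation PIV
  with Gaussian sub-pixel refinement, e.g. actin flow from 60–90 s.
- **Knockdown efficiency** (`blot`): western-blot band signals normalized
  to a loading control, percent knockdown.
- **Statistics** (`stats`): per-condition mean ± SEM, Kruskal–Wallis +
  Dunn or Welch's t pairwise comparisons with significance stars.

The **synthetic generator** (`simulate`) renders the whole phenomenology
— expanding/contracting dark wound, Gaussian-cross-section ring + halo,
per-reporter onsets, premature ring disassembly, inward speckle flow,
Gaussian/Poisson noise — from a parametric config, and returns a manifest
with the exact per-frame truth. Presets `control`, `rac_inhibited`
(pan-Rac inhibition: no ring forms, slower closure, over-expansion) and
`scar_rnai` (disorganized ring, premature disassembly, faster closure)
encode the three published experimental conditions.

## Worked example

```python
from woundrepair import (preset, simulate_stack, segment_wound,
                         summarize_dynamics, measure_ring,
                         unwounded_reference_mean)

sim = simulate_stack(preset("control", seed=1))     # one synthetic embryo
traj = segment_wound(sim.stack)                     # wound area trajectory
s = summarize_dynamics(traj, sim.stack)             # E, R, t_max, onsets
ring = measure_ring(sim.stack, traj,
                    i_uw=unwounded_reference_mean(sim.unwounded[0]))

print(f"initial area      A0    = {s.a0:7.1f} um^2")
print(f"max area          A_max = {s.a_max:7.1f} um^2  at t_max = {s.t_max:.0f} s")
print(f"fold expansion    E     = {s.fold_expansion:7.3f}")
print(f"contraction rate  R     = {s.contraction_rate:7.3f} um^2/s  (t_half = {s.t_half:.0f} s)")
print(f"actin onset             = {s.onsets['actin']:.0f} s")
print(f"ring width (90 s)       = {ring.width:7.3f} um")
print(f"ring relative intensity = {ring.relative_intensity:7.3f}")
```

prints:

```
initial area      A0    =   252.9 um^2
max area          A_max =   439.8 um^2  at t_max = 90 s
fold expansion    E     =   1.739
contraction rate  R     =   7.115 um^2/s  (t_half = 150 s)
actin onset             = 60 s
ring width (90 s)       =   5.291 um
ring relative intensity =   2.459
```

i.e. the pipeline recovers this embryo's configured condition — 1.74-fold
expansion, 7.15 μm²/s closure, a 5.34-μm ring at 2.43× the unwounded
intensity, actin recruitment at 60 s — to within segmentation and noise
error. The same flows through the CLI:

```bash
woundrepair simulate --preset control --seed 1 --out out/
woundrepair dynamics --stack out/control_seed1.tif --out out/metrics
woundrepair run --simulate control --simulate scar_rnai --n 10 --seed 7 --out out/run
```

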