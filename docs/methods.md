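# Methods

This note documents the models, conventions and numerical choices behind
`woundrepair`: what the estimators compute, what the synthetic generator
emulates (and deliberately does not), and where the design was genuinely
open.

## The assay and its measured quantities

A laser wound in the cortex of a *Drosophila* syncytial embryo first
expands, then an actomyosin ring assembles at the wound periphery —
flanked by a broader, dimmer actin halo — and translocates inward until
the wound closes. The measured quantities are:

- **A(t)** — wound area per frame, μm². *A₀* is the first post-wound
  frame's area (the assay offers no other observable definition of
  "initial size"; the ablation target area is configurable separately).
- **Fold expansion** E = A_max / A₀ (dimensionless, ≥ 1).
- **Contraction (closure) rate** R = (A(t_max) − A(t_half)) /
  (t_half − t_max), μm²/s, reported positive. t_max is the earliest frame
  of maximum area; t_half the first later frame with A ≤ 0.5·A_max. The
  area curve's slope changes somewhere in the 50–35% band, so if
  A(t_half) < 0.35·A_max the estimate is flagged (`band_undershoot`)
  rather than re-anchored — the two-point formula is exact for a
  piecewise-linear trajectory regardless of which frame in the linear
  segment is hit.
- **Ring width** W = (D_out − D_in)/2 and **mean ring intensity**
  (I_out − I_in)/(S_out − S_in), where D/S/I are the Feret diameter, area
  and integrated intensity of the filled regions enclosed by the outer
  and inner ring edges, measured at the frame nearest 90 s post-wounding
  (ties → earlier frame). Relative intensity divides the ring mean by
  the mean of a 50 × 50-px box at the center of an unwounded reference
  frame, making it unit-free.
- **Recruitment onset** — first time a reporter is detectably enriched at
  the wound periphery (see below).

## Conventions chosen where the workflow was manual or unstated

The original measurements were made by hand in Fiji; an automated
pipeline needs explicit rules. Each rule below is a package convention,
stated so results are reproducible bit-for-bit:

**Segmentation.** The wound is the largest connected sub-background
component that overlaps the previous frame's mask (first frame: a seed
box, default the central 20% of the image; ties in overlap → larger
component). The per-frame threshold is an Otsu split of a σ = 1 px
Gaussian-smoothed copy restricted to pixels at or below the frame median:
restricting to the lower half keeps the split between wound interior and
background even when the bright ring and halo occupy a large fraction of
the field (an unrestricted bimodal split then lands between background
and ring and floods the mask). A candidate must additionally be genuinely
dark — mean < 60% of the above-threshold median — a scale-invariant check
that rejects the spurious split of an unwounded or fully closed frame.
Once no candidate passes, the wound is deemed closed and later frames
report area 0. Users who prefer manual masks inject them via
`accept_masks`, which bypasses every one of these rules.

**Radial lineplots.** 51 angles equally spaced over [0°, 180°]
*inclusive* (step 3.6°) — taken literally, accepting that 0° and 180°
sample the same line reversed. Each profile is a full diameter line
(default 301 px, odd) centered on the frame's wound centroid, sampled at
1-px spacing by bilinear interpolation; samples outside the image are
dropped, not clamped. The 95% CI is mean ± t₀.₉₇₅,₅₀·SD/√51 across
profiles. *Limitation:* within ~2 px/(angular step) ≈ 32 px of the
center, the 51 lines resample the same pixels, so the across-profile SD
(and hence the CI) underestimates the sampling error there; the CI is
calibrated only in the outer, independently sampled region, and the
coverage test asserts exactly that.

**Ring edge delineation (FWHM rule).** On the folded mean radial curve:
background = median of the outer 20% of valid radii; the ring peak is the
curve maximum; edges are the half-maximum crossings
(background + (peak − background)/2) nearest the peak on each side,
linearly interpolated to sub-pixel radius. For a Gaussian radial
cross-section this recovers the FWHM, so generator width and detected
width agree by construction. "No ring" is declared when the peak fails
*either* of two conditions: peak ≤ background + 3 × robust SD of the
outer region, or peak ≤ 1.1 × background. The second (contrast-floor)
condition is needed because the peak is a maximum over ~150 radial
positions and reaches 3σ by selection alone; a genuine ring is a multiple
of background contrast, not a noise excursion.

**Feret diameters** are maximum pairwise distances between boundary-pixel
centers (computed via the convex hull, identical to the brute-force O(n²)
result). Ring-edge regions are the filled discs enclosed by the
interpolated edge radii.

**Onset detection.** Per frame, the mean intensity of the annulus from
the wound edge to edge + 5 μm is compared with the far-field background
(pixels beyond twice the annulus outer radius; relaxed to the outermost
3% of pixels when the field of view is too small to contain that region).
Onset = timestamp of the first of ≥ 2 consecutive frames exceeding
background mean + 2 SD. On noiseless steps this is exact to the frame;
the 2-SD/2-frame rule is the package's convention.

**PIV.** 32-px windows, 50% overlap, zero-padded FFT cross-correlation of
mean-subtracted windows, normalized per lag by the window-overlap count —
this removes the loss-of-pairs bias that otherwise pulls peaks toward
zero displacement — with 3-point Gaussian sub-pixel refinement per axis.
Windows with vanishing texture variance or a peak-to-second-peak ratio
< 1.2 (second peak searched outside the 3 × 3 neighborhood) are invalid.
Displacements are searched to ± window/2. Interval fields average
per-pair velocities (μm/s) over the pairs in which each window is valid.

**Blot normalization.** normalized_target = kd_target ×
(control_loading / kd_loading); percent knockdown = 100 × (1 −
normalized_target / control_target), clipped to [0, 100] with a warning.
Displayed percentages round half-up through an intermediate one-decimal
step (85.4957 → 85.5 → 86), matching conventional densitometry reporting.

**Statistics.** Kruskal–Wallis omnibus with Dunn's rank z-tests
(tie-corrected) as the pairwise follow-up — raw p-values by default,
since the published tables report uncorrected pairwise values; Bonferroni
or Holm are selectable. Welch's t is the pairwise alternative. Stars:
*, **, ***, **** at 0.05, 0.01, 0.001, 0.0001.

## The synthetic generator

`simulate_stack` renders, per frame and channel:

1. a cortical background B (default 100 intensity units) carrying a
   static multiplicative speckle texture (Gaussian-filtered white noise,
   σ = 1.5 px, 10% contrast) advected radially **inward** at
   `flow_speed` (μm/s) — the source texture is oversized so inward flow
   always has material to draw from;
2. a dark wound disc of radius √(A(t)/π) (interior at 15% of background,
   1-px linear edge ramp), where A(t) is piecewise linear: A₀ →
   E·A₀ at t_max (default 90 s), then down at R μm²/s, floored at 0.
   The linear form is a modelling choice — only the fold and the rate are
   observable — and makes the two-point closure-rate estimator exact;
3. a ring annulus with Gaussian radial cross-section (FWHM =
   `ring_width_true`) centered one ring-width outside the wound edge,
   present from each reporter's onset time (step recruitment by default,
   optional linear ramp) and, if `disassembly_time` is set, decaying
   exponentially afterwards (τ = 60 s default; the real disassembly
   law is unknown);
4. a wider, dimmer halo annulus (FWHM 6 μm, 1.3× background peak, 2-μm
   gap outside the ring) — "less dense actin halo" at a modest contrast;
   the gap keeps the halo's tail from biasing the ring's outer FWHM
   crossing by more than ~2%;
5. additive Gaussian noise (default σ = 5% of background) and optional
   Poisson shot noise.

The ring peak amplitude is set analytically so that the *mean over the
FWHM band* equals `ring_rel_intensity_true` × background (the
area-weighted band mean of a unit-peak Gaussian is
erf(√ln 2)·√(2π)/(2√(2 ln 2)) ≈ 0.810 of peak, independent of ring
radius for a band symmetric about it) — so the FWHM detector and the
intensity formula recover the configured values without any shared code
path. The manifest records exact per-frame areas, center, ring radii,
onsets and all trajectory/flow parameters.

Geometry defaults: 256 × 256 px at 0.22 μm/px (the 301-px profile
diameter then spans ≈ 66 μm, covering wound + ring + halo); frames every
30 s to 15 min then every 60 s to 30 min, mirroring the acquisition
schedule; A₀ = π·9² ≈ 254.5 μm², reading the 18 × 18 μm circular
ablation target as an 18-μm-diameter disc. Wild-type reporter onsets:
actin 60 s, Rac1 60 s, Rac2 78 s, SCAR 33 s.

Preset parameters are the measured condition means: control
(E = 1.74, R = 7.15 μm²/s, ring 5.34 μm at 2.43×), `rac_inhibited`
(E = 2.59, R = 5.62, no ring or halo, reduced flow 0.02 μm/s) and
`scar_rnai` (E = 2.45, R = 9.12, ring 3.43 μm at 1.34×, disassembly from
150 s). Cortical flow speed is not reported anywhere; 0.05 μm/s (control)
was chosen once as a plausible cortical-flow magnitude that displaces
the texture ~7 px per 30-s interval — comfortably within the 32-px PIV
search range.

**What the generator does not emulate** — hence what closed-loop tests do
*not* establish about real data: 3-D stacks (the projection is modelled
directly), photobleaching, anisotropic or non-circular wounds, ring
anisotropy, nonlinear area trajectories, embryo curvature and
illumination gradients, and biologically realistic actomyosin mechanics.
Recovery of the configured parameters shows the estimators are correct
and unbiased under the stated forward model, not that segmentation or
edge delineation are robust to every real-world artifact.

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng(seed)`; identical
config + seed gives bit-identical stacks. Ensembles derive one
independent stream per embryo from (master seed, condition tag, index),
so growing an ensemble never reshuffles existing embryos. The validation
ensembles use 10 embryos × 256² px × 46 frames per condition — ensemble
means of every estimator sit within ~1% of the configured truth at the
default 5% noise, and a full three-condition run takes well under a
minute on one core. Shorter schedules (10 min of frames) are used in
unit tests where late frames carry no information; every preset has
closed by then.

## Known limitations

- The segmenter assumes one wound, darker than background, roughly
  central; multiple simultaneous wounds or bright-interior wounds are out
  of scope (use `accept_masks`).
- The CI of radial lineplots is not calibrated near the profile center
  (see above).
- Ring metrics assume a radially organized ring around the wound
  centroid; strongly anisotropic rings violate the folded-curve FWHM
  model (per-angle width is deliberately not offered).
- PIV reports apparent texture motion; intensity changes that are not
  advection (ring assembly, bleaching) can contaminate windows near the
  ring — invalid-window filtering mitigates but does not eliminate this.
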