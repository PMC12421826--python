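# Methods

## The measurement being modelled

A CMOS microelectrode array images a sample through per-pixel capacitance:
each 10 × 10 μm titanium-nitride electrode measures the dielectric
properties of the material directly above it while an AC excitation
(6.25 MHz, 15 mV pk-pk) is applied. Aqueous culture medium, rich in mobile
ions, reads a high capacitance; biomass (cells plus extracellular matrix)
has a lower permittivity and reads lower. Ionic screening limits how far
above an electrode material can still influence the reading, so the signal
saturates with sample thickness. The default geometry is a 256 × 512 grid
(131,072 pixels, 13.1 mm²) read through 8 multiplexed amplifier channels,
one full frame per 20 s. Images are indexed `(row, col)`, 0-based.

## Forward model

No closed-form capacitance equation is available for this electrode/sample
system, so the package adopts the simplest law exhibiting the three
behaviours that define the measurement — biomass deficit, monotone negative
thickness dependence, and saturation:

C(x, y) = c_med − Δc_s · (1 − exp(−t/λ)) + o_ch + ε

| parameter | meaning | default | rationale |
|---|---|---|---|
| `c_medium_fF` | medium capacitance | 100 fF | arbitrary scale anchor; real instruments report relative ranges |
| `delta_c_fF` | full-thickness deficit, per species | 40 fF | strong contrast regime; per-species values enable mixed-species scenes |
| `screening_depth_um` (λ) | ionic screening depth | 5 μm | puts the signal within e^(−16/5) ≈ 4 % of saturation at 16 μm, i.e. a plateau for thickness ≥ 16 μm |
| `noise_sd_fF` | per-pixel noise SD | 1 fF | offsets ≫ noise, so flat-field correction is visibly necessary |
| `channel_offsets_fF` | per-channel additive offsets | drawn once per run from N(0, 5 fF) | amplifier process variation |

The channel-to-pixel map defaults to 8 contiguous 64-column blocks (the
real interleaving is not public); it is pluggable on `SensorGeometry`.

## Synthetic fixtures and what they do not capture

- **Colony phantoms** — sums of random Gaussian bumps, clipped so a genuine
  zero-thickness background exists and rescaled to a 33.2 μm maximum (the
  observed range for confocal-validated biofilm samples). Smooth by
  construction; real colonies have sharper edges and internal texture.
- **Two-species phantoms** — two contiguous regions split by one smooth
  random boundary curve, each with its own mean thickness, spatial texture,
  and dielectric deficit. Every pixel carries biomass, so the label map
  partitions the grid.
- **Pellicle time-lapses** — the long (512) axis is depth below the
  liquid–air interface, depth 0 at the interface. Colonization starts after
  `lag_h` (24 h) and the colonized band expands at `growth_rate`
  (0.004 of the field per hour); each colonized depth slice spans the full
  short axis, as the sensor sees the film's cross-section. A colonized
  pixel carries an immediate 8 fF base deficit, a densification term that
  lowers the region mean at exactly `densify_rate` (0.05 fF/h), and a
  banded heterogeneity pattern standardized over the current region so the
  noiseless within-region SD equals `hetero_rate·(t − lag)` exactly
  (0.02 fF/h). Frames arrive every 10 min for 168 h (1,009 frames
  including t = 0). The generator produces no pre-lag contrast; a real
  pellicle may be faintly visible at constant area during lag.
- **Confocal stacks** — lateral oversampling 7× (voxel ≈ 1.43 μm), z-step
  1.514 μm, 100 slices by default. A voxel is biomass-bright when its
  centre height is ≤ the local thickness, so a noiseless stack's run-length
  thickness equals `round(t/z_step)·z_step` — consistent with a 0–33.2 μm
  sample discretizing into 22 nonzero levels. The sensor surface appears as
  one slice carrying a bright periodic electrode-reflection pattern
  (period = oversample px). No point-spread blurring, attenuation with
  depth, or stitching artifacts are modelled.

Passing tests therefore demonstrate the *pipeline's* correctness under
known ground truth, not robustness to every optical artifact of real
confocal data.

## Numerical and design choices

- **Offset estimation** uses per-channel *medians* (robust when biomass
  occupies part of a channel) centred by their *mean*, so estimates sum to
  zero — the global level is not identifiable from one frame and is
  preserved. When biomass covers a channel block entirely, in-image
  statistics are biased; the pipeline therefore prefers a blank reference
  frame (captured before sample loading) and otherwise masks to
  confocal-confirmed biomass-free pixels. Correction adds back the mean of
  the subtracted field, preserving the global mean exactly for any channel
  map.
- **Otsu degeneracy** ("is there a second mode at all?") is decided by
  Ashman's D between the two Otsu classes with threshold D < 5: a unimodal
  Gaussian split near its mode gives D ≈ 3.7 at any scale, while genuine
  two-class frames give D ≫ 5 after blurring at any class imbalance.
  Variance-ratio rules were rejected because Otsu applied to pure noise
  already "explains" ~64 % of variance, and ratio thresholds near 1 miss
  frames whose minority class is small.
- **Pellicle detrending** subtracts the frame's global median rather than a
  per-depth-slice median: colonized slices span the full short axis, so a
  per-slice baseline would subtract the pellicle signal itself. The global
  median delivers the needed property — exact invariance to the additive
  drift that media enrichment causes — which the tests assert. Once both
  classes exist, the threshold is seeded from the previous frame's class
  means, keeping segmentation stable as absolute levels drift.
- **Thickness** is run-length from the surface (contiguous occupied voxels
  starting at surface + 1), not topmost-occupied height: robust to detached
  debris floating above the film. A z-slice lying entirely inside biomass
  would defeat the per-slice Otsu threshold; colony phantoms always retain
  background in every slice, and a fixed `intensity_threshold` is available
  for samples that do not.
- **Plateau rule**: the curve is declared flat from the smallest level L
  such that every consecutive level-mean difference at ≥ L is below
  `epsilon_frac` (default 0.02) of the full mean range. The underlying
  plateau is a visual feature; this rule is the package's operational
  definition of it.
- **Windows** for time averaging are half-open, anchored at the first
  timestamp; empty windows are skipped and output timestamps are the means
  of the members'.
- **"16× upsampling"** counts total pixels: each axis grows 4×, mapping
  100 × 100 to 400 × 400.
- **Variance** is unbiased (n − 1) throughout; single-pixel regions report
  variance 0 with an `n_flag`.
- Segmentation defaults: blur σ = 2 px, boundary erosion 3 px, minimum
  hole 25 px, minimum component 16 px (the operations are standard; the
  sizes are package choices). Manual outlier omission is supported as a
  user-supplied exclusion mask only — no automatic air-pocket detection.

## Problem sizes

Property suites run on reduced grids chosen to exercise every code path at
interactive speed: 128 × 256 for calibration (26-slice confocal stack,
oversample 7 → 896 × 1792 lateral), 64 × 128 for segmentation and the
week-long pellicle scenario (1,009 frames, 1-h windows → 169 frames), and
the full 256 × 512 grid where the quantity is cheap (geometry worked
examples, permutation null at n = 131,072, offset recovery with
16,384 pixels/channel). Monte-Carlo statements use 100 seeds (offset
recovery, permutation shuffles) or 20 seeds (species segmentation).

## Known limitations

- The forward model is phenomenological: no electromagnetic field
  simulation, double-layer electrochemistry, or mutual-capacitance mode.
- Cross-modal alignment is crop + integer block-mean only; no sub-pixel
  warping.
- The pellicle segmenter is a documented, reproducible stand-in for
  interactive machine-learning segmentation of drifting time-lapses, not a
  replica of any trained classifier.
- Windowed media statistics inherit slight contamination from depth slices
  colonized mid-window, so "flat media variance" is assessed relative to
  the pellicle trend (the raw-cadence, ground-truth-labelled media variance
  slope is statistically indistinguishable from zero, |t| < 2).
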