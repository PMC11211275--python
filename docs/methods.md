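# Methods

Models, parameter choices and numerical details behind `fibriltrace`, and
the limits of what the synthetic generator can stand in for.

## 1. SERS preprocessing (`fibriltrace.sers`)

Pipeline (in order): shift-axis calibration → despike → smooth → baseline
subtraction → area normalization; replicate sets are preprocessed
individually and averaged sample-wise on their common axis.

**Model and assumptions.** Each replicate is `bands + polynomial baseline +
white noise + sparse cosmic-ray spikes`. The baseline varies slowly
compared with the Raman bands; spikes are single-bin, positive, and far
above the noise; the shift axis is a rigid translation off the true axis
(calibrated against the first-order silicon phonon line).

**Parameters** (`PreprocessConfig`):

| parameter | default | units | rationale |
|---|---|---|---|
| `si_reference` | 520.8 | cm⁻¹ | first-order Si phonon reference; calibration shifts the axis so a measured Si peak lands exactly here |
| `despike_window` | 5 | bins | median window; wider than one spike, narrower than any band (FWHM ≥ 12 cm⁻¹ at 1 cm⁻¹ steps) |
| `despike_z` | 8.0 | robust sd | only replaces bins whose deviation from the rolling median exceeds 8 MAD-based sd; band maxima stay untouched |
| `smooth_window`, `smooth_polyorder` | 11, 3 | bins, – | Savitzky–Golay; preserves cubic features exactly, so an 18 cm⁻¹ band loses < 1 % height while white noise drops > 2× |
| `baseline_degree` | 3 | – | matches the slow fluorescence background; fitted on the axis rescaled to [−1, 1] for conditioning |
| `baseline_exclusion` | (980–1120), (1330–1480), (1540–1800) | cm⁻¹ | windows masked from the baseline fit: aromatic ring modes, CH deformation, and the full amide I/II region. The amide window is deliberately wide (1540–1800) because pseudo-Voigt wings decay as 1/Δν² and bias a finite-degree polynomial fitted too close to the band |

**Numerical notes.** Despiking uses a rolling median and MAD; when the MAD
is zero (noise-free input) the spectrum passes through unchanged, making
the operation idempotent. Normalization divides by the trapezoidal area,
so the pipeline is invariant to detector gain.

## 2. Amide I deconvolution (`fibriltrace.amide`)

**Model.** Within the 1590–1720 cm⁻¹ window the spectrum is a sum of
unit-area pseudo-Voigt components `η·Lorentzian + (1−η)·Gaussian`, scaled
by their areas: three structure bands (α ≈ 1650, β ≈ 1670, coil ≈ 1680
cm⁻¹) plus an optional aromatic band near 1592 cm⁻¹, plus an optional
linear offset. Secondary-structure fractions are the structure-band areas
normalized to 100 % (aromatic and offset excluded). Fitting is multi-start
least squares (lmfit/Levenberg–Marquardt, default 7 starts with centers
jittered ± 3 cm⁻¹); components are relabeled by ascending fitted center so
labels are order-stable.

**The identifiability constraint.** The β and coil bands sit 10 cm⁻¹ apart
with 18 cm⁻¹ widths — separated by barely half a linewidth. With fully
independent shapes the area split is nearly degenerate: a narrow small
band plus a wide large one fits as well as the truth, and realistic noise
moves the β/coil split by far more than the bands' own separation. Since
all amide I sub-bands arise from the same backbone C=O stretching mode,
the default model ties the three structure bands to a **single line-shape
family** (one shared FWHM, one shared η; `share_fwhm=True`,
`share_eta=True`). A linear in-window offset (`fit_offset=True`) absorbs
the residual left under the band by the global polynomial baseline.
Setting all three flags to `False` recovers the fully free model, which
recovers exact parameters on noise-free input (residual RMS < 1e−6) but is
not robust at realistic noise.

**Parameters** (`AmideBandModel`): window (1590, 1720) cm⁻¹;
`center_bound` ± 8 cm⁻¹ (keeps overlapping components from swapping
roles); `fwhm_bounds` (5, 60) cm⁻¹; `initial_fwhm` 18 cm⁻¹ and
`initial_eta` 0.5 (canonical amide I sub-band shape).

## 3. AFM morphometry (`fibriltrace.afm`)

**Forward model.** An AFM image is the grayscale dilation of the true
surface by the probe: a spherical-cap tip of radius `R` (default 8 nm)
preserves heights but broadens every lateral feature. For a flat-topped
ridge of height `h` and width `w`, the image FWHM exceeds `w` by
`2·sqrt(h_eff·(2R − h_eff))` where `h_eff` is the height of the level at
which the width is read. Widths here are measured as the FWHM of
perpendicular profiles, i.e. at half the crest height, so the correction
uses `h_eff = h/2`. `correct_tip_broadening` clamps at zero with a
`DegenerateMeasurementWarning` when the correction exceeds the
measurement.

**Segmentation** (`segment_objects`): plane-levelling, light Gaussian
smoothing (σ = 1.5 px), then *hysteresis* thresholding — seeds at 5 robust
(MAD-based) sd of the smoothed image, grown down to 3 sd — and 8-connected
labelling with components < 4 px discarded. The two-level rule matters on
megapixel fields: among 10⁶ correlated-noise pixels a single 3 sd
threshold admits on the order of a hundred spurious blobs, while a single
5 sd threshold truncates the faint flanks of real objects; hysteresis
keeps exactly the real objects with their full footprints.

**Measurement** (`measure_object`): the half-max support is skeletonized
(with spur pruning); the object *length* is the longest geodesic path
through the skeleton (8-connected, Euclidean edge weights, double-sweep
Dijkstra) × pixel size. The path coordinates are smoothed with a 3-point
moving average before summing: a raw lattice path overestimates length by
the stair-step factor plus noise-induced wiggle (≈ +7 nm on an 85-nm
object at 2 nm/px), while the smoothed path tracks the true centerline
within ≈ 1 nm. *Height* is the mean crest height along the path interior
above the local substrate (median of the background in a margin crop).
*Width* is the mean FWHM of profiles perpendicular to the path (bilinear
sampling at px/4 steps), skipping the rounded end caps; the tip correction
above then yields `width_corrected`.

**Classification** (`classify_object`): aspect ratio (length/width) < 2 →
oligomer; elongated with crest height < 2 nm → protofibril; else fibril.
Thresholds sit in the wide empty margins between the populations
(protofibrils ≈ 0.5 nm tall, fibrils ≥ 4 nm). `network_coverage` is the
field-area fraction of the largest connected protofibril-class component.

## 4. ThT kinetics (`fibriltrace.tht`)

**Model.** Boltzmann sigmoid
`F(t) = F0 + (Fmax − F0)/(1 + exp(−k (t − t_half)))`. Phase boundaries are
the intersections of the tangent at `t_half` with the baseline and
plateau: `t_half ∓ 2/k`. Traces whose relative amplitude is < 20 % are
flagged non-aggregating (buffer controls) and not fitted. Control wells
are excluded from the sample-well mean but never subtracted from it.

## 5. Synthetic generator (`fibriltrace.synthgen`)

**What it emulates.** (a) Replicate SERS acquisitions: preset band tables
(aromatic Phe/Tyr lines at 1003/1032/1592 cm⁻¹; amide I structure bands at
1650/1670/1680 cm⁻¹ whose areas follow the timepoint's α/β/coil fractions,
all with the canonical 18 cm⁻¹ width and 50:50 Gauss/Lorentz shape —
a single line-shape family, which is also what makes the overlapping
decomposition identifiable), cubic baseline, Gaussian noise (sd 5 counts),
Poisson-placed cosmic-ray spikes. (b) AFM fields: protofibrils and fibrils
as random-walk flat-topped ridges with bounded curvature (mature fibrils
carry a sinusoidal twist modulation), oligomers as disks, optional
protofibril network clusters, on a substrate with Gaussian roughness
(0.2 nm RMS at 2 nm/px). (c) Plate reads: quintuplicate sigmoid wells with
2 % amplitude noise plus flat buffer controls.

**Analytic tip dilation.** The observed topograph is *not* produced by
grid-dilating the sampled truth — that double discretization erodes each
edge by up to half a pixel per side and biases FWHM low by ≈ 2 nm at
2 nm/px. Instead the dilated surface is evaluated analytically at pixel
centers from the continuum object geometry (plateau inside `w/2`,
spherical-cap flank out to `sqrt(min(h,R)·max(2R−h,R))`); because dilation
commutes with pointwise max, composing objects by max is exact. The
analytic surface provably dominates `dilate_with_tip` applied to the
sampled truth (tested as an invariant).

**What it does not emulate.** Tip wear/asymmetry and double-tip artifacts;
scanner drift, line noise and feedback overshoot; height-dependent SERS
enhancement, Raman shot noise (noise is additive Gaussian) or replicate-
to-replicate baseline drift; secondary nucleation kinetics (ThT is a
single global sigmoid); 3-D crossing of fibrils (overlaps compose by max,
i.e. co-planar crossings); finite-size convergence of the β/coil ratio to
its population value within one field.

**Seeding.** All derived seeds come from
`SeedSequence(entropy=seed, spawn_key=...)` reduced mod 2³¹, so every
stage (spectra, fit starts, field layout, substrate noise, plate noise)
gets an independent, reproducible stream.

## 6. Timeline integration (`fibriltrace.timeline`)

Seven canonical timepoints (0, 60, 120, 240, 480 min, 24 h, 48 h) with
preset structure fractions and morphology: coil-dominant at 0 min, an
α-helix maximum at 120 min, β and coil nearly equal at 120–240 min,
β-dominant from 480 min onward; fibrils appear at 240 min (4.2 nm tall)
and mature by 24 h (4.7 nm); protofibril networks exist between 60 and
480 min. The β transition is the earliest timepoint at which β *strictly*
exceeds both α and coil *and continues to do so at every later timepoint*.

## 7. Limitations

- **240-min near-tie.** At 240 min the preset β and coil fractions differ
  by only 2 points (37 vs 39 %), while the fitted β−coil difference has a
  seed-level sd ≈ 1.5 points even with the shared-shape model. Roughly one
  seed in ten therefore fits β marginally above coil at 240 min, which the
  strict-persistence rule then reports as a 240-min transition instead of
  480 min. This is inherent to detecting a strict ordering between two
  nearly equal fractions at realistic noise; it is a property of the
  detection rule, not a fitting error.
- The free (unshared) amide model is exact on noise-free data but should
  not be used at realistic noise for the reasons in §2.
- Length measurement assumes open curves; a closed-loop skeleton would be
  reported as its longest open geodesic.
- The tip correction assumes a spherical cap and a flat-topped cross
  section; real fibril cross sections are rounded, so corrected widths are
  conventional (FWHM-level) rather than literal footprint widths.
- `network_coverage` counts only the largest connected protofibril
  component, so fields with several comparable clusters under-report total
  network area.
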