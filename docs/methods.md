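# Methods

## Scope

`cavigap` quantifies ultrasound-and-microbubble (USMB) cavitation-induced
permeabilization of an endothelial monolayer grown in a microfluidic
vascular channel. It covers four linked pieces:

1. a **synthetic-image generator** producing junction-stained monolayer
   mosaics with ground-truth interendothelial gaps;
2. the **gap pipeline**: tile stitching, ROI-wise segmentation and
   geometry, per-condition statistics and the percent-change contrast;
3. a **coated-microbubble model**: Rayleigh–Plesset radial dynamics with
   a buckled/elastic/broken shell tension law;
4. **dose and design calculators**: pulse arithmetic, MI/TI safety
   indices, plane-wave intensity, channel/capillary hemodynamics and
   chamber volume.

## Synthetic monolayer and gaps

The generator emulates the statistical structure the analysis assumes —
not the optics of any particular microscope.

* **Cell mosaic.** Cell centres are dart-thrown with a minimum spacing of
  half the mean cell pitch; pixels are assigned to the nearest centre
  with the streamwise coordinate compressed by `cell_elongation`
  (default 1.6), giving an anisotropic Voronoi partition that mimics the
  flow-aligned, polygonal "cobblestone" morphology of a mature
  endothelium. Junctions are the region boundaries, dilated to
  `junction_width_px` (3 px) and rendered bright over a uniform
  background.
* **Gaps.** Gap count per channel is Poisson with mean
  `n_gaps_mean × effect_multiplier`; per-gap areas are log-normal,
  `ln A ~ N(ln 42 µm², 0.5²)`. Gaps are irregular ellipses (random
  orientation, axis ratio 0.45–1, a few percent axis jitter) centred on
  junction pixels — interendothelial by construction — and
  rejection-sampled with a 2 px clearance so two gaps can never merge
  into one 8-connected component. The truth table records the *rendered*
  pixel count of each gap, so segmentation is scored against what is in
  the image rather than the sampled target area.
* **Conditions.** `CTRL`, `US` and `USMB` share the per-seed cell mosaic
  and differ by count multipliers 1.0, 2.3 and 4.6, so the programmed
  total-area contrasts are +130 % and +360 % in expectation. Control
  channels draw Poisson(60) gaps. Intensities default to
  background 3000, junction 9000, gap 40000 (16-bit), with Gaussian read
  noise (SD 800) and Poisson shot noise (`var = I/scale`, scale 0.01),
  i.e. a gap-to-background SNR of roughly 18.
* **Tiles.** The field is cut into an overlapping grid (default 2×2,
  overlap ≥ 0.2) with integer placements recorded; noise is applied per
  tile. Reassembly at the true offsets reproduces the noiseless field
  exactly.
* **Randomness.** One master seed; every stage draws from a named
  substream (`SeedSequence([seed, hash(name)])`), so outputs are
  bit-reproducible and conditions are statistically independent.

What the generator does **not** model: illumination fields,
photobleaching, out-of-focus light, the 3-D channel walls, VE-cadherin
pattern classes, or dark-gap stains (the pipeline's `invert` flag covers
the latter). Passing tests therefore demonstrate correctness of the
measurement chain under a known object model, not segmentation
robustness on real stains. The distribution family of real gap areas is
unknown; log-normal is a generator choice.

The defaults above (including the 0.65 µm/px pixel size typical of a
20× CCD acquisition) were fixed when the generator was designed and are
exposed in `MonolayerSpec` / `ConditionSpec` rather than hard-coded.

## Gap pipeline

* **Stitching.** Translation-only registration: each tile is registered
  to its left neighbour (first column: top neighbour) by phase
  correlation on the nominal overlap strips, and placements are
  accumulated row-major from the top-left anchor. If the re-aligned
  overlap correlates below 0.5 the nominal grid offset is used and a
  warning is raised (featureless overlaps degrade the same way).
  Overlaps are blended by linear feathering (weights ramp from the tile
  border). Rotation and scaling are not modelled; microscope stages
  translate.
* **Equalization.** Per-ROI contrast normalisation. The default is a
  linear min–max stretch to the full 16-bit range. Classic histogram
  equalization is available (`method="hist"`), but it is deliberately
  not the default: rank-equalization flattens the ROI histogram, and on
  a flat histogram Otsu's criterion degenerates to a median split (for a
  uniform distribution the between-class mean separation is 1/2 at any
  cutoff, so the variance `t(1−t)/4` peaks at `t = 0.5`), which merges
  junction pixels into the gap blob. The linear stretch preserves the
  intensity separations Otsu needs. Both methods preserve pixel rank
  order; a constant ROI is returned unchanged with a warning.
* **Thresholding.** Pixels strictly above the cut-off are gap signal.
  The cut-off is per-ROI Otsu by default, or a fixed configured value.
  Degenerate single-level ROIs yield an empty mask plus a warning.
* **Blobs.** 8-connected components; specks under `min_blob_area_px`
  (default 4) are discarded. The gap is the component whose centroid is
  nearest the ROI centre (ties: larger area, then scan order), matching
  the framing assumption that each ROI was drawn around a single gap.
* **Geometry.** Area is the pixel count times the pixel area. Two
  perimeter conventions are provided and documented so shape factors are
  comparable:
  * `contour` (default): the marching-squares 0.5-level boundary with a
    3-point cyclic moving average that removes the staircase bias; a
    rasterised disc of radius 20 px measures within a few percent of
    `2πr` and its shape factor `4πA/P²` is ≈ 0.98.
  * `edge_count`: exposed pixel-edge count (the crack boundary); exact
    for axis-aligned rectangles (a 5×5 square gives 20) but it
    overestimates curved boundaries, capping the shape factor of any
    pixel set at `π/4 ≈ 0.785`.
* **Statistics.** Per-condition totals, counts and an area histogram
  (log-spaced, 12 bins over the observed range by default). The
  treatment effect is `100 × (A − A_ctrl)/A_ctrl` on total gap area.

### Numerical and degenerate-input behaviour

ROIs are clipped to the image; a fully outside ROI is an error naming
its id. ROIs with no surviving blob produce a null row (`found=False`)
and are counted. Binarization at a fixed cutoff is idempotent. Areas
scale exactly with the square of the pixel size, perimeters linearly,
and the shape factor is dimensionless — these are tested invariants.

## Coated-bubble model

The radial dynamics follow the Rayleigh–Plesset equation

    (p_B − p_L∞)/ρ_L = R R̈ + (3/2) Ṙ² + 4 µ_L Ṙ/(ρ_L R) + 2 σ(R)/(ρ_L R)

with the piecewise effective surface tension of a phospholipid shell:
zero below the buckling radius, elastic `χ(R²/R_b² − 1)` between
buckling and break-up, and the bare gas–water value `σ_water` once the
coating has ever broken (a latched, irreversible state). No radiation
damping term is included; the model is faithful to the incompressible
form above rather than physically complete at large Mach numbers —
driven collapses are therefore more violent than a compressible model
would predict, and trajectories that reach the collapse floor
(`R < R0/100` by default) are truncated and flagged rather than raised.

Closures the tension law needs but the dynamics do not fix:

* **Gas.** Polytropic, `p_B = p_B0 (R0/R)^{3κ}` with κ = 1.07 by default
  (near-isothermal heavy inert gas such as SF₆). κ is configurable in
  `[1, 5/3]`.
* **Initial internal pressure.** `p_B0 = p_ambient + 2σ(R0)/R0`, which
  makes `R0` an exact rest state — an undriven simulation stays at `R0`
  to solver tolerance.
* **Break-up radius.** Defaults to `R_b √(1 + σ_water/χ)`, the radius at
  which the elastic branch reaches `σ_water`, so σ(R) is continuous at
  break-up; an explicit override allows a discontinuous rupture.
* **Shell defaults.** χ = 0.55 N/m, σ_water = 0.072 N/m,
  `R_buckling = R0` are literature values for SonoVue-type lipid shells
  and should be replaced by agent-specific characterisation when
  available.
* **Drive.** `p_L∞(t) = p_ambient − PNP·sin(2πft)` inside a burst
  (first half-cycle is rarefaction; the phase is configurable), ambient
  between bursts.

**Integration.** `scipy.integrate.solve_ivp` with the Radau stiff
scheme, `rtol = 1e-8`, radius `atol = 1e-12 m`; the velocity component
uses `atol × f` (one radius tolerance per drive period) — a scalar
`1e-12` applied to Ṙ makes the error controller spin on equilibria.
Integration proceeds in segments: a break-up event terminates the
segment, latches the shell broken and restarts; a collapse event
truncates with a flag. Output is sampled at 50 points per drive cycle by
default. The Minnaert closed form
`f0 = (1/2πR0)√(3κ p_ambient/ρ_L)` is implemented only as an independent
linearization oracle for tests.

## Dose and hemodynamics calculators

All calculators are pure functions over SI-converted inputs:

* `PD = n_cycles/f`, `PRF = 1/T_rep`, `DC = PD·PRF`,
  `n_pulses = ⌊duration·PRF⌋`. For the 1 MHz / 500-cycle / 50 ms / 30 s
  protocol this gives 500 µs, 20 Hz, 1 % and 600 pulses. The duty cycle
  is always computed from PD·PRF rather than taken on trust.
* `MI = PNP[MPa]/√(f[MHz])`, `TI = W_p/W_deg`; classification: *safe*
  when both < 1, *above_FDA_limit* when MI > 1.9, else *caution*.
* Plane-wave intensity `I = p²/(2ρc)` with water defaults
  (ρ = 998 kg/m³, c = 1482 m/s): 0.4 MPa ↔ 5.4 W/cm², 0.72 MPa ↔
  17.5 W/cm².
* Rectangular-duct mean velocity `V = Q/S`; capillary Poiseuille
  relations `V = τR/(4µ)` and its inverse; wall shear by the slit
  closure `τ = 6µQ/(wh²)` or the exact duct Fourier series evaluated at
  the wide-wall midpoint (50 odd terms). For the 100×200 µm² channel at
  25 µL/min the slit value is 12.5 dyn/cm² and the exact midpoint value
  is ≈ 1.35× higher — side-wall drag raises the pressure gradient needed
  for the same flow, a fact verified in the tests against an independent
  finite-difference solve of the duct Poisson problem.

## Validation experiment and problem sizes

`cavigap.io.contrast_recovery_experiment` is the package's own
end-to-end check, also used by `scripts/acceptance.py`: per replicate
seed it builds one 1024² cell mosaic, draws CTRL/US/USMB gap
configurations on it, tiles each with noise, stitches, analyses the
truth ROIs and pools totals across seeds before taking percent change.
With 20–32 replicate seeds the programmed +130 %/+360 % contrasts are
recovered well within the Poisson/log-normal sampling error of the
generator itself (a few percent standard error on the pooled ratio),
and every gap of ≥ 50 rendered px² is re-measured exactly at the default
study conditions. These sizes keep the whole experiment within a couple
of minutes on one CPU while leaving ≥ 3σ margins on the recovery bands.

## Known limitations

* The pipeline assumes bright gaps after optional inversion; mixed or
  textured gap interiors are not modelled or tested.
* Stitching estimates integer translations only; sub-pixel stage error,
  rotation and illumination mismatch between tiles are out of scope.
* The bubble model has no radiation damping, no thermal damping beyond
  the polytropic exponent, and no bubble–bubble or bubble–wall
  interactions, so it should not be used to predict inertial-cavitation
  thresholds.
* TI is a plain power ratio; no tissue model is provided to derive
  `W_deg`.
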