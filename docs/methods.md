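# Methods

## Toolpath model

A scaffold is a square footprint of side `L` filled with parallel strands
and stacked `n_layers` times.  Layer `k` sits at `z = k·h` (no first-layer
squish offset; `h` is the only Z control).  Coordinates are absolute
millimetres; the footprint's lower-left corner is at a configurable bed
origin.

**Rectilinear pattern.**  Strand directions alternate per layer following
`angle_sequence` (default `(90, 0)`, the standard 0°/90° lay-down): 90°
layers run strands along Y spaced `d1` in X, 0° layers along X spaced `d2`
in Y.  Strand positions are `linspace(0, L, round(L/spacing)+1)`, i.e.
`round(L/spacing)+1` strands including both edges; when `L` is not an
integer multiple of the spacing the effective spacing is adjusted to span
the footprint exactly, as slicers do.  Strands are connected in
boustrophedon (serpentine) order; the short connecting links are extruded
by default (continuous deposition), with a `links="travel"` option.

**Triangular pattern.**  Rows of triangle waves with apex spacing `d1`
along X and amplitude `d2` along Y tile the square at row pitch `d2`
(adjusted to `L/round(L/d2)` so the field spans exactly `L`).  Rows are
visited serpentine-fashion.  Row-to-row links are *always travel moves*:
an extruded vertical link would break the invariant that every extruding
segment is a wave flank of slope `±d2/(d1/2)`, which is also what the
flank-slope tests assert.  When a wave ends exactly where the next row
begins the rows merge seamlessly with no link.

## Extrusion model

Deposited strands are assumed to have a stadium cross-section
`A = (w−h)·h + π·(h/2)²` (a rectangle plus the circle formed by the two
semicircular caps; degenerates to a circle at `w = h`).  The E-axis
increment of a segment of length `L_seg` follows from volume conservation,
`E = A·L_seg·4/(π·d²)·f`.

Two conventions exist for `d`.  Physically, E is the length of *filament*
advanced by the extruder, so `d` should be the 1.75 mm filament diameter.
The generator lineage this package models used the *nozzle* diameter
(0.40 mm) instead, which inflates E by `(1.75/0.40)² ≈ 19×`; on real
hardware that overshoot is absorbed into the firmware's steps-per-mm or an
equivalent recalibration, so relative behavior (and everything downstream
of ratios, such as the multiplier sweeps) is unaffected.  Both are
implemented behind `e_denominator`; the default is `"nozzle"` for fidelity
to the original routines, and the choice is recorded here rather than
silently "corrected".

Defaults: `w = 0.68 mm` (1.7× nozzle — the top of the recommended
1.05–1.7× window; wide first-layer strands aid adhesion, which is the
binding failure mode in the packaged experiments), `h = 0.20 mm`, `f = 1`.

**Effective strand width.**  Inverting the area equation at a given `f`
yields the width actually deposited: `w_eff = h + (f·A − π(h/2)²)/h` when
the scaled volume can still fill a stadium of height `h`.  Below
`f·A < π(h/2)²` no such width exists; the material detaches from the
layer-height constraint and the model reports the equivalent circular
diameter `2·√(f·A/π)`, flagged `fiber_regime`.  With the defaults the
boundary sits at `f ≈ 0.247`; at `f = 0.20` the equivalent diameter is
~180 µm.  This is a volumetric bound, not a drawing model: actual fibers
form thinner than this because the fast-moving nozzle stretches the
under-fed melt, so the flag marks *candidacy* for fiber formation, not a
predicted fiber diameter.

## G-code dialect

`M140/M104` set bed and nozzle, `M190/M109` wait on each, `G28` home,
`G90` absolute XYZ, `M82` absolute E, `G92 E0` zero, `G1` motion,
`M106/M107` fan, `M84` release.  E is absolute and cumulative; there is no
retraction.  Formatting is canonical — X/Y/Z 3 decimals, E 5 decimals,
F integer mm/min, F and Z words only on change — which makes
`emit(parse(text))` byte-identical and `parse(emit(tp))` exact up to word
quantization (5·10⁻⁴ mm on vertices, 10⁻⁵ mm on E).  Layer 1 moves carry
`first_layer_speed`; the fan command is placed at the start of layer
`fan_from_layer` (default 1: one fan state per print).  Parsing counts
layers at Z increases, so no-Z-raise passes stay on their base layer.

## Experiment matrices

The packaged table (`data/experiments.csv`) is the source of truth for the
35 experiments: 4 multiplier (F), 8 speed (V), 13 fan (T), 9 surface-pass
(P) and 1 diagonal-pass (D) rows.  Conventions:

* first-layer speed is 600 mm/min (10 mm/s) for every experiment;
* F-matrix prints run at 600 mm/min with the fan off (the base model);
* pass experiments print 3 base layers at `f = 1.00`, 600 mm/min, fan
  PWM 255, then deposit pass strands on the last layer *without raising
  Z*, at the row's pass multiplier and speed.  Parallel passes re-run the
  strand-along-Y field spaced `d1`; diagonal passes run at 45° with
  perpendicular spacing `d1` (the pass-line spacing is not dimensioned in
  the source material; `d1` keeps the pass density comparable);
* rows V8B, T12B and T13B are recorded but flagged: their first layer
  never adhered (too little polymer), so the default sweep skips them —
  32 G-code files from 35 rows;
* three fan rows carry internally inconsistent printed percentage
  annotations (e.g. "255 (19.6%)"); the numeric PWM column is taken as
  authoritative and the annotations kept verbatim in `pwm_note`.

## Printability rules

R1 layer height ≤ 0.8·d_nozzle (error), R2 width in [1.05, 1.7]·d_nozzle
(warning), R3 speed ≥ 100 mm/s instability (warning — the threshold is
inclusive so the 6000 mm/min = 100.0 mm/s sweep ceiling triggers it),
R4 first-layer speed > 25 mm/s adhesion (warning), R5 fan PWM in 0..255
(error), R6 temperatures in the material window (warning; PCL: nozzle
130–170 °C, bed 30–45 °C, overridable per material).  Errors mark
physically meaningless output, warnings mark quality risks.  The audit
recomputes R1/R3/R5 from parsed G-code and derives per-segment implied
multipliers from the E words, so a file can be checked without its
generating configuration.

## Fiber metrology

**Calibration** averages `n` repeated ruler measurements: each
`(pixels, known µm)` pair gives a ratio, and the scale is their mean with
sample SD (n−1).  A single measurement is allowed but flagged, with SD
reported as 0.

**Automated measurement** (designed to be testable, unlike the manual
ImageJ workflow it replaces): Otsu threshold → skeletonize the foreground
→ local width at skeleton pixels is `2·EDT − 1` px (EDT = Euclidean
distance transform; the −1 accounts for edges lying half a pixel beyond
the outermost foreground centres) → skeleton pixels at or above the
fiber/strand cutoff (default 150 µm — between the tens-of-µm fiber scale
and the hundreds-of-µm strand scale) are discarded, and the remaining thin
skeleton splits into per-fiber components at strand junctions → at up to
40 pixels per component (3 trimmed from each end, tangent from a local
PCA window) a perpendicular transect measures the foreground run length,
with the inside/outside edge refined by bisection to ~10⁻³ px → the
per-fiber diameter is the median transect, kept only if at least 3 valid
transects exist and the median is below the cutoff (this also rejects the
spurious short skeleton branches that medial axes grow at strand corners).
Run-length transects are exact for rasterized straight fibers regardless
of skeleton centring, so noise-free recovery is exact to pixel
quantization; the procedure is 90°-rotation invariant because transects
follow the local structure orientation.  Manual point-pair measurement is
exposed via `transects=`.

Reports use the sample SD (n−1) and the `mean ± S.D.` convention.

**Synthetic micrographs** emulate a digital-microscope view of a strand
lattice: strand bands at the `d1`/`d2` pitches (default the reference
scaffold, 1.0/2.5 mm) of width 400 µm, fibers spanning the macropores
horizontally or vertically (alternating per pore), additive Gaussian
sensor noise (SD 0.03 on the 0–1 intensity scale) and 8-bit quantization.
Fibers are assigned to pores proportionally to the span available, evenly
spaced; widths are rasterized to the nearest achievable pixel band (the
ground-truth table records both requested and rasterized width) and
sub-pixel widths are rejected.  What this does **not** emulate: uneven
illumination, out-of-focus blur, fiber curvature and sagging, lumps and
junction menisci, and intensity texture of real PCL — so passing tests
demonstrate the *measurement machinery* is correct and unbiased on ideal
straight fibers, not that real-micrograph segmentation is solved.

## Problem sizes and numerical choices

The test-suite and acceptance runs use the reference 20 mm scaffold
(119-segment toolpath), 100-path fuzz batches for volume conservation and
round-trip checks, and one 1200×2700 px micrograph with 50 fibers at
2 µm/px for the closed loop — sizes chosen so a full run stays in seconds
while keeping every check statistically meaningful.  Volume conservation
is asserted at 10⁻⁹ relative (pure floating-point algebra), multiplier
linearity at 10⁻¹² relative, G-code round-trips at the quantization bound.
The closed-loop criterion (sample mean within 2 standard errors of
48 µm, SD within 25 % of 12 µm) is dominated by n = 50 sampling
variation, not measurement error: measured means track the rendered
ground-truth sample to ~0.1 µm.

## Known limitations

* The extrusion model is purely volumetric: no melt rheology, die swell,
  pressure advance or drawing dynamics, so fiber diameters cannot be
  predicted, only the under-extrusion regime flagged.
* The triangular pattern's absolute dimensions are a concretization
  (triangle wave with apex spacing `d1`, amplitude `d2`); other readings
  of the same sketch are possible.
* `parse` handles only the emitted dialect plus opaque pass-through of
  unknown commands; arcs, relative E and firmware extensions are out of
  scope.
* Fiber measurement assumes roughly straight, non-overlapping fibers;
  touching or strongly curved fibers will merge or fragment components.
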