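# Methods

## The analysis chain

`shadowcell` analyzes 8-bit grayscale shadow images of cells recorded by a
lens-free imager (LED + pinhole illumination, bare CMOS sensor). The chain
conceptually duplicates the photographed image: all pixel classification
lives in a separate label plane (sentinels 96 candidate / 175 cluster / 60
center / 255 background), while contrast measurements read the untouched
original. A raw pixel may legitimately equal a sentinel value, which is why
sentinels never overwrite intensities; debug exports render the label plane
with the literal sentinel values for visual inspection.

### Adaptive binarization

The image is partitioned into a 4×4 grid (16 regions; remainder rows/columns
are absorbed by the last tile so the partition is always exactly 4×4). Each
region's *determination value* is its mean intensity minus the **gray
offset**, an empirical per-cell-line constant in intensity units, clamped to
[0, 255]. Pixels *strictly below* the determination value become candidates;
equality goes to background (the conservative choice — fewer false
candidates). Local per-tile thresholds are used rather than one global
value: the tiling only has a purpose if it compensates the slowly varying
LED illumination across the sensor. Cells cast darker-than-background
shadows, so candidates are low-intensity pixels, and the offset doubles as
the debris filter: anything whose dip is shallower than the offset never
enters clustering.

### Clustering and size rules

Candidates are grown by repeatedly centering a 3×3 window on every newly
absorbed candidate pixel until no window holds a fresh one. That procedure
is exactly the closure of 8-connectivity, so each cluster is one
8-connected component of the candidate mask — the test suite enforces this
equivalence against an independent connected-component labeler on random
fixtures. The scan starts at the top-left pixel; clusters are therefore
reported in raster order of their seed, which fixes the detection order
deterministically.

Size rules on the grown cluster's bounding box:

| bbox                                   | call    | yield |
|----------------------------------------|---------|-------|
| ≤ 20×20 px                             | singlet | 1     |
| ≤ 20×40 px or ≤ 40×20 px (else)        | doublet | 2     |
| anything larger                        | noise   | 0     |

The doublet rule is applied symmetrically in orientation (attached cell
pairs have no preferred axis). Only box dimensions are tested; no fill-ratio
criterion is applied. Cell clumps and islands need no extra rule — their
merged footprint exceeds 20×20 px and falls under noise.

Center placement: a singlet's center is the floor midpoint of its box (ties
toward top-left). A doublet receives two overlapping 20-px boxes tiled along
the long axis of length L, with centers at long-axis offsets ⌊L/4⌋ and
⌊3L/4⌋ — the midpoints of the two half-boxes — and the floor midpoint on the
cross axis. Border clusters are kept (bounding boxes are clipped to the
image; edge-touching clusters get no special treatment).

### PPD viability

For each detected center, the peak-to-peak distance (PPD) is max − min
intensity over an 11×11 window centered on it, computed on the raw image.
Windows at the border are clipped, not padded — padding would fabricate
intensities into the extrema. A cell is DEAD iff PPD ≥ the **viability
constant** (ties dead; dead cells have the higher contrast, up to 3.54×
that of live cells, because a ruptured, flattened cell attenuates the light
over a shorter internal path). The window is centered on the marked center,
not re-centered on the local extremum. Like the gray offset, the viability
constant is empirical per cell line and has no universal default;
`calibrate_ppd_threshold` (midpoint of the class-mean PPDs on a labeled
sample) is a convenience for synthetic or pre-labeled data only.

### Concentration and summary statistics

* Hemocytometer convention: cells/mL = mean grid count × 10,000 × dilution.
* Area–volume convention: cells/mL = count / (FOV area [mm²] × chamber
  depth [mm]) × 1000 × dilution. The chamber depth is a required geometry
  input; 0.1 mm (a typical counting-chamber depth) is the illustrative
  default, not a device constant.
* Viability % defaults to (total − dead)/total × 100, which is bounded in
  [0, 100] and consistent with "viability approached 50%" usage. The
  literal form (live − dead)/live × 100 is available as mode
  `"as_printed"`; it can be negative and is kept only for fidelity with
  reports using that form.
* ER = (Σx_ref − Σx_test)/Σx_ref × 100 over paired concentration series;
  CV = sample SD (n−1 denominator)/mean × 100 over replicates. Both are
  scale-invariant, which the property tests exercise.

## The synthetic scene generator

The generator emulates what the algorithm consumes, not the underlying
optics. Each object is a radially symmetric parametric profile: a flat-ish
super-Gaussian central dark dip (exponent 4) plus a Gaussian first-order
bright ring at 0.35× the object diameter with relative height 0.35. The
rendered patch is rescaled so its max − min equals the requested amplitude
within quantization (±1 count). This is deliberately *not* a Fresnel
propagation model — the analysis only reads contrast and footprint size, so
a controlled profile keeps generation deterministic and desk-fast; the
polarity (dark center, bright ring) is a convention, as real polarity varies
with the cell–sensor distance.

The dip core radius is `min(0.23 × diameter, 3.5 px)`. The cap mirrors how
the zero-order peak width of a contact-mode shadow is governed by the source
point-spread rather than by cell size, and it has two structural
consequences: every single cell's binarized footprint stays inside the
20-px singlet window across the whole 5–80 µm diameter range, and the full
dip contrast always fits the 11×11 viability window. Without the cap, an
80 µm cell's flat dark core would both overflow the singlet rule and look
nearly uniform to the PPD window.

Object classes:

* **live / dead cells** — diameter uniform in 5–80 µm (converted to px via
  the 2.2 µm pixel pitch), amplitude = live amplitude × U(0.85, 1.0), dead
  additionally × 3.54 (the design contrast separation);
* **debris** — 2–4 px specks at 0.25× live amplitude, below the suggested
  gray offset, so binarization rejects them (as intended by the
  determination value);
* **clumps** — diagonal chains of overlapping dip-only sub-patterns
  spanning 32–44 px, exceeding 20 px on both axes so the noise rule always
  rejects them. Sub-patterns carry no individual rings (a dense mass does
  not resolve per-cell rings; rings would also pinch off the chain ends
  into spurious singlets).

Placement is rejection sampling with non-overlapping footprints separated by
≥ 3 px (bounded retries; exceeding them raises a capacity error reporting
the achieved density). Zero-mean Gaussian sensor noise (default sd 5) is
added last, then the field is clipped and quantized. All randomness flows
from one `numpy` generator per scene, so a config + seed reproduces a scene
byte-identically.

Default conditions: background 200 counts, live amplitude 55 (keeps the
3.54× dead ring just inside the 8-bit range on a 200 background), full
frame 1944×2592 at 2.2 µm pitch; tests and benchmarks use 512×512 crops for
desk-scale runtime (the rules are purely local, so crops exercise the same
behavior).

Threshold helpers tied to the generator: `suggest_gray_offset` = 0.45× live
amplitude (≈60 % of the live dip depth of 0.74× amplitude, and ≥4.5 sensor
noise sd at the benchmark noise level, keeping stray-pixel false positives
to ≲1 per 5-Mpx-equivalent frame) and `suggest_ppd_threshold` =
0.74 × (1 + 3.54)/2 × live amplitude, the midpoint of the worst-case live
and dead dip depths (worst case = the ring truncated out of the 11×11
window for large cells). These describe the synthetic conditions only; real
cell lines need empirically established constants.

### Dilution series

`generate_dilution_series` emulates a serial-dilution counting experiment:
the expected object count per scene is concentration × FOV area [mm²] ×
chamber depth [mm] / 1000. By default the realized count is the *rounded
expectation* and replicate variability comes from placement and sensor noise
alone: at the scaled-down 512×512 FOV the Poisson aliquot noise (λ ≈ 25 at
the lowest level) would dominate the regression scatter and obscure the
counting linearity the series is meant to probe, whereas at the full sensor
FOV the distinction is immaterial. `count_mode="poisson"` restores sampled
counts for studies of that variability. Per-scene seeds derive
deterministically from the master seed. The benchmark series uses 10 µm
particles at 5 levels spanning 2×10⁵–1.6×10⁶ cells/mL × 3 replicates, and
the pipeline's counts regress on nominal concentration with R² ≥ 0.995.

## What the synthetic tests do and do not show

Passing recovery tests (100 % on clean well-separated scenes; ≥95 %
recall/precision at noise sd = live amplitude/10) demonstrates that the
implementation applies the stated rules exactly and that the stages compose
correctly. They do **not** validate performance on real captures: real
shadow patterns vary with z-distance and cell morphology, touching cells
occur at geometries the doublet rule only approximates, illumination
gradients may exceed what 16 tiles flatten, and real per-cell-line constants
must be measured, not derived. The improvement-ratio utilities operate on
published per-instrument averages and check only the arithmetic, not the
underlying measurements.

## Numerical choices and edge cases

* Tie-breaks: pixel == determination value → background; PPD == viability
  constant → dead; center midpoints floor toward top-left.
* 16-bit inputs are rejected unless explicitly downscaled (value → round
  half up of v/257), because the sentinel thresholds are defined on the
  8-bit scale. Multi-channel inputs reduce by channel mean, rounded half up.
* Degenerate inputs: an empty candidate plane yields an empty cluster list;
  zero detected cells yields viability `None` (undefined) rather than a
  number; CV requires n ≥ 2 and mean > 0; ER requires a nonzero reference
  sum.
* Determinism: identical image + config give identical results; the CLI and
  library share one code path.

## Known limitations

* The doublet split is geometric (quarter points of the long axis); no
  intensity-based refinement of the two centers is attempted, and clusters
  of ≥3 attached cells are all rejected as noise rather than split.
* The synthetic renderer's amplitude/footprint model is parametric; it
  cannot answer questions about wavelength, z-distance or refractive
  effects.
* Size distributions are reported as bounding-box diagonals of the
  *candidate core*, which saturates for large cells under the point-spread
  cap; they rank sizes but are not calibrated µm measurements.
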