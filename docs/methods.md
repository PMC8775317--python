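# Methods

## The measures

All quantities derive from the histogram of digital numbers (DNs) of one
pixel set — an entire band, the pixels overlapping one polygon region of
interest (ROI), or one k×k moving window. Probabilities are plug-in relative
frequencies `count/total` with no smoothing; no spatial information enters
any measure (they are permutation-invariant functions of the DN multiset).

For a pixel set with N distinct DNs and probabilities p₁…p_N:

| quantity | definition | range | units |
|---|---|---|---|
| system extension | N = number of distinct DNs | ≥ 1 | states |
| maximum entropy | Hmax = log₂ N (default) | ≥ 0 | bits |
| Shannon entropy | He = −Σ pᵢ log₂ pᵢ | [0, Hmax] | bits |
| variability | V = He/Hmax | [0, 1] | — |
| disequilibrium | D = Σ (pᵢ − 1/N)² | [0, 1) | — |
| SDL | V·(1 − V) | [0, 0.25] | — |
| LMC | V·D | [0, 1) | — |

Only *present* DNs enter any sum: absent values lie outside the system
extension, so they contribute nothing to He or D. This matters for D, whose
uniform reference is 1/N over the occupied states, not over the full 0–255
alphabet.

**Hmax convention.** Two normalizations are exposed through `hmax_mode`.
The default, `"log2"`, takes Hmax = log₂ N, under which V spans exactly
[0, 1] (V = 1 iff equiprobable) and the SDL and LMC extremes below hold.
The alternative `"literal"` takes Hmax = N itself, for comparison with
legacy scripts that normalized by the extension; under it V no longer
reaches 1 and the analytic extremes do not apply. All defaults, tests and
shipped numbers use `"log2"`.

**N = 1 convention.** A constant pixel set has He = Hmax = 0, making V a
0/0 form. V is defined as 0 there: a single-DN patch is the paradigm of
order, so V, D, SDL and LMC are all exactly 0.

**Analytic extremes.** SDL = V(1−V) has maximum 0.25 at V = 0.5 and is 0 at
V ∈ {0, 1}. LMC = V·D is 0 at both extremes (V = 0, and D = 0 when
equiprobable); over two-state distributions its maximum is 0.15291 at
p ≈ 0.8776, i.e. 0.15 to two decimals. LMC is *not* globally bounded by the
two-state maximum — skewed histograms with larger N can exceed it (e.g.
≈ 0.23 for a strongly dominated 11-state distribution) — so the package
asserts only the provable bounds 0 ≤ LMC < 1.

## Per-ROI analysis

For each (band, ROI) pair the pixels overlapping the polygon are selected,
nodata values are removed first, then descriptive statistics and the
metrics are computed and emitted as one row of a band-major results table
(columns `roi_id,band,count,min,max,mean,sd,N,Hmax,He,He_Hmax,D,SDL,LMC`).

- **Overlap rule.** Default `"center"`: a pixel belongs to the ROI when its
  center lies inside the polygon; a center exactly on the boundary is
  included (point-intersects semantics — deterministic, and pixels are never
  double-counted across polygons that do not share boundary-crossing
  centers). Option `"all_touched"`: any pixel whose square cell intersects
  the polygon. The center rule is the standard rasterization convention;
  neither rule is claimed to reproduce any particular legacy tool.
- **Standard deviation** is the population form (divide by n): the pixel set
  is the complete population of the ROI, not a sample.
- **Empty ROIs** (no intersecting or only-nodata pixels) produce a flagged
  row with count 0 and NaN statistics rather than aborting the run.
- Coordinates: 0-based row-major pixel indices; map placement through a
  north-up affine transform (rotation/shear is out of scope); polygons in
  map coordinates; a declared EPSG mismatch between raster and ROI layer is
  an error, not a silent reprojection.
- Band labels default to "1"…"k" and can be remapped so outputs mirror a
  sensor's band numbering.

A *complexity signature* is one metric's column for one ROI read across
bands in band order — the cross-band profile used to compare land-use types.

## Moving-window mapping

A k×k kernel (k odd, ≥ 3, even sizes rejected) slides over one band; the
metric of each window's histogram is written to the window's central pixel
of a float32 output raster.

- **Border policy:** no padding. The (k−1)/2-pixel margin is invalid
  (sentinel −9999, declared as nodata in the file): padding would fabricate
  DNs and bias N.
- **Nodata:** excluded from the window histogram; a window remains valid
  with ≥ 1 valid pixel (a single valid pixel gives N = 1, metric 0); an
  all-nodata window is invalid.
- The implementation contract is the naive per-window recomputation; the
  tests compare every interior pixel against an independent brute-force
  evaluation.

On a boundary between two homogeneous patches the windows that straddle the
edge — exactly k−1 center positions — score positive SDL/LMC while both
interiors score 0, so maps delineate patch limits with a line that widens
as k grows.

## Raster and vector formats

GeoTIFFs are read and written through `tifffile`, with the georeferencing
written directly as GeoTIFF tags (ModelPixelScale, ModelTiepoint, a minimal
GeoKey directory carrying the EPSG code) plus the GDAL ASCII nodata tag, so
outputs open in GDAL/QGIS/rasterio. Only north-up transforms are supported.
ROI layers are polygon GeoJSON; the identifier attribute is chosen by name,
identifiers must be unique, and invalid geometries are repaired with
`make_valid` on load.

## Synthetic scenes

The generator emulates a land-use mosaic with three analytically pinned
regimes, so tests have closed-form expectations:

- **constant patches** — the ordered extreme (all metrics 0);
- **equiprobable patches** — n DNs each exactly `pixels/n` times
  (divisibility is enforced), so V = 1 and D = 0 hold *exactly*;
- **mixture strips** — exact DN proportions (each proportion must allocate
  a whole pixel count), emulating transition areas; the default canonical
  scene runs the strip from a 90/10 mix (V ≈ 0.469, LMC ≈ 0.150) in band 1
  to 50/50 (V = 1, SDL = 0) in band 4, giving each ROI a band-dependent
  signature.

The canonical scene is three 20×20 patches (400 pixels each) side by side
across 4 bands, on a 20 m UTM grid — small enough that every test recomputes
its expectations by brute force in milliseconds while still exercising every
code path. Patches are exact-count shuffled multisets, not i.i.d. draws:
expected metrics are deterministic closed forms, never stochastic. All
shuffling uses numpy's seeded PCG64 generator; a scene is bit-reproducible
from its seed. DNs stay in 0–255, mimicking 8-bit sensor quantization.

What the generator does *not* emulate: radiometric noise, spatial
autocorrelation (no variograms or Gaussian fields), atmospheric effects, or
realistic inter-band correlation. Passing tests therefore demonstrate the
correctness of the measures and of the extraction/mapping machinery on known
distributions, not the ecological behavior of the measures on real scenes.

## Numerical choices

- Base-2 logarithms throughout; entropies in bits.
- Internal consistency checks and test comparisons use 1e-9 absolute
  tolerance; values persisted in float32 maps are compared at 1e-6.
- He is clipped to Hmax before division (guarding summation round-off), and
  V to [0, 1].
- CSV floats are written with 12 significant digits, which round-trips well
  below the 1e-9 comparison tolerance.
- The acceptance script's grid searches use step 1e-6 over the unit
  interval; the SDL peak is exact on that grid (0.5 is a grid point) and the
  two-state LMC peak is accurate to far better than the two decimals at
  which it is reported.

## Known limitations

- Strictly per-band: DNs are never pooled across bands into one histogram
  (per-band tables and maps are the intended product).
- No on-the-fly reprojection, rotated transforms, category-I/II entropy
  variants, Rényi/Tsallis families, or spatially explicit (co-occurrence)
  entropies.
- The moving-window mapper is a straightforward per-window recomputation;
  very large scenes would want tiling or incremental histogram updates,
  which are out of scope here.
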