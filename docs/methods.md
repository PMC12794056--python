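# Methods

## The measurement

Automated fibrosis mapping (AFM) quantifies interstitial fibrosis in a
Masson's-trichrome-stained kidney section *locally around each tubule*. The
inputs are an RGB section image and a set of labelled tubule polygons
(distal or proximal, as a digital-pathology GeoJSON export). For each
tubule the pipeline:

1. computes the area-weighted polygon centroid (shoelace formula);
2. samples a square tile of `nominal_size` pixels (default 512) centered on
   that centroid, half-open in both axes;
3. classifies every tile pixel as fibrotic or not with a pointwise HSV box;
4. reports the **fibrotic metric**: fibrotic pixels / counted pixels, a
   fraction in [0, 1] shown as percent (1.0 = 100%).

The hypothesis of interest — is fibrosis enriched around distal tubules? —
is then a two-sample comparison of the per-tile metrics of the two classes,
with an independent t test and a Mann–Whitney U test.

### Coordinate and color conventions

All coordinates are 0-based pixels, x rightward, y downward, matching array
indexing; windows are half-open, so an unclipped tile has exactly
`nominal_size**2` pixels. Hue is in degrees on the full 0–360 circle with
red at 0° and green at 120° (several imaging libraries use a 0–179
half-scale; this package does not).

### Segmentation parameters

A trichrome green threshold is irreducibly a judgment call; the historical
choice was made by eye. The package therefore treats the threshold as a
recorded parameter rather than a constant: a pixel is fibrotic iff

    hue_min <= hue <= hue_max,  sat >= sat_min,  val_min <= val <= val_max

with defaults hue ∈ [90°, 180°] (green–cyan collagen band), `sat_min` =
0.15 (excludes near-white background and glass), val ∈ [0.20, 0.95]
(excludes hematoxylin-dark nuclei below, glare above). These defaults are
implementation choices; every run manifest records the values actually
used, which is the auditable substitute for a manual threshold. Note the
value ceiling means a maximally bright saturated green (value 1.0) is
excluded as glare by default; stained tissue sits well below that.

### Edge and interior policy

Tubules near the section edge would have truncated tiles. Default policy is
`clip`: the window is intersected with the image and the metric denominator
becomes the clipped pixel count; `skip` drops such tubules instead. The
annotated tubule's own interior is *included* in the tile by default (the
tile is a search area around the tubule); `--exclude-tubule-interior`
rasterizes the annotation polygon, forces its pixels non-fibrotic, and
removes them from the denominator. Both choices are recorded per record.

## Statistics

* **t test** — Welch by default: the two classes have very different tile
  counts in real cohorts (roughly 1:2.4) and no variance-equality evidence;
  pooled-variance Student is available as `--t-flavor student`. If both
  groups are constant, the statistic is undefined for equal means (error in
  `independent_t`; the pooled comparison reports t = 0, p = 1, since
  identical samples carry no evidence) and signed-infinite with p = 0 for
  unequal means.
* **Mann–Whitney U** — midranks for ties; exact null distribution when the
  pooled sample is tie-free and `n_a + n_b <= 20` (enumeration cost grows
  combinatorially), otherwise normal approximation with tie-corrected
  variance and continuity correction. The method used is recorded. An
  all-tied pooled sample has zero rank variance and is reported as p = 1.
* **Sidedness** — the scientific hypothesis is directional (distal >
  proximal), but the default is the conservative two-sided alternative;
  `--alternative greater` gives the directional test.
* No multiple-testing correction is applied across disease groups; each
  group's row is a self-contained comparison.

Both tests are computed by scipy.stats behind this interface; the test
suite checks them against an independent full-enumeration oracle and a
hand-written Welch formula.

## The synthetic-histology generator

Patient whole-slide images are not publicly available, so validation runs
on generated slides with analytic ground truth. The generator emulates
exactly the features the pipeline is sensitive to:

* **Color populations.** Fibrosis RGB jittered around (60, 150, 110)
  (hue ≈ 153°), tubule epithelium around (215, 150, 160) (pink, hue ≈
  351°), background and lumina around (245, 245, 245). Stained classes get
  independent per-channel Gaussian jitter (σ = 12); near-white pixels get a
  shared luminance jitter (σ = 12) plus a small per-channel term (σ = 2),
  so their saturation stays below the segmentation floor — a slide with
  zero fibrosis density contains zero fibrotic pixels by construction.
  These values are a synthetic convention, not biology; they are chosen to
  sit far inside/outside the default HSV box.
* **Tubules.** Non-overlapping star-shaped polygons (jittered radial
  profile around an ellipse, 20 vertices) at rejection-sampled centers with
  a minimum spacing of twice the maximum radius; pink rim, near-white
  lumen; classes assigned by random permutation, so at zero enrichment the
  two classes are exchangeable by construction.
* **Fibrosis field.** A Boolean model: elliptical blobs (rasterized, hard
  edged) from a Poisson point process. For center intensity λ and mean blob
  pixel area ā, coverage probability is 1 − exp(−λā), so λ is solved
  exactly from the requested area fraction; the mean *rasterized* blob area
  is obtained by quadrature over the radius/rotation distribution, which
  absorbs the pixelation bias of small blobs. Blob centers are sampled in a
  frame padded by the maximum blob radius so coverage has no deficit at the
  slide border. Within distance `r` of any distal centroid the center
  intensity is raised so local coverage is `p0 + delta`; overlapping
  enrichment disks do not stack. Blobs are drawn first and tubules on top,
  so tubule interiors are never fibrotic. Hard-edged blobs (rather than
  alpha-blended soft edges) are deliberate: a soft edge would make the
  segmented area depend on where the threshold cuts the blend ramp, and the
  analytic expectation below would no longer be exact.
* **Determinism.** One numpy Generator seeded once; draws are consumed in a
  fixed order (placement, class permutation, tubule shapes, base blobs,
  enrichment blobs, jitter fields). One seed gives byte-identical images
  and annotations.

### Analytic ground truth

`expected_tile_fraction` returns the exact expectation of a tubule's tile
metric: with `T` the (possibly edge-clipped) tile, `I` the union of tubule
interiors, and `E` the union of enrichment disks (all via exact polygon
geometry; disks are 96-segment buffers),

    E[metric] = ( p0 · area(T \ I) + delta · area((T \ I) ∩ E) ) / area(T)

with the denominator reduced by the own-tubule interior when interior
exclusion is simulated. Two approximations remain and are quantified by
the calibration tests: (i) coverage ramps over one blob radius at
enrichment-disk boundaries, which the sharp-step formula ignores (the ramp
is nearly symmetric, so the tile-average error is second-order); (ii) about
1% of fibrosis-colored pixels jitter across the hue 180° boundary and are
missed by segmentation. The measured mean bias (observed − expected) is a
few parts per thousand, well inside the ±0.02 contract.

## Problem sizes

Full-scale defaults mirror a real section: 2048² slide, 512-px tiles,
tubule radii 30–60 px, 30 distal + 70 proximal. Simulation-heavy analyses
use two reduced geometries chosen once and used everywhere:

* `reduced_spec` — 560² (or 480²) slide, 64-px tiles, 3–5 px tubules, 60
  distal + 120 proximal; used for null (type-I error) replication, where
  only exchangeability matters.
* `effect_spec` — same tubule/tile geometry on a 1600² slide; the 64-px
  enrichment disks then cover only ~25% of the section, so each distal tile
  is fully enriched while most proximal tiles are not, giving a
  distal-minus-proximal contrast close to `delta`. On a small slide the
  disks of 60 distal tubules would tile the whole section and the contrast
  would collapse — slide area, not tile size, is what carries the spatial
  signal.

## What passing tests do and do not show

The synthetic cohorts validate the machinery: metric exactness, threshold
semantics, statistical calibration (type-I error within [0.035, 0.065] at
α = 0.05 over 1000 null cohorts), power and unbiasedness of effect
recovery, and byte-level reproducibility. They do not validate the
biological threshold choice on real trichrome stains (stain intensity
varies between labs), nor the per-tile independence assumption: tiles of
neighboring tubules overlap and are spatially correlated, and the pooled
tests inherit the original design's decision to treat tiles as independent
units. Under random labelling the null calibration survives this
correlation (the permutation distribution is exact by exchangeability),
but p-values for real, spatially clustered labels are approximate — the
per-slide breakdown is emitted so clustering stays visible.

## Pseudobulk utility

For each (cell type, individual) pair with at least `min_cells` cells
(default 1), raw counts are summed over cells and scaled to counts per
million. Aggregation always happens on raw counts, never on per-cell CPM,
so pooling individuals is count-weighted by construction. Pairs below
`min_cells` are omitted and listed; pairs with zero library size are
flagged rather than emitted as NaN columns.
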