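# Methods

This note documents the models and procedures implemented in `fociquant`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the package's known limitations.

## Image model and conventions

Images are 2-D arrays of non-negative intensities (8-bit, 16-bit, or
float), one per channel: blue = DAPI nuclear counterstain, green = γH2AX
(DSB marker), red = 53BP1 (DDR protein). Channel roles are mapped
explicitly — never inferred from filenames or order. Coordinates are
(row, col), 0-based, origin top-left; bounding rectangles are half-open
`[r0, r1) × [c0, c1)`. Native integer intensities are preserved through
segmentation; sums use 64-bit accumulators because a 16-bit 2048² field
overflows 32-bit arithmetic. Physical pixel size is deliberately not
modeled: acquisition metadata is often unreliable, so all areas are in
pixels.

## Nucleus segmentation and cropping

The blue channel is binarized at the Otsu threshold — the histogram split
maximizing between-class variance. For 8-bit images the histogram uses the
native 256 levels; otherwise 256 equal-width bins over the data range. Ties
are broken toward the smallest threshold so the result is deterministic. A
constant image has no meaningful threshold and raises an error, which the
pipeline records as a QC exclusion (`degenerate_histogram`) rather than a
crash.

Cleanup is the smallest standard sequence that removes non-nuclear debris:
a morphological opening (disk, radius 2 px by default), hole filling, and
8-connected component labeling. Components smaller than `min_area_px`
(default 200 px — debris), larger than `max_area_px` (default 50 000 px —
clumps), or touching an image edge (clipped nuclei cannot be measured
fairly) are dropped and counted in QC. Touching nuclei survive as single
merged components; there is no watershed splitting, and the `max_area_px`
filter is the only defense. All values are configurable.

Each surviving nucleus is outlined (inner 4-boundary by default: mask
pixels with an outside 4-neighbor; a Canny option exists for compatibility
— on a binary mask both trace the same rim) and cropped by
**fill-and-subtract**: the bounding rectangle is copied twice, the nucleus
region is zero-filled in one copy, and the difference leaves the original
intensities inside this nucleus and zero everywhere else. This matters
when bounding rectangles overlap: pixels belonging to a *neighboring*
nucleus are zeroed too, so intensity is never double-counted. Total
intensity over the mask is conserved exactly (integer arithmetic), and the
test suite asserts this conservation and the pairwise disjointness of
masks.

## Foci segmentation by fuzzy c-means

Within each nucleus, the pixel gray levels (a 1-D feature; position is
deliberately not used) are clustered by fuzzy c-means minimizing

    J = Σ_k Σ_i u_ik^m |x_k − v_i|²,   Σ_i u_ik = 1,

with the standard alternating updates
`u_ik = 1/Σ_j (d_ik/d_jk)^(2/(m−1))` and `v_i = Σ u^m x / Σ u^m`. Pixels
are hard-assigned to their maximum-membership cluster (ties to the
higher-centroid cluster, favoring foci sensitivity) and the
highest-centroid cluster is the foci class. Clustering each nucleus
separately is what removes the need for any global intensity threshold.

Implementation notes:

- The iteration runs over the *unique* intensity values weighted by pixel
  counts — exactly equivalent to per-pixel clustering and much faster on
  integer images.
- Defaults: `c = 3` (background / intermediate / foci; the one structural
  parameter), `m = 2.0`, tolerance 1e-5 on the maximum centroid shift in
  [0, 1]-normalized intensity units, 300 iterations maximum.
- Initialization places centroids at the (2i+1)/(2c) quantiles of the
  observed intensities, making the default path fully deterministic; a
  seeded random initialization is available but never used implicitly.
- The objective is non-increasing by construction and asserted per run in
  the tests; membership rows sum to 1 within 1e-9.
- Only pixels inside the nucleus mask are clustered — the zero padding of
  the bounding rectangle would otherwise consume a cluster.
- A nucleus with fewer than `c` distinct values (blank or saturated)
  yields an empty, flagged foci image (`degenerate_fcm`), not an error.

The extracted foci image keeps original intensities on the foci support
and zero elsewhere.

### What the top cluster captures

A Gaussian focus has a bright core and a dim skirt. The
top-of-three-clusters rule selects pixels above roughly half the local
peak height: it captures every core pixel and no pure-background pixel,
but the skirt falls into the intermediate cluster. In absolute terms the
integrated foci intensity therefore measures a reproducible *fraction* of
the total emitted focus signal (≈ 35–50 % on the synthetic scenes,
depending on density). This does not harm the metric's purpose — comparing
foci formation between cells and conditions — because the capture fraction
is stable across conditions; the acceptance checks quantify exactly this
(see "Dense-foci regime" below). Whether intermediate-cluster pixels
belong to dim foci is left unresolved; only the top cluster is counted as
foci.

## Per-nucleus metrics

- **Foci count**: connected components of the foci support (8-connectivity
  default) with at least `min_focus_px` pixels (default 4 — rejects
  single-pixel noise; both configurable).
- **Total foci area**: support size after the same size filter.
- **Integrated intensity** `I_sum = Σ_{(i,j)∈S} I(i,j)`: exact wide sum
  over the support (unfiltered — every segmented foci pixel carries
  signal).
- **Co-localization ratio** `Ra = Σ_{S_G} I_R / Σ_{S_G} I_G`: both
  operands are the *extracted* foci images, so the denominator equals the
  total green foci intensity and raw off-focus background — which depends
  on acquisition settings — never enters the ratio. Two channels
  co-localize at a pixel when both extracted intensities are positive.
  `Ra` is undefined (NaN, QC-flagged, excluded from statistics) when the
  nucleus has no green foci intensity. Co-localized red foci counts/areas
  are reported alongside (red components intersecting S_G, and
  |red support ∩ S_G|).
- **Percentage difference** `|d1 − d2| / min(d1, d2) × 100`: symmetric;
  undefined when the smaller value is ≤ 0. One published worked table
  prints 55.8 for the area metric where its own printed inputs (2054,
  2754) give 34.08 by this formula; the package follows the formula and
  treats the printed 55.8 as an erratum.

## Group statistics

Per-cell metrics are compared between two groups with the two-sided
Wilcoxon rank-sum (Mann-Whitney U) test: exact null enumeration when
n₁+n₂ ≤ 20 and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections (scipy's
implementation; the tests verify the exact branch against a
full-enumeration oracle). Group spread is summarized as mean ± sample SD
(n−1) and CV = SD/mean × 100 (undefined for non-positive means). P-values
are kept at full precision and formatted `<0.001` in reports — a printed
"0.000" is not a probability. Groups below 255 cells trigger a warning
(the recommended screening-scale minimum), not an error, so small analyses
still run. Replicates are pooled; no mixed-effects modeling and no
multiple-testing correction are applied.

## Synthetic scenes

`generate_scene` renders what the pipeline needs to be tested against:
non-overlapping elliptical nuclei placed by rejection sampling (fully
inside the field, ≥ 3 px clearance so neighbors never merge), a domed
DAPI-like blue profile per nucleus, an independent per-nucleus, per-channel
staining background (the between-cell variation that motivates per-nucleus
thresholding), and foci as 2-D Gaussian puncta confined to their nucleus
mask. Shot noise (Poisson) and Gaussian read noise (SD 10 counts default)
are applied last; output is 16-bit by default. Everything derives from one
seed; identical specs give bit-identical images.

Co-localization is controlled by φ: `round(φ · n_green)` green foci
receive a red partner at the same center and sigma, with amplitude scaled
by the ratio of the red/green amplitude-range midpoints; independent red
foci number `round((1−φ) · n_draw)`. Defining the co-localized count
against the *green* foci makes φ = 1 an exact channel copy (given equal
amplitude ranges and backgrounds and no noise), so the pipeline's Ra = 1
exactly in that scenario — a sharp end-to-end identity test. The recorded
ground truth includes every mask, every focus (center, sigma, amplitude,
co-localization flag), and the rendered focus signal per nucleus/channel.

Two presets bracket the interesting regimes:

- `sparse_spec`: 8 nuclei per 384² field, 4–8 foci each, σ 1.5–2 px,
  centers ≥ 12 px apart, amplitude/background ≥ 10 — the easy regime where
  a correct pipeline recovers essentially every focus (`truth_match`
  scores recall by center containment and precision by components
  containing a true center).
- `dense_spec`: 5 large nuclei per 512² field, 60–80 foci each at σ = 2 px
  — mean nearest-neighbor spacing below 2σ, so puncta merge into
  conglomerates and counting collapses.

What the generator does **not** emulate: optics-accurate PSFs, chromatic
shift between channels, uneven illumination, saturation, touching nuclei,
mitotic or apoptotic morphologies, and out-of-focus light. Passing the
synthetic recovery tests therefore demonstrates correctness of the
algorithmic chain under the stated image model, not robustness to every
artifact of real acquisitions.

### Dense-foci regime

With the dense preset the pipeline detects ~15–20 % of the true focus
number — counting saturates, as expected when puncta merge. The integrated
intensity metric is judged by what it is for: recognizing a true
difference in foci formation. Two dense conditions whose focus amplitudes
differ by 1.5× give measured mean `I_sum` ratios within 10 % of the true
signal ratio (typically ~3–5 %), while the measured count ratio stays near
1 — counting is nearly blind to the same contrast. This is the package's
quantitative statement of why intensity, not counting, is the robust
readout at high damage density; the absolute capture fraction discussed
above cancels in the comparison.

## Determinism and problem sizes

The default pipeline has no random step (quantile FCM initialization,
deterministic tie-breaks, sorted outputs), so identical inputs produce
byte-identical CSVs — asserted end-to-end in the tests. The test suite and
the acceptance script run on desk-scale scenes (384²–512² fields, 5–10
nuclei, up to 20 seeds per property), sizes chosen to exercise every code
path with comfortable statistical margins on a single CPU; all generator
parameters scale to full 2048² fields unchanged.

## Known limitations

- Touching nuclei are not split; they survive as one component unless
  removed by the size filter.
- The foci-class definition (top cluster of three) measures a stable
  fraction of total focus signal, not its absolute value; absolute
  radiometry is out of scope.
- `Ra` compares extracted foci images; it is linear in red intensity but
  invariant only if the green *support* is unchanged — rescaling green
  intensities rescales the denominator accordingly.
- No correction for bleed-through between channels; co-localization at
  the pixel level assumes co-registered channels.
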