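# Methods

## Physical model

A brightfield tile of absorbing stains follows the Beer–Lambert law per
channel: `I_c = I0_c · exp(−(M d)_c)`, where `I0` is the incident
(background/white) intensity, the columns of the 3×2 mixing matrix `M`
are the per-stain OD direction vectors, and `d ≥ 0` the per-pixel stain
amounts. Taking natural logs gives the optical density
`od_c = ln(I0_c / I_c)`, which is linear and additive in the stains.
Zero intensities are clipped to one count before the ratio so OD stays
bounded, and OD is clipped below at zero (pixels brighter than the
background carry no absorption signal).

Normalizing each OD vector to unit sum projects it onto the barycentric
chromaticity triangle. This decouples color from amount exactly: a
pixel-wise intensity rescaling `I ↦ I0 · (I/I0)^k` multiplies OD by `k`
and leaves every chromaticity point fixed (a tested invariant). All
cluster statistics are computed in an orthonormal 2-D basis of the
triangle plane (`u = (1,−1,0)/√2`, `v = (1,1,−2)/√6`, origin at the
centroid); barycentric points are rank-2, so a planar parameterization
is required for non-degenerate Gaussians, and the basis being
orthonormal makes planar distances equal barycentric distances.

`I0` defaults to the per-channel 99th-percentile intensity of the tile
(an estimate of the unstained background) when an image is read from
disk; synthetic tiles carry their true `I0`.

## Blind decomposition

Pixels with total OD below `min_total_od = 0.10` are near-white
background whose chromaticity is noise-dominated; they are excluded
from the cloud. A Gaussian mixture (full covariances, ridge
regularization 1e-6, k-means++ initialization from the caller's seed,
at most 500 EM iterations, log-likelihood tolerance 1e-8) is fitted to
the planar cloud. Non-convergence raises an error carrying the
iteration count; component means closer than 0.05 barycentric distance
raise a collapsed-stain error (a single-stain tile can instead fall
back to a one-component model via a config flag). Components are
returned in a canonical order — descending red barycentric coordinate,
ties by weight — which both makes the fit label-permutation invariant
and implements the stain assignment: Picrosirius red stains stroma, so
the redder component is stromal.

Unmixing solves, per pixel, non-negative least squares of the OD vector
against the two mixing-matrix columns. For two columns the NNLS
solution is closed-form: the unconstrained 2×2 solve when it is already
non-negative, otherwise the better of the two clipped single-column
projections. This is exact (verified against forward-synthesized pixels
to 1e-6) and vectorizes over the whole tile.

Raw densities are divided by a fixed constant `od_scale = 2.5` and
clipped to [0, 1] so that density maps are comparable across tiles and
the nucleus-intensity threshold below has a fixed meaning. The constant
is a design choice of this package: some fixed scale must exist for a
threshold on "intensity from 0 to 1" to be well-defined, and 2.5 OD
comfortably covers the darkest nuclei in the synthetic model.

## Stain-quality metrics

Protocol quality is summarized by three numbers on the fitted model and
cloud: (1) the Mahalanobis distance between the two component means
under the mixture-weight-pooled covariance, `√((m1−m2)ᵀ S⁻¹ (m1−m2))` —
weight pooling rather than hard-count pooling keeps the measure a
property of the model alone; (2) the Calinski–Harabasz index
`[tr(B)/(k−1)]/[tr(W)/(n−k)]` over a maximum-posterior hard assignment
(the index requires labels; the model supplies the most probable ones),
with an infinity sentinel when within-scatter vanishes; (3) the EM
weights, the normalized amount of color per cluster. Both metrics are
invariant under rigid motions of the planar coordinates.

The comparison fixture for a poorly separating stain places the two
cluster means ≈ 0.10 apart in barycentric distance with σ = 0.03 —
visibly overlapping clusters, but still an identifiable mixture. Much
closer means (≈ 2σ) make the mixture effectively unidentifiable and EM
then hits its iteration budget by design; that regime is reported as a
convergence error rather than a meaningless score.

## Segmentation

Glands are the low-stromal-density regions enclosed by stroma; all
stages run on the normalized stromal map, with the epithelial map used
only for the final nucleus filter.

1. **Opening.** Grayscale morphological opening with a rectangular 6×6
   px kernel smooths gland boundaries and removes sub-kernel clutter.
   The kernel trades off separating adjacent glands (larger) against
   not merging them (smaller).
2. **Mask.** Gradient-maximization thresholding: among 256 uniformly
   spaced candidate levels on the map's range, select the threshold
   maximizing the mean Sobel gradient magnitude over boundary pixels
   (pixels 8-adjacent to the opposite class) of the thresholded image;
   ties keep the lower threshold. Foreground is `map ≥ t` and the
   gland-candidate mask is `map < t`; with this convention the lowest
   candidate yields no boundary and is skipped, so a two-level image
   selects a threshold strictly between its levels. The criterion uses
   local image content (boundary sharpness) rather than the global
   histogram. A constant map has no threshold and raises.
3. **Seeds.** The gland foreground (inverted stromal map) is eroded
   with adaptive elliptical structuring elements driven by the local
   structure tensor (Gaussian window σ = 3 px): anisotropy
   `(λ1−λ2)/(λ1+λ2)` interpolates the SE between a disk (flat or
   isotropic neighborhoods) and a line-like ellipse aligned with the
   direction of least variation (along edges), with semi-axes bounded
   by `erosion_max_axis/2 = 4.5` px. The erosion severs inter-gland
   bridges thinner than the SE while the edge-aligned ellipses spare
   small glands. For tractability the per-pixel SE field is discretized
   into a bank (4 anisotropy levels × 6 orientation bins over [0, π),
   one disk for the isotropic level); the image is eroded once per
   distinct SE and each pixel takes its own bin's result.
   `local_structure_tensor_se` exposes the continuous per-position
   ellipse for inspection. The eroded map is thresholded again by
   gradient maximization and its connected components inside the mask
   become the seeds. No seeds is a warning, not an error — stroma-only
   tiles legitimately contain none.
4. **Watershed.** Marker-controlled watershed on the Sobel gradient of
   the (smoothed) stromal map, flooding restricted to the mask; every
   region contains exactly its seed and no labeled pixel leaves the
   mask. A seed outside the mask is an error naming the seed.
5. **Filtering.** Every true gland contains at least one nucleus.
   Regions smaller than `min_object_size = 90` px (the mean epithelial
   nucleus area) are removed as `too_small`; regions without a
   connected blob of ≥ `min_nucleus_pixels = 10` pixels at epithelial
   density ≥ `min_nucleus_intensity = 0.7` are removed as `no_nucleus`.
   `min_nucleus_pixels` quantifies "sufficient pixels" and is
   configurable. Relaxing either threshold can only grow the accepted
   set (a tested monotonicity property). Rejections are recorded with
   their reason, and the pre-filter label map is kept on the result so
   rejections can be attributed to specific structures.

The whole pipeline is deterministic given the seed (the only stochastic
step is EM initialization). Connectivity is 8-connected throughout;
coordinates are 0-based (row, col).

### Interpreting the two ambiguous readings

Eroding the *stromal* map directly would merge glands rather than
separate them; the operative reading — adopted here — erodes the gland
foreground (equivalently, dilates the stroma), which shrinks gland
regions and severs thin connections, making one seed per gland
possible. Likewise the watershed floods the *gradient* of the stromal
map, not the raw map: basins then correspond to gland interiors bounded
by the steep stromal transition.

## Synthetic generator

The generator is the package's study condition, not a tuning knob. It
paints per-pixel densities — stroma 1.2 OD (normalized ≈ 0.48) with a
smooth ±12% texture field outside glands, epithelial cytoplasm 0.45 OD
(≈ 0.18), nuclei 2.1 OD (≈ 0.84, above the 0.7 floor with noise
margin), lumina 0 — and renders `I = 240 · exp(−M d)` at 8 bits with
two noise sources: a smooth multiplicative stain-intensity field
(CV = 0.05, emulating staining variation; it moves OD magnitude, not
chromaticity) and additive Gaussian CCD noise (σ = 2 counts). Default
references are stroma ≈ (0.60, 0.25, 0.15) and epithelium ≈
(0.30, 0.30, 0.40) in barycentric OD chromaticity — a red-absorbing
versus blue/purple-absorbing pair; no published numeric chromaticities
exist, so these are plausible constructions.

Gland shapes are smoothed random-radius star polygons. Architectures:
benign / well-formed glands have a single central lumen and basally
placed nuclei; cribriform glands carry 2–6 disjoint lumina on an
interior ring; fused glands are unions of overlapping lobes sharing one
instance id; single cells are 90–220 px epithelial blobs with one
nucleus. Two trap architectures reproduce the structures the nucleus
filter must reject: `nucleus_free_trap` rings of cytoplasm around a
lumen with no nucleus (rejected as `no_nucleus`) and `bare_nucleus`
isolated nuclei without cytoplasm (≈ 78 px, rejected as `too_small`).
Ground truth records the full gland footprint (lumina included), an
architecture tag per instance, and the nucleus mask.

Named suites (≤ 12 tiles, ≤ 512×512 px) cover the architectures;
`mixed` draws one tile from each. Tiles are deliberately small so the
full test suite and the reproduction script run in tens of seconds on
one CPU; the algorithm itself has no tile-size dependence beyond
runtime.

What the generator does **not** emulate: real nuclear texture and
chromatin patterns, out-of-focus blur, tissue folds and staining
artifacts, touching glands separated by sub-resolution stroma, and the
continuous morphological spectrum between Gleason patterns. Passing
tests therefore demonstrate correctness of the algorithmic chain under
the stated absorption model and architecture geometry — not clinical
performance on scanned slides, which the published expert study
addresses and which cannot be reproduced without the original data.

## Evaluation

Object categorization replaces an expert's visual judgment with
explicit thresholds (defaults `iou_match = 0.5`, `coverage_low = 0.2`,
`coverage_high = 0.7`; all prominent in config). Per predicted object,
in order: **over-segmented** if ≥ 2 truth objects each cover ≥
`coverage_low` of it, or if its area exceeds `1/coverage_high` times
its best-matching truth object; **under-segmented** if it covers <
`coverage_high` of its best truth object; **correct** (gland or
non-gland by the truth tag) if best IoU ≥ `iou_match`; otherwise
under-segmented when residual overlap is still substantial, else a
correctly segmented non-glandular object. The tree guarantees exactly
one category per object. A truth object is *found* iff a
correctly-categorized prediction matches it at `iou_match`; a gland
whose only match is an under-segmentation counts as missed.

Summary arithmetic: per-category percent = 100·count/total to two
decimals (half-up); headline accuracy = integer-rounded percent of
objects neither over- nor under-segmented; gland and non-gland shares
among the accurate objects. Fed the published categorization counts of
11,447 objects, this arithmetic reproduces the published percentages
exactly.

## Numerical choices and edge cases

- EM: k-means++ init with caller seed, `n_init = 1`, ridge 1e-6; the
  fit is bit-reproducible given seed and point order, and recovered
  parameters are order-invariant to test tolerance for well-separated
  clusters.
- NNLS: collinearity guard `det(G) ≤ 1e-12 · G00 · G11` raises a
  degenerate-stain error.
- Thresholding: candidate grid is `linspace(min, max, 256)`; scores are
  compared strictly, so ties keep the first (lowest) candidate.
- Structure tensor eigenvectors use the closed-form 2×2 solution with a
  fall-back to coordinate axes when the off-diagonal vanishes; a zero
  tensor yields a maximal disk.
- Watershed ties follow scikit-image's deterministic priority-queue
  order (flooding value, then insertion order).
- Degenerate inputs raise typed errors mapped to CLI exit codes:
  invalid input → 2, degenerate data → 3.

## Known limitations

- The adaptive-erosion SE bank quantizes orientation to 30° bins; very
  thin diagonal bridges near a bin boundary may be severed slightly
  asymmetrically.
- The per-tile blind fit assumes both stains are present in reasonable
  amounts; a tile dominated by one stain needs the single-stain
  fallback and then yields no epithelial map.
- Evaluation thresholds are surrogates for visual judgment; reported
  category percentages shift with them, which is why they are config
  fields rather than constants.
- No whole-slide tiling/stitching: inputs are single tiles.
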