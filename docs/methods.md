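# Methods

## Problem setting and model

Two whole-slide images of serial sections — a *target* and a *source* —
share tissue geometry up to (i) a global rigid-plus-scale displacement
from mounting and scanning and (ii) small nonrigid distortion from
sectioning. The registration model is the global part only: a 2D
similarity with isotropic scale `S`, proper rotation `R` and translation
`T`, carried on (y, x, 0) vectors with an inert third axis,

    [y', x', 0]^T = S · R · [y, x, 0]^T + T .

`T` lives at the estimation level `l_low`; at a finer level `l` it scales
by `2**delta` with `delta = l − l_low` (factor-2 pyramid). The residual
nonrigid part is deliberately not modelled — it is what the landmark
evaluation measures.

## Pyramid representation

A slide is a factor-2 pyramid of `m × m` tiles (`m = 256`). Level indices
grow with magnification; level `l+1` has exactly double the width and
height of level `l` up to ceiling rounding. Tile `(l, i, j)` covers
`[i·m, (i+1)·m) × [j·m, (j+1)·m)` (0-based, half-open; `i` = column,
`j` = row); edge tiles are padded to full size with white (255, 255, 255),
the slide background. Downsampling is 2×2 box averaging (integer
arithmetic, round half-up) — antialiased and cheap; level rasters agree
with a direct float box-filter chain within 2 intensity units.

`l_low` is the highest-magnification level whose total pixel count is
≤ `(2m)² = 262,144`. For the two scanner raster sizes the package is
exercised against (117,095 × 92,537 at 40× and 113,501 × 228,816 at 20×),
this puts `l_low` 8 and 9 halvings below the base respectively — a
≤ 512 px problem regardless of slide size.

## Stain separation

Stain amounts mix linearly in optical density (Beer–Lambert):
`OD = −log10(max(I, 1) / I0)` per channel with `I0 = 255`; the `max(·, 1)`
guard keeps fully absorbed pixels finite. The stain matrix has one row per
stain, one column per channel; a pixel with amount vector `g` mixes to
`o = g @ rows` and deconvolution inverts on the right, `g = o @ rows⁻¹` —
an exact linear inverse (round-trip error is float epsilon). The shipped
matrix provides two measured stain rows; the third row is completed as the
normalized cross product of the first two, which makes the matrix
invertible and the completion orthogonal to both stains. The *cytoplasm
feature* is one amount channel (default channel 0, configurable because
stain order differs per assay) clipped at zero and mapped to 8 bits with a
fixed ceiling (amount 1.0 → 255) so feature maps are reproducible across
slides.

## Global estimation

Keypoints are scale-space difference-of-Gaussian extrema with
gradient-histogram descriptors (scikit-image's SIFT; the detector is the
modelling choice, the descriptor a practical attachment). Matching is a
0.8 ratio test with cross-checking, followed by RANSAC under a similarity
model: inlier threshold 3 px at `l_low`, 2000 iterations, minimum 8
inliers, seeded generator. Fewer than 8 inliers raises
`InsufficientCorrespondencesError` — the pair is declared unregistrable
rather than silently mis-registered. All of these are conventional values
and are exposed in `RansacConfig`.

From the inlier pairs `P` (target) and `Q` (source), centred as
`p′ₖ = pₖ − p̄`, `q′ₖ = qₖ − q̄`:

* `S = sqrt( Σ‖p′ₖ‖² / Σ‖q′ₖ‖² )` — the centred-variance ratio, the only
  reading under which a pure rescaling is recovered exactly;
* `R` from the SVD of `C = Σ q′ₖ p′ₖᵀ`. Because the third vector component
  is identically zero, `C` is rank-deficient in 3D and the usual 3D
  determinant correction can leave an in-plane reflection uncorrected; the
  implementation therefore runs the 2×2 SVD on the supported plane with
  the `diag(1, det(VUᵀ))` fix and embeds the result, so `det(R) = +1`
  always;
* `T = p̄ − R S q̄`.

This closed form attains the least-squares optimum; the tests verify it
never leaves more residual than an exhaustive (angle, scale) grid sweep
(0.5° / 0.01 steps, translation solved per node).

## Propagated multi-level registration

A target FOV (level `l`, top-left `(u, v)`, size `w × h`, tile grid
`n1 × n2`) is served from the source without warping a full level:

1. `[v_s, u_s, 0]ᵀ = (SR)⁻¹ ([v_t, u_t, 0]ᵀ − 2^Δ T)`, rounded to the
   nearest pixel (halves away from zero);
2. source tiles covering the mapped FOV are fetched with a
   `⌊q/2⌋`-tile halo on every side (`q = 5`, odd); tiles beyond the slide
   border are white;
3. each output tile's `q·m × q·m` *enlarged area* is transformed
   independently — no shared mutable state, so areas may run concurrently —
   and its central `m × m` crop becomes the output tile;
4. the `n1 × n2` crops are stitched.

The per-area translation factors `T_g = −m·R·[(o−⌊q/2⌋), (k−⌊q/2⌋), 0]ᵀ`
and `T′ = R·[−(m−2λx)·⌊q/2⌋, −(m−2λy)·⌊q/2⌋, 0]ᵀ + T_g` are computed and
recorded per area; the renderer applies the equivalent composed affine by
inverse mapping from output-tile target coordinates into the enlarged
source area. The crop position is pinned by the requirement that the
identity transform passes source tiles through bit-identically, and the
stitched FOV then equals a whole-level warp wherever the pulled-back
content lies inside the halo: with `q = 5`, `m = 256`, content within
`⌊q/2⌋·m = 512` px of the tile is always available, which covers the
method's whole working regime (|angle| ≤ 20°, scale 0.8–1.25). Overlap
margins `λx = λy = 0` by default (tiles abut exactly); the parameters are
exposed but untested values other than 0 only alter the recorded `T′`.

Interpolation is bilinear with white fill everywhere (generation,
low-level warp, per-area rendering, oracles), so tile-propagated output is
bit-comparable with a whole-level warp rather than merely close.

## Evaluation protocol

Source landmarks are forward-mapped with level calibration; a pair is
matched when the Euclidean distance to its target partner is ≤ 5 px
(threshold and level configurable; the default applies the 5 px rule at
the annotation's own level). The per-pair score is the matched fraction —
with the default 5 landmarks per pair, scores are multiples of 0.2 —
and pair scores are summarized with mean, sample std, standard error and a
t-based 95% CI (small-sample appropriate). Accuracy is monotone in the
threshold by construction.

## Synthetic phantoms

The generator emulates the preparation chain the method faces in practice:

* **Geometry** — gland-like rings (epithelium around a lumen, lined with
  nuclei) plus scattered stromal nuclei on a stromal tissue ellipse over
  white background. Default canvas 4096 × 4096 px with 12 glands of radius
  60–140 px, which puts `l_low` three levels below base (512 px) and keeps
  a full generate-and-register run in a few seconds.
* **Stain difference** — the same structure map rendered through two stain
  profiles (per-class amount weights mixed through the stain matrix and
  exponentiated to intensity). The two renders differ strongly in color
  while their cytoplasm feature maps stay spatially correlated — the
  premise of cross-stain matching.
* **Displacement** — the source is resampled under a known similarity
  (angle within ±20°, scale 0.8–1.25, shift given in px at `l_low`),
  emulating mounting/scanning offset.
* **Sectioning jitter** (optional) — a smooth low-frequency displacement
  field with ~512 px node spacing, RMS displacement normalized to 0.75×
  the stated amplitude and softly saturated (tanh) at the amplitude:
  deformation is pervasive, as in real sections, while the amplitude stays
  a hard bound on every landmark's displacement. Amplitudes up to 16 px
  are accepted so degradation protocols (e.g. 8 px) are expressible;
  the default is 0.
* **Noise** — iid Gaussian sensor noise (default σ = 2 intensity units),
  drawn through a 256-quantile lookup so the integer-rounded marginal
  matches the normal law at one byte per sample.

Ground truth carries the transform at `l_low` and one landmark pair per
gland center at base resolution; with zero jitter the pairs satisfy the
transform to ≤ 0.5 px. Everything derives from a single seed through
separate child streams (geometry, jitter, two noise draws), so identical
specs give bit-identical pyramids.

What the phantoms do **not** model: real chromatin/cytoplasm texture
(structures are piecewise-constant classes with nearest-neighbor resampled
edges), stain-density variation within a class, tissue folds and tears,
scanner focus artifacts, and JPEG compression. Passing tests therefore
demonstrate the geometric and photometric machinery — level selection,
stain-space matching, closed-form estimation, tile propagation — under
controlled conditions, not keypoint robustness on arbitrary clinical
material.

## Protocol sizes and study conditions

* Parameter recovery: 20 phantom pairs per run, angle uniform ±15°, scale
  0.9–1.1, per-axis shift ±200 px at `l_low`, zero jitter, default noise.
  Success means scale within 1%, angle within 0.5°, translation within
  2 px.
* Tile/whole-warp agreement: 3 phantom pairs, every level from `l_low` to
  base, one ≥ 512 px FOV per level, ≥ 99% of non-seam pixels within 2
  intensity units (a 2 px band at tile borders is excluded; observed
  agreement is 100% because propagation is exact inside the halo).
* Evaluation protocol: 3 noiseless pairs (expected accuracy 1.0) and 8
  pairs at 8 px jitter (accuracy strictly below 1.0, threshold-monotone);
  these draw shifts within ±100 px so every ground-truth landmark stays
  on-slide.

## Numerical choices

* Coordinates: public point arrays are (x, y); the (y, x, 0) embedding is
  internal and `T` is stored in (y, x, 0) order. 0-based, half-open pixel
  rectangles; `i` = column, `j` = row.
* Pixel rounding of mapped corners: half away from zero.
* Warps: `scipy.ndimage` order-1 (bilinear) with `grid-constant` white
  fill, float32 accumulation, round-half-even to uint8.
* Degenerate inputs raise typed errors rather than returning garbage:
  coincident source points (scale), rank-zero covariance (rotation),
  singular `S·R` (localization), collinear stain vectors (completion).
* Determinism: SIFT is deterministic; RANSAC and the generator take
  explicit seeds; repeated runs are bit-identical.

## Known limitations

* The global model is similarity-only; shear, anisotropic scale and
  nonrigid distortion land in the residual by design. No per-tile local
  refinement or seam blending is performed.
* Rotations far outside the validated regime would push content past the
  `q`-halo; `q` is configurable if that regime is ever needed.
* Stain vectors are fixed configuration; there is no data-driven stain
  estimation.
* Reading proprietary scanner containers is out of scope; pyramids are
  built from rasters or imported via external region readers.
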