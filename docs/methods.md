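# Methods

## The analysis model

`tubequant` treats a bright-field tube-formation-assay field as a network
of dark, elongated cords on an uneven lighter background. No intensity
threshold separates tube from background reliably in such images, so the
pipeline detects tubes by their *borders*: the Canny detector marks pixels
of high spatial intensity derivative, and morphological cleanup turns the
border marks into a solid binary mask of tube-occupied area. All network
statistics then derive from two binary images — the tube mask and its
one-pixel skeleton.

Assumptions this model makes:

* tube borders produce the dominant intensity gradients in the field
  (debris, bubbles and scratches also produce edges; the `clean` step
  removes small ones, large defects are a known failure mode);
* input is uncompressed TIFF — lossy compression blunts the very
  high-frequency changes edge detection relies on, so strict mode rejects
  non-TIFF input;
* saturated (pure black/white) pixels depress the local derivative and can
  hide edges; no correction is attempted.

## Parameters

All eight user parameters travel as one JSON profile so an analysis can be
replicated exactly; defaults sit at the midpoint of each typical working
range. The intended workflow is to tune on one representative image
("sandbox" mode) and batch the rest unattended.

| name | unit | default | role |
|---|---|---|---|
| `scale` | µm/px | 2.75 | converts pixel measures to µm (length ×s, area ×s²) |
| `canny_connect` | px | 7 | edge points within this distance join one object |
| `dilate` | px | 4 | second closing radius; merges nearby objects |
| `fill` | px² | 2600 | enclosed holes strictly smaller than this are filled |
| `clean` | px² | 5500 | objects strictly smaller than this are cleared |
| `clip` | px or Inf | 50 | spur trim per endpoint; Inf deletes branch-free tubes |
| `overlap` | px | 10 | min skeleton overlap for an object's area to count |
| `radius` | px | 90 | branch points within this radius merge into one |

`fill` and `clean` are pixel *areas* of holes/objects; both thresholds are
strict ("smaller than"). `clip = Inf` iterates endpoint removal to a fixed
point, which intentionally annihilates whole branch-free components — the
parameter exists to exclude small tube-like fragments from quantification.

## Numerical and design choices

**Edge detection.** The Canny hyperparameters are not user-facing:
Gaussian sigma is fixed at 2.0 and the hysteresis thresholds derive from
the gradient-magnitude histogram (Otsu high threshold, low = 0.4 × high).
A constant image returns an empty mask rather than an error.

**Connecting edge points.** "Join points within `canny_connect` pixels"
is a single-linkage connectivity contract, and plain morphological closing
cannot honor it for isolated points (the erosion step re-separates them).
The bridge step therefore draws explicit one-pixel lines between the
closest pixels of component pairs within reach (a gap of `canny_connect`
background pixels is spanned), after which two disk closings
(`canny_connect`, then `dilate`) solidify the mask. Every step is
extensive: output ⊇ input.

**Connectivity.** Foreground components are 8-connected throughout. Holes
are labeled with the complementary 4-connectivity: with 8-connected
background a one-pixel diagonal contour would leak and an enclosed hole
could never be detected (the discrete Jordan-curve requirement).

**Skeletonization.** Zhang–Suen thinning (via scikit-image), iterated to
its fixed point. It removes only simple points, so component counts — and
the Euler characteristic — are preserved; the test battery checks this
over 100+ randomized masks along with idempotence. Zhang–Suen was chosen
over Guo–Hall thinning because it erodes diagonal line ends far less
(~0.1% vs ~0.6% of a short 45° bar's length), at the cost of grid-exact
90°-rotation symmetry: a rotated bar's skeleton can differ from the
rotated skeleton by a pixel, though its length and topology agree.

**Spur clipping** walks inward from every endpoint (pixel with exactly one
8-neighbor) in raster order, removing up to `clip` pixels and stopping at
the first pixel with ≥ 3 neighbors in the unclipped skeleton. On a straight
crossing the walk may halt one pixel before the junction because diagonal
adjacencies make that pixel a branch pixel too; this is intentional —
branch-point semantics are purely local neighbor counts.

**Length.** Each distinct 8-adjacent skeleton pair contributes once:
1 px for orthogonal pairs, the literal factor **1.414** for diagonal pairs
(the conventional constant; the difference from √2 is < 0.02%). A diagonal
pair that is also joined through a shared orthogonal foreground neighbor
is skipped so corners are not double-counted. This (1, 1.414) chain metric
is exact for axis-aligned and 45° directions and overestimates oblique
directions by up to ~8% (worst near 22.5°) — a known property of the
weighting, not of the implementation.

**Branch points** are counted after spur clipping. Raw branch pixels
(≥ 3 neighbors) are grouped by single-linkage clustering at distance
`radius` (k-d-tree pairs + connected components; deterministic raster
enumeration) and each group is replaced by its coordinate mean. The
consolidated count is reported; raw pixel counts remain available on the
analysis record.

**Area** keeps only edge-mask components whose skeleton intersection holds
≥ `overlap` pixels — an object must contribute to the length measurement
for its area to count. Thickness is area/length, 0 for an empty image and
NaN (missing) in the degenerate length-0, area-positive case, so
`thickness × length = area` holds identically whenever length is positive.

## The phantom generator

Phantoms emulate the in-silico validation strategy: line networks with
analytically known truth. Strokes are hard-edged, round-capped capsules;
the medial axis of a capsule is exactly its core segment, so a uniform
detection halo does not bias the recovered centerline length. Ground truth
is computed from geometry, never from the raster: total length is the sum
of Euclidean segment lengths × scale; junctions are points where ≥ 3
segment branches meet (an interior passage counts two branches, an
endpoint one, so corner and collinear joints are not junctions), merged
within the consolidation radius; area truth is the rasterized stroke union
× scale².

The shipped validation suite holds 22 noiseless phantoms — bars at 0°,
45°, 90° (including a rotated bar of identical truth length), T/Y/X
junctions, a plus, 2×2 and 3×3 grids, an 8-armed asterisk, polyline
curves, parallel bars, an H, a comb, a closed box and a blank control —
plus two salt-and-pepper variants (density 0.02). All segments lie at
multiples of 45°, where the chain metric is exact, mirroring the archetype
geometry the validation design calls for; junctions are separated by well
over the consolidation radius. Rendering is deterministic: identical
spec + seed give identical bytes. An optional linear illumination gradient
stresses robustness to background non-uniformity (off by default).

What the phantoms do **not** emulate: cell texture, debris, Matrigel
autofluorescence, focus variation, or oblique tube orientations. Passing
the phantom bar therefore demonstrates the geometric correctness of the
measurement chain, not segmentation quality on real micrographs — that is
what the profile-tuning workflow addresses per data set.

**Tuned phantom profile.** Following the sandbox-then-batch workflow, the
profile shipped for the suite was calibrated on the phantom archetypes and
then frozen: `canny_connect=3, dilate=2, fill=300, clean=700, clip=0,
overlap=5, radius=30` at 1 µm/px for 5-px strokes. `clip` calibrated to 0:
capsule caps leave no thinning spurs, and the Zhang–Suen backbone already
ends within ~1 px of the true segment tips. With this profile every
noiseless phantom's recovered length agrees with truth to ≥ 99.2% and
every junction count is exact; this is what `scripts/acceptance.py`
recomputes. The 0.02-density noise variants exceed what this
noiseless-tuned cleanup can remove (specks merge under closing) and carry
no accuracy bar; consolidation robustness to scattered spurious node
pixels is verified directly at the node-mask level.

**Known systematic effects.** The detected mask is wider than the drawn
stroke by ~2 px (≈1 px edge-localization halo per side) plus 1 px of
inclusive rasterization; thickness therefore overestimates the drawn width
by a roughly constant ~3 px, a relative error that shrinks as tubes get
wider. Tests bound the absolute halo at narrow widths and check the 15%
relative recovery on a wide (30 px) cord.

## Problem sizes

Validation phantoms are 768×768 px with 300–650 px segments — large
enough that sub-pixel end effects stay under the 1% length criterion
while the whole 22-image suite analyzes in a few seconds. The randomized
topology battery uses 100 masks of 40–120 px a side.

## Limitations

* Large-scale dish defects (cracks, scratches) and saturated regions are
  not corrected.
* No per-segment statistics and no loop/mesh counting; the four summary
  metrics are the scope.
* The oblique-direction bias of the (1, 1.414) chain metric applies to
  real tubes as well; lengths of networks with many tubes near 22.5°
  orientations are measured slightly long.
* Optic-disc exclusion for fundus images is not implemented; the
  non-black restriction is the only adaptation.
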