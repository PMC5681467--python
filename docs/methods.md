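# Methods

## Problem setting

Wax-embedded lung tissue scanned by μCT produces a 3D density image in
which airway and vessel walls are bright (X-ray dense), wax is
intermediate, and trapped air is dark. Two properties drive the design:

* the scans are far larger than RAM (≈1800×2000×2000 voxels at 32-bit),
  so every image-wide operation must run block-by-block; and
* vessel lumens are wax-filled, so lumen and background share one
  intensity and no local classifier can separate them — the lumen must be
  removed *after* classification using the original intensities.

## Block store and halos

A volume is partitioned by ceiling division into cubic blocks (default
edge 256 voxels — the value consistent with the published block counts of
245 for a 1600×1600×1200 scan and 72 for 1374×1497×500 — configurable).
Edge blocks are truncated, never padded, so the cores partition the
volume exactly; arrays are indexed (z, y, x), 0-based, half-open, and
blocks enumerate row-major with x fastest. Each block is one
uncompressed TIFF named `block_{i:04d}_{j:04d}_{k:04d}.tif`; a JSON
sidecar `meta.json` carries dims, block edge, halo, dtype, voxel size,
and — after `compute_meta` — the global min/max and a 256-bin histogram
with explicit edges (well-defined for float volumes). The histogram is
aggregated over blocks with shared edges, so it equals the unsplit
volume's histogram exactly.

Halos are constructed on read, not stored: `read_block_with_halo` fills
interior faces from neighbouring blocks and volume-boundary faces by
mirror reflection about the boundary voxel (the same `mirror` mode the
filters use, so a single-block store needs no halo at all). For any
operator with spatial footprint radius ≤ halo, blockwise application
therefore reproduces whole-volume application — exactly for integer
operators and to float rounding otherwise — because each output voxel is
computed from identical input values. Blocks are independent, so
processing order is irrelevant and parallel execution would be trivial.

One deliberate exception: the entropy feature quantises intensities over
the *slice's* min–max range by default (see below), which is not a
footprint-local property. For seam-free blockwise prediction with the
entropy feature enabled, pass an explicit `entropy_range` in the
`FeatureSpec`; the pipeline's tests do exactly that.

## Feature bank

Features are 2D, computed slice-wise along z (training annotations are
made on slices, and the screening that selected these filters was 2D).
Raw intensity is always feature 0. Defaults, chosen to span wall
thicknesses of a few voxels at 8 μm resolution:

| group | parameters (default) | features |
|---|---|---|
| Gaussian blur | σ ∈ {1, 2, 4, 8} | 4 |
| Neighbors | radii {1, 2} × 8 compass directions | 16 |
| Entropy | disc radius 4, 64 bins | 1 |
| Structure tensor | (σ_d, σ_i) ∈ {(1,1), (1,3), (2,3)}, both eigenvalues | 6 |
| Hessian | σ ∈ {1, 2, 4}; eigenvalues + orientation | 9 |

37 features total with the raw intensity. All convolutions and windows
use mirror boundaries. The neighbour feature for direction d at (y, x)
is the intensity at (y + r·dy, x + r·dx), directions ordered N, NE, E,
SE, S, SW, W, NW with y increasing downward. Entropy is the base-2
Shannon entropy of the equal-width-binned histogram over a disc;
a degenerate intensity range yields zero entropy. Structure-tensor
eigenvalues come from Gaussian-derivative gradients at σ_d whose outer
product is smoothed at σ_i. Hessian eigenvalues are ordered by signed
value; the orientation is the angle in [0, π) from +x of the eigenvector
of the larger-magnitude eigenvalue, 0 by convention at isotropic points.

Derivative kernels are sampled Gaussians truncated at 4σ; even-order
kernels are corrected to exactly zero DC response so constant inputs map
to exactly zero (the uncorrected truncated kernel leaves a ~1e-4
relative residual). The plain blur kernel is normalised to unit sum; on
finite slices the mirror boundary perturbs the slice mean at
O(perimeter/area), which is the accuracy limit of "mean-preserving" for
any boundary rule other than periodic.

No normalisation or histogram equalisation is applied anywhere in the
feature path: intensities are proportional to density and rescaling would
destroy comparability between blocks and between scans.

A `FeatureSpec` fingerprint (SHA-1 of the canonical field serialisation)
is stored with every trained model, and prediction refuses a spec whose
fingerprint differs — training/prediction feature-order mismatches are
structurally impossible.

## Classifier

A random forest (scikit-learn), 200 trees, √(n_features) candidate
features per split, fixed seed 17 by default. Training samples are the
feature vectors of labelled voxels exactly as given — no resampling or
reweighting, because the intended label sets are small and curated (a
few tubes as foreground, a few representative background regions).
Foreground annotations cover wall *plus* lumen: the enclosed edge pair is
the easiest evidence for edge-type filters, and the wax-filled lumen is
removed later by the intensity refinement. Probabilities are soft votes
averaged over trees, so class probabilities sum to 1 per voxel and the
map is deterministic given (samples, trees, seed).

## Post-processing

* `threshold_probability`: mask = (P ≥ t); monotone in t.
* `refine_by_intensity`: mask ∧ (I ≥ t₂). Both thresholds are manual
  parameters by design — the global histogram printed by the `meta`
  command guides the choice; no automatic threshold is applied.
* `label_regions` / `remove_small_regions`: 3D connected components at 6-
  or 26-adjacency (default 26: vessels are elongated and touch
  diagonally). Components with fewer than `min_size` voxels (default
  700) are deleted; size-equal components survive (strict `<`). Kept
  components are returned voxel-for-voxel unchanged, and the filter is
  idempotent.
* Morphology: erosion/dilation with the 6-connected cross element,
  iterated for radius > 1 (an octahedral effective element — a "radius" is
  otherwise undefined on a voxel grid). Erosion treats out-of-volume
  voxels as foreground and dilation as background, so the duality
  erode(¬M) = ¬dilate(M) holds exactly. Two composite schemes are
  provided: opening-then-closing, and closing–opening–opening(r=2).
  All morphology here is 3D.
* `compare_denoisers` reports Dice, false positives removed, and true
  voxels lost for the three options. On thin-walled phantoms the
  region-size filter loses zero true wall voxels while the radius-2
  opening scheme deletes 1-voxel-thick walls outright — the quantitative
  form of the qualitative superiority of connected-region filtering.

The pipeline runs prediction out-of-core via `map_blocks`, but runs
post-processing on the assembled volume: thresholding and refinement are
pointwise and cheap, and connected-component filtering is inherently
global. At the probability map's float32/uint8 sizes this is far below
the memory footprint of the raw-volume stages.

## Synthetic phantom

`default_phantom(seed)` renders a 96³ float32 scene: wax 20000, wall
35000, bubbles 8000 (16-bit-range values so 8/16/32-bit code paths are
exercised by casting); one "airway" (lumen radius 7, wall 3) and one
"vessel" (lumen 4, wall 2) as curved polyline tubes crossing the volume;
three air bubbles; one box of smoothed-noise "alveolar" texture
(amplitude 3000); and additive Gaussian noise with σ = 10 % of the
wall−wax contrast. Tube centerlines are polylines with linear
interpolation — the simplest shape giving curved tubes; distances are
exact point-to-segment. Walls override lumens where tubes overlap;
bubbles override everything and are excluded from the truth masks. Truth
masks are computed before noise and are therefore noise-invariant.

What the phantom does *not* model: beam hardening, ring artifacts,
partial-volume blur at interfaces, fibrotic texture, and the contact of
tissue with the capsule edge. Passing tests therefore demonstrate the
*mechanics* of the workflow (seam-freeness, determinism, threshold
logic, denoiser ranking, recoverability of cleanly separated walls), not
segmentation quality on real low-contrast tissue, where filter scales and
both thresholds need expert tuning per scan.

`make_labelset_from_truth` emulates manual annotation: it picks slices
containing foreground and samples up to 200 foreground (wall ∪ lumen)
and 200 background voxels per slice, deterministically per seed.

## Pipeline and reproducibility

`run_pipeline(config)` chains split → train/load → predict (blockwise,
halo ≥ the feature bank's maximum footprint, automatically raised with a
warning if configured smaller; a single-block grid runs with halo 0 since
mirror padding at its faces equals whole-volume boundary handling) →
assemble → threshold → refine → denoise → export. Every stage logs its
parameters and voxel counts to stderr, and a JSON manifest captures the
full configuration, so any run is restartable from its intermediate
stores and reproducible bit-for-bit under fixed seeds.

`pick_test_block` selects the block whose intensity variance is closest
to the volume-wide variance (ties to the lowest index) — a deterministic
proxy for "a representative block" used to trial a segmentation cheaply.
It favours blocks containing structure over flat wax, though the
structure found may be any high-variance feature (a bubble as readily as
a tube).

Problem sizes used by the test suite and the acceptance script — 96³
end-to-end runs, 64³ denoiser phantoms, 32² oracle slices, ≤ 32³
flood-fill masks, 50 randomized round-trip cases — were chosen so the
whole suite completes in well under a minute apiece while each check
still has the structure it needs (multiple blocks per axis, odd edge
remainders, thin and thick walls).

## Known limitations

* Features are 2D slice-wise; genuinely 3D filter banks (3D Hessian
  vesselness) are out of scope.
* Two classes only (foreground/background); walls of airways and vessels
  are not distinguished from each other.
* The entropy feature's default slice-range quantisation trades exact
  blockwise reproducibility for scan-level robustness; fix the range
  explicitly when that matters.
* Mesh export is the raw marching-cubes iso-surface; no smoothing or
  decimation.
* No distributed execution; the block structure is parallel-ready but the
  scheduler is a plain loop.
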