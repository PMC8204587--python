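# Methods

## Problem setting

Localization-based super-resolution microscopy (STORM) renders an image
from the fitted positions of single-molecule blinks. Compared with
conventional fluorescence images, the result has three properties that
matter for automated nuclei instance segmentation: nuclei appear as
collections of discrete bright speckles rather than contiguous intensity
gradients; the background is almost exactly zero; and diffuse "noisy
regions" — non-specific binding, unbound fluorophores, out-of-focus
fluorescence and autofluorescence — can rival true nuclei in local
brightness and are easily mis-segmented as objects.

`stormseg` implements everything *around* an instance segmenter for this
regime: image preparation, semantic noise removal, resolution of
overlapping detections, tile-based processing of full-resolution frames,
and the matched-instance evaluation protocol. The segmenter itself is
pluggable; a threshold/connected-components reference segmenter is
included so the full pipeline runs without any trained network.

## Preprocessing (`stormseg.imageops`)

* **Resizing.** Downsizing by an integer factor k is exact k×k block
  (area) averaging — the "bilinear with averaging" dialect of common
  image tools; non-integer downsizing is bilinear with an anti-alias
  prefilter; upsizing is plain bilinear. Integer outputs round
  half-to-even, so integer-factor downsizing conserves the global mean
  to rounding.
* **Label maps** are resized with nearest-neighbour only. This
  guarantees the output label set is a subset of the input's; when a
  downsized segmentation is scored against full-resolution ground
  truth, the pipeline upsizes the label map this way first.
* **Gaussian blur** uses an isotropic kernel truncated at 4σ with
  reflecting boundaries; the default σ = 2 px matches the blur variant
  of the acquisition pipeline this package targets. σ = 0 is the
  identity.
* **Histogram equalization** first min–max normalizes to the full
  bit-depth range ("with normalization", limiting intra-image
  variation), then maps intensities through the normalized cumulative
  histogram — 256 bins for 8-bit input and the full 65 536 bins for
  16-bit (exactness preferred over speed at this scale). The mapping is
  monotone non-decreasing and spans the full range. A constant image is
  returned unchanged with a warning. The fixed stage order is
  resize → blur → equalize, and it is logged.

## Noise removal (`stormseg.denoise`)

The noise-map *producer* is an interface — any callable mapping an image
to per-pixel noise probabilities in [0, 1]. Two providers ship: a
file-based one for maps computed elsewhere (typically a trained semantic
network), and a classical baseline that scores the smoothed local
density of lit pixels, which is the statistic that distinguishes diffuse
noise regions from near-zero background. Training of a semantic network
is deliberately out of scope.

The probability map is quantized to 256 bins and binarized with Otsu's
method: the threshold maximizes the between-class variance
ω₀ω₁(μ₀−μ₁)², ties break toward the lower bin, and a single-populated-bin
histogram degenerates to "all one class". Pixels *strictly above* the
threshold count as noise — this convention makes an all-zero map produce
an empty mask. Subtraction zeroes the image under the mask and touches
nothing else; masked-region removal (rather than arithmetic subtraction
of probabilities) is the interpretation implemented, since the
workflow's denoised images show flagged regions removed outright. No
morphological cleanup is applied to the mask.

## Instance post-processing (`stormseg.instances`)

Small instances — area below 25 % of the image-average instance area,
with the mean computed once before any removal — are deleted first.
Remaining pairwise overlaps are then resolved with a four-way rule.
With overlap O and fractions f_A = O/|A|, f_B = O/|B|,
f_U = O/|A∪B|, evaluated in order:

1. **merge** if f_U > 0.5 or f_A > 0.5 or f_B > 0.5 ("more than 50 %"
   is strict; "total pixel area" is read as the combined area |A∪B|);
2. **random assign** if f_A ≤ 0.1 and f_B ≤ 0.1 (the "10 % or less"
   inclusive reading resolves the boundary case in the rule's wording);
3. **assign** if exactly one fraction is ≤ 0.1: the whole overlap goes
   to the instance with the greater overlap *fraction* (the rule's
   premise is stated in fractions, so "greatest overlap" is read as
   fraction, not absolute pixels);
4. **split** otherwise: compute the centroids of the two full masks
   (overlap pixels counted in both, unweighted binary center of mass),
   take the midpoint M of the centroid segment, and assign each overlap
   pixel by the sign of (p − M)·(c_A − c_B) — i.e. along the
   perpendicular bisector of the centroid segment. Exact ties go to the
   smaller id; coincident centroids admit no bisector and escalate to a
   merge, logged.

Pairs are processed largest-overlap-first, ties toward the smaller id
pair, recomputing after every action. The processing order is a design
choice made for determinism and a simple termination argument: every
action strictly reduces the total count of multiply-owned pixels. Random
assignment draws one Bernoulli(0.5) per contested region from a
generator seeded by the run configuration, so the whole stage is a pure
function of input and config. Afterwards small-instance removal runs
once more with the mean recomputed on the current set, since splitting
can create new small fragments. Multi-way (> 2) mutual overlaps are
handled pairwise-iteratively.

## Tiling and stitching (`stormseg.tiling`)

Full-resolution frames (5120 × 5120 in the target acquisition) are cut
into 512 × 512 tiles overlapping neighbours by a 128-pixel margin:
stride = tile − margin, per-axis tile count ⌈(L − tile)/stride⌉ + 1,
last origin clamped to L − tile (clamping, not padding, so no synthetic
border content is ever created). Reassembling raw tiles at their origins
is bit-exact.

Stitching places each tile-local instance at its tile origin, then
merges instances from different tiles whose masks share pixels in a
shared region. The match threshold (minimum intersection over the
smaller fragment) defaults to 0 — any shared pixel matches — a
permissive choice whose residual errors are cleaned up by the downstream
overlap resolver, which runs whenever the merged result still contains
overlaps. Global ids follow first-seen order (tile row-major, then local
id), so stitching is deterministic. With the margin comfortably larger
than an instance fragment, stitching a perfect per-tile segmentation
equals the whole-image segmentation up to label permutation; this
round-trip is asserted in the acceptance suite on a 1536 × 1536
synthetic frame.

## Evaluation (`stormseg.metrics`)

Matching is one-to-one at an IoU threshold, default 0.7 and inclusive
("achieved 0.7" = ≥ 0.7): each ground-truth instance pairs with its
maximum-IoU prediction when that IoU reaches the threshold. No
assignment solver is needed because for thresholds above 0.5 two
predictions cannot both exceed the threshold against one ground-truth
mask; a solver-style brute-force matcher exists in the test suite as the
independent oracle. For configured thresholds ≤ 0.5 candidates are taken
greedily in descending IoU to preserve one-to-oneness.

Scores: F1 = 2TP/(2TP+FP+FN); FN% = FN/n_gt; FP% = FP/n_gt — note both
percentages use the *ground-truth* count as denominator, which is the
convention of the evaluation protocol this package implements (FP% can
therefore exceed 1). Degenerate cases: n_gt = n_pred = 0 scores F1 = 1
with both percentages 0; n_gt = 0 with predictions present reports
FP% = ∞ with a warning. The Hausdorff distance is the symmetric
max-min Euclidean distance over foreground pixel coordinates, reported
as the mean over matched pairs (NaN when nothing matched). Whether the
distance is taken over all foreground pixels or boundary pixels only is
a config option (`full` default, `boundary` available); for solid masks
the two coincide on the outer contour. Dataset aggregation defaults to
the per-image mean, with pooled-count aggregation available. "F1
averaged across instances" is ambiguous as stated in the protocol (F1 is
a per-image quantity); per-image averaging is what is implemented.

## Synthetic generator (`stormseg.simgen`)

The generator emulates the three STORM image characteristics above, not
the optics: no localization-precision model, drift, PSF fitting or 3-D
rendering.

* Nuclei are rotated ellipses (rotation uniform in [0, π), semi-axes
  uniform in `radius_range`, default 10–18 px at 512²), centers
  rejection-sampled to honour `min_separation` (default 40 px); a
  bounded number of failed attempts raises an explicit placement error,
  never silently fewer nuclei. Elliptical truth keeps centroid and
  Hausdorff oracles analytic — a testability choice; real nuclei are
  irregular.
* Each nucleus receives Poisson(density × area) localizations. *Dense*
  texture samples them uniformly in the ellipse (default density 2.0
  per pixel); *discrete* texture samples from a mixture of
  `cluster_count` (default 8) tight sub-clusters (spread 1.5 px),
  default density 0.3 — the defaults guarantee discrete-mode per-pixel
  occupancy is below dense-mode, the texture contrast the two labelling
  regimes show in practice.
* Every localization splats a Gaussian spot of width `spot_sigma`
  (default 1 px) truncated at 3σ; spots accumulate additively and the
  sum is clipped to the bit-depth maximum (default 16-bit), with spot
  peak at half the dynamic range. Truncation bounds the render cost and
  keeps the background *exactly* zero outside spot support.
* Noise regions are unions of 3–7 overlapping random disks (radii
  10–25 px), rendered at `noise_density` (default 0.5). No quantitative
  description of real noise regions was available to calibrate against,
  so these defaults are free parameters chosen once as plausible for
  tissue-style diffuse noise. Noise masks are clipped to be disjoint
  from truth masks.
* Truth masks are made pairwise disjoint even when `min_separation`
  permits ellipse overlap, by assigning contested pixels to the nearest
  nucleus center.
* The pixel grid convention is row-major, 0-based, pixel centers at
  integer coordinates; all randomness flows from one `numpy` generator
  seeded by `SimParams.seed`, so generation is a pure function of the
  parameter set.

What passing tests on this generator do **not** show: robustness to
irregular nucleus shapes, intensity heterogeneity across a tissue
section, pathology-grade texture variation, or realistic noise
morphology. They do show that the processing stages are exact on their
own contracts and mutually consistent end-to-end.

## Pipeline (`stormseg.pipeline`, CLI)

Stage order is fixed: preprocess → denoise → (tile) → segment →
(stitch) → postprocess → evaluate. Denoising precedes segmentation
because the noise mask is subtracted from the *image*, producing the
denoised frame the segmenter sees. When preprocessing downsized the
image, the final label map is upsized (nearest-neighbour) back to the
ground-truth frame before scoring. Every stage writes its artifact with
a stage suffix plus a JSON manifest (config hash, seed, versions,
per-stage timings); data artifacts are byte-identical across re-runs
with the same config — the manifest's timings are the only run-to-run
variation. Segmenters are name-resolved plugins (`threshold-cc`,
`external-labelmap` for predictions produced by external networks).
Exit codes: 0 ok, 2 config error, 3 data error.

## Problem sizes used in the checks

The acceptance checks run at desk scale by choice: 10 000 sampled mask
pairs for the overlap rule, 100 random instance sets for resolution
invariants, 200 scenes for matching, 500 point-set pairs for Hausdorff,
1 000 histograms for Otsu, one 5120² frame for tiling arithmetic and
reassembly, one 1536² synthetic frame for the stitch round-trip, and an
8-nucleus 512² frame for end-to-end recovery.

## Known limitations

* The overlap rule's published wording leaves the exact-0.1 boundary and
  the pair-processing order open; the choices above are documented and
  deterministic, but other readings would occasionally differ on
  borderline pairs.
* Greedy pairwise resolution of multi-way overlaps is order-dependent by
  construction (the order is fixed and deterministic here).
* The classical density-based noise provider is a baseline, not a
  replacement for a trained semantic model on real data.
* Hausdorff on full masks penalizes area errors as well as boundary
  placement; use `boundary` mode when only contour accuracy matters.
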