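# Methods

This note records the models and procedures `spotstack` implements, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic benchmarks do and do not demonstrate.

## Data model and coordinates

A dataset couples a genes × spots integer count matrix with a spot table and
per-section images. Pixel coordinates use the raster convention: `px_x` is
the pixel column and `px_y` the pixel row, 0-based, origin top-left; the
positions file's `pxl_row_in_fullres` therefore maps to `px_y`. Array
coordinates map to physical positions with hexagonal geometry: odd rows are
offset by half a spacing in x and the row pitch is spacing·√3/2, so nearest
neighbors sit exactly one spacing apart (100 μm for Visium; `geometry="square"`
is available for legacy orthogonal arrays). Spots flagged out-of-tissue are
loaded but excluded from analysis unless asked for. Both positions-CSV
dialects (headerless v1 and headered v2) and gzip-compressed matrix/TSV
inputs are accepted; the default image is the low-resolution one with its
matching scale factor.

Datasets persist as a directory bundle in the platform layout itself (one
Space-Ranger-style subtree per section plus a JSON manifest). This keeps
bundles plain-text-plus-PNG, diffable, and guarantees the reader and writer
exercise the same code paths.

## Tissue masking

Pipeline: downscale to a 400-px working width (bilinear, anti-aliased) →
luminance grayscale (0.299/0.587/0.114) → Otsu threshold (256 bins) → a
piecewise-linear contrast normalization that maps the threshold to mid-gray
(making the downstream split insensitive to staining brightness) → isotropic
Gaussian blur, σ = 2 px → SLIC superpixels → k-means with k fixed at 2 on
per-superpixel mean features → cleanup.

Choices worth knowing:

* **SLIC** is implemented in-package as grid-seeded localized k-means
  minimizing d² = d_color² + (compactness/S)²·d_xy², colors scaled to a
  0–100 range so the conventional `compactness = 10` balances the two
  terms; 10 iterations; disconnected fragments are reattached to the
  nearest main segment afterwards. The implementation guarantees at most
  `n_segments` segments for *any* requested count (down to 2), which
  off-the-shelf implementations do not. Defaults: `n_segments = 1000`,
  `compactness = 10`.
* **Cluster features** are taken from the *unblurred* normalized image;
  the blur exists to stabilize superpixel boundaries, and blurred features
  would bleed background into thin tissue margins.
* **Which cluster is tissue:** the darker one (stained tissue absorbs
  light); the border-touching fraction is computed as a confirming cue.
  Additionally, pixels darker than the global Otsu threshold are tissue by
  definition of the light-background assumption — this union keeps the mask
  correct when nearly the whole frame is tissue and k-means is forced to
  split hairline variation.
* **Cleanup:** holes and specks smaller than 1% of the frame are
  filled/removed. This is post-processing beyond the core pipeline, added
  for robustness.
* A constant image has no Otsu threshold and raises a degenerate-image
  error rather than returning an arbitrary mask.

The pipeline is deterministic for a given seed (k-means is seeded; SLIC is
grid-seeded and seed-free).

## Serial-section alignment

Edges are the mask minus its 8-neighborhood erosion — on a binary raster
exactly the set of pixels with nonzero gradient magnitude — capped at 2000
points by a seeded uniform subsample. ICP alternates nearest-neighbor
correspondence (one-directional, source→target, KD-tree) with a closed-form
Kabsch/SVD rigid fit; the correspondence RMSD is recorded per iteration and
is provably non-increasing; iteration stops at relative improvement < 1e-6
or 100 iterations, and non-convergence returns the best iterate flagged
rather than an error.

Two structural safeguards:

* **Reflections** are handled by an explicit two-branch search (plain and
  x-mirrored source), each branch constrained to proper rotations, the
  lower final RMSD winning — never by letting the SVD flip sign freely, so
  every iterate is a valid rigid transform.
* **Global convergence:** plain ICP is local, so each branch restarts from
  a coarse sweep of initial rotations (30° steps, centroids pre-aligned).
  On the synthetic benchmark (rotations up to ±45°, translations up to
  ±50 px, random reflections) this recovers the planted transform to
  ~1e-13 px; without the sweep, rotations beyond ~15° routinely fall into
  local minima.

An optional trim fraction discards the worst correspondences per iteration
for partial-overlap cases; the default is no trimming. Images are resampled
by backward warping (output pixel samples input at T⁻¹x) with bicubic
interpolation and white fill, matching the stained-slide background; spot
coordinates are scaled into the working frame, transformed, and scaled back.

Registration accuracy against *rasterized* masks is bounded by boundary
discretization (~0.5 px staircase noise): transform parameters come back
within ~0.3° and ~2 px on 200-px frames, while analytically transformed
point sets are recovered to machine precision.

## Spot graph and spatial statistics

Spots of the same section within 150 μm (1.5× the lattice spacing) are
neighbors; the graph is symmetric, self-edge-free, and block-diagonal over
sections. On the regular lattice interior spots have exactly six neighbors.

The spatial lag is the **sum** (not mean) of neighbor expression,
`lag = expr · A`; border spots consequently have smaller lags, which is
accepted and documented. The autocorrelation ranking computes, per gene, the
Pearson correlation between expression and lag across all pooled sections
(per-section mode available); genes with zero variance in either vector are
undefined and sort last; ties break by gene identifier. Expression input is
the caller's choice of normalization — the CLI defaults to Pearson
residuals.

Region neighbors: for a target label, the inner border is the set of target
spots adjacent to a non-target spot and the outer neighbors are non-target
spots adjacent to a target spot; the two sets are disjoint by construction.

**Wilcoxon rank-sum DE.** Two-sided test per gene between two disjoint spot
groups; genes detected in fewer than `min_frac = 0.1` of spots in both
groups are skipped; log2 fold change uses means with one pseudocount;
Benjamini–Hochberg adjustment by default with a Bonferroni flag for parity
with pipelines that use it. p-values:

* both groups ≤ 8 spots: exact enumeration of all C(m+n, m) assignments of
  the observed values (ties handled naturally); the two-sided p is
  P(|U − mn/2| ≥ observed).
* larger groups: a tie-corrected normal approximation with an Edgeworth
  kurtosis correction. The rank sum is a sum of m midranks drawn without
  replacement from the pooled midranks, so its exact null variance and
  fourth moment follow from finite-population moment formulas (the
  variance term reduces to the classical tie correction, and the symmetric
  midrank population kills the skewness term). Enumerating *all* achievable
  U values shows this approximation is within 0.0024 of exact for tie-free
  groups of 5–8 (0.012 at 4 vs 4); plain normal approximation errs by up to
  0.03 there. Below ~5 per group, or with heavy ties, the null lattice is
  too coarse for any continuous approximation — which is exactly why the
  exact path owns all groups up to 8.

## Normalization and factor analysis

Pearson residuals use a negative-binomial noise model with a single global
dispersion θ (default 100): μ[g,s] = (gene total · spot total)/grand total
and r = (x − μ)/√(μ + μ²/θ), clipped to ±√(n_spots). A per-gene regularized
dispersion fit is deliberately not implemented: the global-θ residual is
fully specified, closed-form, reduces to the Poisson residual as θ → ∞, and
feeds the same downstream factorization. Count filtering is gene-first
(genes below the count threshold are dropped, then spots), so a spot can be
removed because its counts lived in dropped genes; this order dependence is
intentional.

The non-negative transform clips residuals at zero (a shift-by-minimum mode
exists behind a flag); clipping discards the "below expectation" half of the
signal but keeps the factorization sparse and interpretable.

NMF minimizes ½‖X − WH‖²_F by the classical multiplicative updates, whose
objective is non-increasing; the recorded trace is asserted against in
tests. Initialization runs FastICA with k components; each component's sign
is chosen so its positive parts carry the larger mass, and the positive
parts seed W and H. Exact zeros are absorbing states of multiplicative
updates, so zeros in the clipped initialization are lifted to a small floor
(1% of the mean positive entry) — without this the factorization freezes in
poor local minima. ICA failure falls back to a seeded random initialization,
flagged in the result. Convergence: relative objective decrease < 1e-5 or
200 iterations by default; multiplicative updates converge slowly near an
exact factorization, so reconstruction-accuracy studies use larger budgets.
On output W's columns are L2-normalized with compensating row scaling of H.
The factor count k is a required user parameter; no automatic selection is
attempted. All randomness sits behind one seed; the same seed reproduces the
model bitwise on one platform.

## Rendering

HSV multi-feature view: hue_i = i/k, saturation 1, value = the winning
feature's min-max-rescaled value (ties to the lowest index; constant
features rescale to all zeros; all-zero spots are black). Rescaling is
computed jointly across all spots of all sections so colors are comparable
between sections (per-section ranges can be supplied). The encoding is
invariant to positive per-feature rescaling.

Nuclei segmentation is deliberately simple: Otsu restricted to in-mask
luminance, dark pixels → connected components ≥ 2 px → centroids. If the two
Otsu classes differ by less than 0.15 in mean luminance the tissue is
treated as featureless and no points are returned (texture is not nuclei).
Touching nuclei are not declumped — the goal is overall morphology, not
precise per-cell segmentation. Stacking assigns section i the plane
z = i·z_spacing; no downsampling is applied (a cap flag exists).

## Synthetic data: what it emulates and what it does not

The generator produces stained-section-like images (a low-frequency Gaussian
random field thresholded at the requested area quantile as the tissue blob —
so the true mask covers the requested fraction by construction — pink tissue
with mild texture, near-white speckled background, dark ~2 px nucleus
disks), hexagonal lattices, spatially patterned counts, and known rigid
misalignments. Counts are NB(μ, θ) via gamma–Poisson with variance
μ + μ²/θ — the same parameterization as the residual model. Planted factors
are Gaussian bumps whose centers are drawn by greedy farthest-point
selection so the k patterns are distinct (coincident centers would make the
planted ground truth unidentifiable); each factor owns a disjoint gene set
(default n_genes/2k genes) with expected expression baseline·(1 + effect·pattern),
log-normal per-gene baselines around a mean of 2 counts. The
ranking-power fixture plants one bump gene and builds nulls as spatial
permutations of its counts, isolating spatial structure from expression
level. Everything is bitwise reproducible from (parameters, seed).

Reference conditions used by the test suite and the acceptance script:
masking on ten 256×256 sections (blob fraction 0.4); ICP on twenty
perturbations of a ~700-point edge set (rotation U(−45°, 45°), translation
U(−50, 50) px, reflection with probability ½); ranking power on a 500-spot
lattice with 1 + 999 genes over 20 seeds (effect 3, θ = 10); NMF on 800
spots × 200 genes with 4 planted factors over 5 seeds; Wilcoxon accuracy on
100 tie-free fixtures with groups of 5–8; the end-to-end run on the two-
section "small" preset. These sizes keep the full suite around a minute.

What passing these benchmarks does **not** show: the images lack real
staining variation (no stain separation, folds, bubbles, debris, uneven
illumination), so mask IoU ≈ 0.99 here is an upper bound on real sections;
misalignments are exactly rigid, so nothing is claimed about tissue
deformation between sections (non-rigid registration is out of scope);
planted factors are smooth disjoint Gaussian bumps, while real expression
programs overlap in genes and space; and NB counts with a single θ
understate gene-specific technical variation. The statistics
(oracle-agreement checks, exact-test accuracy) are data-independent and do
transfer.

## Known limitations

* Rigid alignment only; manual or deformable alignment must come from
  outside (a user-supplied transform JSON is accepted).
* The autocorrelation ranking has no significance calibration (no Moran's I
  / Geary's C null) — it is a ranking, by design.
* NMF with multiplicative updates finds local minima; different seeds give
  different (sign/permutation-equivalent) factorizations, and k is not
  selected automatically.
* Nuclei counts are biased down by clumping and the 2 px area floor.
* The Space Ranger reader targets the spatial outputs (counts + spatial/
  directory); it does not parse HDF5 feature matrices.
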