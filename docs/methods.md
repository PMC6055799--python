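# Methods

## The quantification pipeline

The analysis chain mirrors the standard interactive workflow for cortical-ER
micrographs, made headless and reproducible:

1. **Contrast enhancement** — optional small-σ Gaussian smoothing, then a
   monotone percentile rescale to [0, 1] clipping a stated fraction of
   extreme pixels (`saturation_fraction`, default 0.01). Monotonicity
   guarantees downstream thresholds see the same ordering of pixels.
2. **Segmentation** — either a global threshold (Otsu's between-class
   variance criterion when none is given) or a trainable three-class pixel
   classifier {ER, background, rejected}. The classifier is a seeded random
   forest over a multi-scale feature bank (per scale σ ∈ {1, 2, 4} px:
   Gaussian-smoothed intensity, gradient magnitude, Laplacian of Gaussian,
   difference of smoothings at σ vs 1.6σ; reflect boundary handling). The
   rejected class absorbs bright non-ER objects such as dye-stained
   mitochondria, which are excluded from the ER mask rather than leaking into
   it. Label budgets in tests are ~1500 px per class, drawn from phantom
   truth.
3. **Closing** — disk radius 2 px, 1 iteration (default), to repair
   segmentation gaps and restore network connectivity. Computed on a padded
   array so it remains extensive at the image border.
4. **Enclosed polygons** — background components (4-connected, the dual of
   the 8-connected foreground; this duality prevents diagonal leakage through
   a 1-px tubule) that touch neither the ROI border nor any non-ROI pixel.
   Components smaller than 4 px are slivers of rasterization or segmentation,
   not lacunae, and are not counted (`MIN_LACUNA_PX`).
5. **Cisternae** — iterated binary opening (disk radius 3 px, 3 iterations by
   default, i.e. 3 erosions then 3 dilations), which erases structures
   thinner than roughly twice the accumulated radius; surviving components
   below 0.25 μm² are dropped. All three values are configuration, echoed in
   every output, since the source workflow specifies only "several
   iterations".
6. **Skeleton and junctions** — topology-preserving 2D thinning with
   deterministic raster-order tie-breaks; cisternae pixels are subtracted so
   only the tubular network remains. Junction pixels have ≥ 3 skeleton
   8-neighbours; 8-adjacent junction pixels merge into one junction reported
   at the cluster centroid; endpoints have exactly 1 neighbour. Junction
   density is the cluster count over ROI area in μm².

   Three skeleton-hygiene steps remove well-known thinning artifacts before
   junction counting: background holes < 8 px are filled (far below any real
   lacuna; un-filled they seed spurious skeleton loops), terminal spurs of at
   most 4 px that run into a junction are pruned (genuine open tubule ends
   are kept at full length), and pixels with exactly two mutually-adjacent
   neighbours (redundant staircase-corner pixels, each of which fabricates a
   triple point) are deleted; the last two are iterated to a fixed point.
   Degree-≥3 clusters of any multiplicity count as one junction.

## Dynamics

Per-frame binarization (Otsu by default, or a fixed threshold) defines
occupancy. The **persistency composite** colours each pixel white if occupied
in every selected frame and otherwise by the latest frame in which it was
occupied (jet colormap; the colormap itself is a presentation choice). The
**CFI** of a pixel is the number of frames in which it is occupied; the
distribution over ever-occupied pixels is compared between conditions as a
per-bin frequency ratio against a control (undefined — not zero — where the
control bin is empty) plus a one-sided Mann–Whitney test on the per-pixel
values. The underlying persistency method does not fix a specific test;
the rank test is our documented choice and is configurable.

**Tracking** detects bright compact components inside an area window per
frame and links them greedily by nearest neighbour under a gate
(`max_link_px`, default 5 px/frame). Two tracks mapping to one detection log
a merge (the nearer track survives); a track whose last detection overlaps a
persisting cisterna is labelled absorbed-into-sheet. A track *moved* if its
maximum displacement from origin exceeds `d_min_px` (default 2 px) and is
*directed* if additionally its net-over-path-length straightness is ≥ 0.7.
These gates are explicit configuration: the source workflow's manual
displacement criterion is unstated, so published moved/fixed percentages are
reproduced as arithmetic on given counts, not as a recovery target.

## Statistics

The Wilcoxon rank-sum statistic uses midranks for ties. For pooled n ≤ 20
the p-value is exact by enumeration of all C(n, n_a) rank assignments
(two-sided: assignments at least as far from the null mean as observed);
otherwise a normal approximation with tie-corrected variance and a 0.5
continuity correction is used. Welch's t uses the Welch–Satterthwaite degrees
of freedom. Tests are two-sided by default (sidedness is not stated in the
comparisons being mirrored). Per-lacuna polygon areas are pooled across the
images of a group, matching how per-lacuna n is usually reported; cisternae %
and junction density contribute one value per image. Box summaries use
linear-interpolation quartiles (numpy default) with whiskers at the most
extreme points within 1.5 IQR.

## The phantom generator

The generator emulates what the quantification consumes, not ER physics:

* **Geometry** — the tubule graph is the Voronoi ridge network of blue-noise
  (Poisson-disk) seed points in the ROI: three-way-dominant junctions and
  convex-ish polygonal lacunae of fairly even size, as in cortical ER.
  Blue-noise seeding (spacing 0.72·√(area/n), relaxed if dart-throwing
  stalls) avoids the sliver cells of uniform sampling. Vertices get Gaussian
  jitter capped at 30% of the shortest incident edge (preserving straight-
  line planarity); edges shorter than `min_edge_px` (6 px) are contracted
  into single higher-degree vertices; edge pairs subtending < 30° at a shared
  vertex and non-adjacent edges closer than 4.5 px are removed (they cannot
  rasterize as distinct tubules at the rendered width, so the truth graph
  must not contain them). Bounded faces are enumerated by half-edge traversal
  of the embedding; for a connected planar graph their count equals
  E − V + 1, which the tests verify independently.
* **Rendering** — tubules are pixels within width/2 (default width 3 px ≈
  0.15 μm at 0.05 μm/px) of an edge segment; cisternae are elliptical
  patches (default radii 12–18 px ≈ 1.5–3 μm², aspect 0.75–1) anchored at
  junctions and face centroids, grown until a target ROI-area fraction is
  met (the last patch is binary-searched onto the target, achieving ±1% of
  ROI area); distractors are bright ellipses kept ≥ 2 px clear of the ER.
  Intensities (background 0.05, tubules 0.6, cisternae 0.85, distractors
  1.0) pass through a Gaussian PSF (σ = 1 px), Poisson photon noise at a
  stated peak count (default 200; 50 is the "moderate noise" condition) and
  additive Gaussian read noise (σ = 0.01) — the standard confocal
  approximation.
* **Truth** — masks are recorded pre-noise. The resolvable interior face
  count (the oracle for lacuna counting) is computed per face on the vector
  graph: polygon-fill pixels outside the rendered foreground, counted per
  4-connected component of at least `MIN_LACUNA_PX`, so a cisterna that
  splits a lacuna in two counts twice, exactly as the pixel-domain analysis
  will see it.
* **Motion** — a spatial fraction of the ROI is mobile; its vertices follow
  a discretised Ornstein–Uhlenbeck (AR(1)) displacement d_t = ρ d_{t−1} + ε,
  ε ~ N(0, s²(1−ρ²)), started at zero, giving bounded Brownian-like motion
  with stationary sd s (default ρ = 0.8, s = 1.5 px) without tearing the
  network; cisternae ride on their anchor vertices. Puncta start at
  junctions and are stationary, directed (constant velocity along a random
  direction, reflecting at the ROI) or mobile-undirected (gated random
  walk); scheduled merge/split/absorb events rewrite trajectories and are
  logged in the truth tracks. Frame 0 equals the single-frame render for the
  same spec (scene, noise and motion use separately spawned seeded streams).

Image size defaults to 256×256 at 0.05 μm/px (the source acquisitions do not
state dimensions; both are configuration). Test and validation problem sizes
— 10 recovery seeds, 12 images per group in the two-condition study, 50-frame
CFI videos, 20 puncta × 5 seeds for tracking, 500 null simulations for test
calibration — were chosen as the smallest sets at which the recovery bounds
and calibration intervals are stable across seeds.

## What the phantoms do and do not show

Phantom tests demonstrate that the pipeline recovers known geometry,
fractions, counts and motion classes under a realistic confocal noise model,
and that the statistical engine is calibrated. They do not establish
performance on real micrographs: real ER has curved tubules, intensity
heterogeneity along membranes, depth-dependent background, cytoplasmic
streaming and acquisition drift, none of which the generator emulates.
Parameters that matter on real data (thresholds, opening radius/iterations,
minimum cisterna size, tracking gates) are therefore exposed in
configuration and echoed in every output rather than fixed.

## Numerical and design notes

* All randomness flows from integer seeds through `numpy` seed sequences;
  identical spec + seed gives bit-identical images, truth and outputs.
* The generator's resolvability constraints (minimum edge length, angle,
  clearance) intentionally couple the truth graph to the rendering width:
  ground truth must be *representable* in the raster for recovery bounds to
  be meaningful.
* Cisternae-vs-truth Jaccard degrades monotonically with noise in
  expectation, but single realizations can improve slightly under mild noise
  because noise offsets a small systematic under-segmentation bias; the
  corresponding test fixes the threshold and tolerates 0.015 of
  per-realization jitter.
* Junctions covered by cisternae are subtracted together with the sheet;
  recovery is therefore assessed against truth junctions outside the
  (dilated) cisternae mask, or on cisternae-free phantoms.
* The opening with i iterations is i erosions followed by i dilations
  (equivalently, opening by a larger effective element); it is idempotent at
  one iteration and never grows with more.
* Degenerate inputs: empty ER masks yield empty-but-valid results (0
  polygons, 0% cisternae, empty skeleton); all-tied samples give p = 1 with
  a warning; zero-area ROIs and sub-pixel tubule widths are rejected.
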