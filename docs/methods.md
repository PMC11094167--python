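# Methods

This note documents the models, parameters and numerical choices behind
`spherograph`, and what the synthetic benchmarks do and do not establish
about real data.

## Problem and data model

A tumorsphere slice is a pair of co-registered 2-D intensity grids: a
nuclear stain (used only to find and localize cells) and a stemness marker
(used only to quantify per-cell marker content). Physical metadata default
to 0.12 µm/px in-plane and 2 µm slice thickness. Coordinates are 0-based
and row-major; a centroid is (x = column, y = row) in pixels. All
intensities are carried as floats regardless of the source bit depth,
since morphology and background subtraction produce non-integers.

## Marker cleaning

The marker protein is cytoplasmic and rides on a smooth diffuse background
(out-of-focus light, unbound marker in the bulk). `clean_marker` computes
the morphological reconstruction by dilation of the image from a seed
eroded with a disc (default radius 3 px) and subtracts it — the white
top-hat by reconstruction. The operation is anti-extensive (output ≤
input) and exactly removes any structure the erosion cannot suppress,
i.e. everything broader than the structuring element; punctate marker
spots survive. The erosion radius is the only parameter; 3 px was sized to
keep marker puncta (a few pixels across at 0.12 µm/px) while removing
cell-scale and spheroid-scale background. Downstream intensity sums use
the cleaned channel by default (`use_raw_marker` switches this off).

## Nuclei enhancement

`enhance_nuclei` chains CLAHE → opening → area closing → bilateral filter.
Parameter defaults (all exposed in `EnhanceParams`):

| parameter | default | role |
|---|---|---|
| CLAHE clip limit | 0.01 (normalized) | local contrast without noise blow-up |
| CLAHE tile grid | 8 × 8 tiles | neighborhood scale of equalization |
| opening disc radius | 2 px | detaches touching nuclei |
| area-closing threshold | 64 px² | fills dark intra-nuclear spots |
| bilateral σ_spatial | 5 px | denoising reach |
| bilateral σ_range | 0.1 × intensity range | edge preservation |

The operator family is fixed by the pipeline design; the sizes are this
package's choices, set to the scale of MCF-7 nuclei at 0.12 µm/px
(nucleus ≈ 10–15 µm ≈ 80–120 px across, so a 2 px opening and a 64 px²
closing act far below nuclear scale). Output is min–max normalized to
[0, 1] and the chain is deterministic.

## Segmentation

The default `classical` backend is fully self-contained: Otsu threshold
(offset configurable) → small-object removal (< 30 px²) → Euclidean
distance transform → peak seeding with a minimum separation (default
7 px, about one nucleus radius) → marker-controlled watershed. A
`pretrained` backend delegating to a star-convex CNN
(StarDist `2D_versatile_fluo`) is supported when that optional package is
installed; the classical backend is the default so the repository builds,
tests and reproduces with no downloads. Centroids are unweighted means of
member pixels. Faint out-of-focus nuclei are simply absent from the
result, not rescued. Two spheroid-membership filters are offered (radial
`enclosing_fraction` with a robust 90th-percentile core radius, and
`largest_component` on a length-pruned Delaunay graph); both drop cells
without relabeling, and neither is applied by default.

## Territories and marker sums

The territory of each cell is its Voronoi region over the cell centroids
plus `n_boundary` (default 64) artificial sites placed uniformly on a
circle of `boundary_scale` (default 1.15) times the minimal enclosing
circle of the centroids; pixels nearest an artificial site stay
unassigned, which bounds the border cells' regions. The defaults make
border-cell areas insensitive to the boundary density (asserted by test).
Pixel assignment is an exact chunked nearest-site argmin, so equidistant
pixels deterministically go to the lowest cell id. Marker content is the
cleaned-channel sum over the region; total intensity over assigned pixels
is conserved exactly. The spheroid radius is reported as the enclosing
circle's radius times the pixel size — one of several defensible radius
definitions (equivalent-area disc and farthest-cell distance being
others); it is a descriptive output, not an input to any statistic.

## Phenotype threshold

Per-cell sums below the 5th or above the 95th percentile are assigned
directly (low → differentiated, high → stem) and excluded from the fit,
because the maximum-likelihood mixture is sensitive to extremes. A
two-component Gaussian mixture is then fit (EM, full per-component
variances, fixed seed) and the threshold V solves

  w₁ N(V; μ₁, σ₁) = w₂ N(V; μ₂, σ₂),  μ₁ < V < μ₂,

i.e. the posterior-0.5 point — the unique statistically meaningful
boundary of a 2-GMM. The root is found on **log** densities: for widely
separated components both pdfs underflow to zero between the means while
the log-density difference remains a well-behaved quadratic. If the
weighted densities do not cross between the means (extreme weight
imbalance), the midpoint of the means is used with a warning. A cell is
stem iff its sum strictly exceeds V ("surpasses" ⇒ the boundary cell is
differentiated).

Numerical caveat: when the modes are separated by many component sds, the
crossing depends on the fitted σ ratio amplified by roughly
(μ₂ − μ₁)/(2σ); on a 90-sd benchmark mixture this gives the single-draw
estimator a sampling sd near 1.3 even though classification itself is
unaffected (any V between the modes classifies identically). Benchmarks
of the crossing's *location* therefore average over a fixed list of
dataset seeds. On realistically overlapping data (2–3 sd separation) this
amplification is absent.

Support checks: `elbow_cluster_count` runs k-means for k = 1..k_max and
applies the maximum-distance-to-chord rule on the normalized (k, log W)
curve — the log scale makes the rule invariant to rescaling the sums.
Because the chord rule cannot select an endpoint, an elbow-free smooth
decay (maximum normalized distance below 0.25; unimodal samples measure
≈ 0.10–0.13, bimodal ≈ 0.45) is reported as one cluster.
`model_selection_scores` reports BIC/AIC per k. `check_seed_robustness`
refits over seeds 0..19 and flags a relative spread above 5%.

## Neighbor graph and homophily statistics

The cell graph is the Delaunay triangulation of the real centroids only
(artificial sites are not cells); optional pruning of edges longer than a
multiple of the median length is off by default. Four statistics:

* **Assortativity** r = (Σᵢeᵢᵢ − Σᵢaᵢ²)/(1 − Σᵢaᵢ²) from the symmetric
  phenotype mixing matrix e (Newman's attribute assortativity);
  undefined (None) for edgeless or single-phenotype graphs.
* **Homophily ratio** — same-type edges / all edges.
* **Stem connected components** — components of the stem-induced
  subgraph; isolated stem cells are their own components.
* **Stem mean degree** — mean stem-neighbor count per stem cell,
  isolated stem cells counted with degree 0 (the inclusive convention;
  the degree histogram is also returned so the exclusive mean is
  recoverable).

All four are computed directly on edge arrays (the permutation loop
evaluates them tens of thousands of times); the test suite checks them
against brute-force enumeration and against networkx.

## Permutation null and tests

The null fixes the topology and relocates the stem labels uniformly at
random, preserving their count — 10,000 relocations by default, seeded
from one master seed. For each statistic the report gives the null mean
and sd, z = (observed − mean)/sd with a two-sided normal p (one-sided
available), significance at α = 0.001, and an empirical percentile p
with the +1 correction (the observed graph is never part of the null
sample). The ensemble sd (not a standard error) is used, since the
question is whether the observed value could be a draw from the null
distribution.

A note on centering: the assortativity coefficient is a ratio statistic
and carries a negative O(1/n) bias under label permutation (≈ −0.006 at
n ≈ 150–200). Its null mean is therefore near, not exactly, zero. The
z-test is unaffected — it centers on the ensemble's own mean — and
measured type-I rates at α = 0.001 are at or below ~0.002.

## Synthetic fixtures

The generator emulates one confocal plane through a tumorsphere at the
study scale: 100–450 cells in a disc of ≈ 100 µm at 0.12 µm/px, stem
fraction ≈ 0.3, nuclei ≈ 6 px mean radius packed by dart throwing with an
18 px minimum separation. Labels are either uniform (the null) or grown
as connected lineages from the center across Delaunay links, with
`clustering_strength` s setting the probability s/(1+s) of extending the
stem frontier versus labeling a random cell (s = 0 recovers the null;
the default s = 20 plants strong paths). Rendering: nuclei as Gaussian
blobs (σ = half the nucleus radius) plus noise; the marker as per-cell
Gaussian spots whose integrated intensity is drawn from the phenotype's
distribution (defaults 60 ± 12 vs 200 ± 20, a 10-sd separation), over a
diffuse background halo. Spots are punctate (σ = 0.75 × nucleus radius)
so the cleaned per-cell sums stay proportional to the planted draws;
wider spots bleed across neighboring territories and blur the planted
bimodality.

What the fixtures do **not** emulate: optics (PSF, z-blur, vignetting),
intensity heterogeneity within a phenotype beyond a single Gaussian,
nucleus shape irregularity, overlapping/out-of-focus nuclei, and marker
localization differences between cytoplasm and nucleus. Passing the
end-to-end benchmarks therefore shows the pipeline's stages compose
correctly and recover planted structure under clean conditions; it does
not certify segmentation accuracy on crowded real images, where the
pretrained backend exists precisely because classical watershed
degrades.

## Benchmark problem sizes

The shipped benchmarks use sizes chosen to exercise each claim while
keeping the whole suite fast on one CPU: 200-cell rendered spheroids for
end-to-end recovery; 1,000 random 150-cell graphs × 200 relocations for
type-I calibration; 100 planted-paths replicates × 500 relocations for
power; 10,000 relocations wherever a single null distribution is
reported. Larger ensembles change none of the conclusions, only the
Monte-Carlo error bars.

## Known limitations

* Single-plane analysis; multi-slice input is handled as independent
  slices plus pooled summaries (counts add; statistics are per-slice).
* The Voronoi territory is a proxy for the cell's cytoplasmic extent and
  inherits centroid errors.
* The two-component mixture is the default phenotype model; more
  components are only scored (BIC/AIC), not classified.
* Convex-hull Delaunay edges can join non-touching border cells; the
  optional long-edge pruning addresses this but is off by default since
  the reference procedure does not prune.
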