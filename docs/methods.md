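# Methods

This note documents the models implemented in `nichecircuit`, the
defaults they ship with, and the choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic landscapes and virtual species

The generator produces everything the pipeline consumes, with known
truth:

* **Climate fields.** Each layer is a smooth latitudinal or
  longitudinal gradient plus a Gaussian random field with exponential
  covariance `exp(-h/L)`, generated by spectral filtering of white
  noise (radial spectral density `2πL²(1+(2πLf)²)^(-3/2)`), padded by
  ~4 correlation lengths against periodic wrap-around and standardized.
  `L = autocorr_range` (default 2000 m on 100-m cells) is directly
  recoverable from an empirical exponential variogram — the suite
  checks agreement within 25%. Future scenarios add per-variable
  deltas to the present layers, nothing else.
* **Terrain and hydrology.** The DEM is a southward regional gradient
  with autocorrelated relief. Before D8 flow routing the DEM is
  depression-filled by priority-flood with an epsilon gradient;
  without filling, flow paths die in the random field's pits and the
  stream network never branches. Streams are cells whose flow
  accumulation reaches a threshold (default 40 cells); Strahler order
  follows the standard junction rule (equal-order confluence
  increments, otherwise the maximum propagates) and is verified against
  an independent recursive implementation. Distance-to-stream uses
  only orders ≤ 3, mirroring the exclusion of large rivers that the
  species do not use.
* **Water points, habitat, barriers.** Water points are a uniform
  Poisson scatter (default 2·10⁻⁷ points/m², i.e. ~30 on a 12×12-km
  landscape — the density of pools/springs a regional inventory might
  hold). Habitat classes are quantile slices of a smooth field. Roads
  are full-extent polylines; urban patches are disjoint discs placed by
  rejection sampling.
* **Virtual species.** The full truth multiplies a logistic function
  of two climate variables, an exponential distance-to-water decay
  (scale 800 m) and a per-habitat-class bonus, so every predictor
  family used downstream matters. A climate-only variant exists for
  evaluating the purely climatic ensemble against a truth it can in
  principle represent. Occurrences are drawn without replacement at
  the cell level with probability ∝ truth (points at cell centres), so
  sampled datasets arrive pre-thinned.

Everything is deterministic under a fixed seed (bit-identical rasters
and point sets). What the generator does **not** emulate: climate
physics and inter-variable dependence structures of real bioclimate
data, observation bias in occurrences (roads/accessibility), mixed
positional error, and real CRS handling (a single projected local CRS
is assumed). Passing tests therefore demonstrate correctness of the
machinery and recoverability under honest sampling noise — not
robustness to the biases of real occurrence data.

## Raster utilities

Slope/aspect use Horn's 3×3 kernel with edge padding; aspect is the
downslope azimuth, clockwise from north, nodata on flats. Euclidean
distance is cell-centre to cell-centre (`scipy.ndimage`
distance transform). Resampling anchors the output grid at the input
origin (bilinear for continuous, nearest for categorical layers). VIF
screening regresses each layer on the others over a fixed-seed random
sample of ≤ 10 000 jointly valid cells, iteratively dropping the
largest VIF ≥ 10; ties break by layer name for determinism. GeoTIFF
I/O stores pixel scale, tiepoint and nodata tags (plus band names in
the image description) through tifffile and round-trips values,
transform and nodata exactly.

## Ensemble niche model

Defaults: SRE quantile
q = 0.025; 10 pseudo-absence replicates × 1000 points (uniform over
cells outside the envelope; duplicate cells are disallowed — the
stricter choice, avoiding degenerate repeated rows downstream);
pseudo-absence case weight `n_presences/1000` equalizes class
weight. Learners: quadratic logistic regression (standardized linear +
squared terms; C = 100 ridge keeps separable fits defined), gradient
boosted trees (5000 trees, learning rate 0.001, depth 3, bag fraction
0.5, ≥ 10 observations per leaf; the tree count is fixed — no early
stopping), random forest (500 trees, 2 candidate
features per split, node size 5).

Spatial validation: residual Moran's I correlograms (20 equal-width
bins to half the extent diagonal) from preliminary fits; the SAR is the
smallest bin midpoint from which Moran's I stays below 0.05, and the
checkerboard block side defaults to twice the SAR. Two deliberate
refinements of the naive reading of "‖I‖ stably approaches 0":

1. the criterion is **one-sided** (I < tol). Moran's I of positively
   autocorrelated residuals is biased negative at long lags — the
   per-bin statistics share the global mean, so short-lag excess must
   be compensated — and a two-sided rule latches onto that artifact
   and returns the maximum distance instead of the autocorrelation
   range;
2. bins with fewer than 30 pairs are treated as uninformative (the
   standard correlogram support rule of thumb).

Each replicate × family is fitted on one checkerboard fold and
evaluated on the other (both orientations), giving Boyce and TSS per
model; members passing B > 0.7 **and** TSS > 0.5 (strict inequalities)
form the ensemble with weights ∝ B. Permutation variable importance is
`1 − cor(pred, pred with layer shuffled)` averaged over permutations
and normalized to percentages.

The Boyce index uses 101 moving windows of width one-tenth of the
prediction range (standard continuous-Boyce practice); windows without
background support are dropped. Note the index is itself an estimate:
with only ~100 evaluation presences spread over 101 windows its
sampling noise is substantial, which is why recovery experiments
evaluate on a large independent occurrence sample.

## Projection and extrapolation

MESS follows the classic percentile formulas per variable (negative
exactly where a variable leaves its calibration range; the calibration
sample is the model's training support). The MEDI combination rescales
each GCM's MESS by the global min/max across GCMs, adds ε = 10⁻⁶ and
normalizes to convex weights per cell; identical projections pass
through unchanged and a zero MESS range degrades to the plain mean.
No single equation is standard for this weighting step, so the
monotone convex form is isolated in a single function (`medi_combine`) for easy
replacement. Scenario enumeration is the plain Cartesian product in
(year, SSP, GCM) order.

## Fine-scale overlay

Weights default to ENM 0.40, habitat 0.20, distance-to-stream 0.15,
distance-to-water 0.15, slope 0.05, aspect 0.05 (an ENM-dominant,
habitat- and water-heavy expert prior; fully overridable). Curve families are fixed
per predictor — exponential decay for distances, Gaussian for slope,
circular Gaussian (angular distance) for aspect — rather than
auto-selected, for reproducibility. Continuous transforms fit the
binned occurrence/background frequency ratio by least squares and are
rescaled so their maximum over the background range is 1; categorical
scores are frequency ratios rescaled to a maximum of 1 (classes absent
from the background score 0 with a warning). The overlay is a weighted
arithmetic mean with nodata propagation; future projections replace
only the ENM layer.

## Connectivity

The Keeley-style negative-exponential transform with c = 4 maps
suitability to resistance on the [1, 100] scale customary for that
transform family. The grid graph uses the 8-neighbourhood with
average-resistance edge weighting and √2 diagonal division — the
convention of the reference circuit-theory tool. Focal nodes are
occurrences snapped to cells (coincident points collapse; a
zero-distance pair would be meaningless). Pairwise solves ground one
focal node, factorize the reduced Laplacian once (sparse LU) and reuse
it for all injections; per-cell current is half the summed absolute
edge currents (the full 1 A at the two focal cells) and pairs
accumulate. Kirchhoff balance at non-focal nodes holds to 10⁻⁸
(verified against a dense pseudoinverse oracle). A configurable pair
cap with deterministic, evenly spaced subsampling keeps large node
sets tractable — the full quadratic pair count of a few hundred nodes
is beyond a desk-scale run, and synthetic defaults use ≤ 30 nodes.
Cumulative maps keep raw sums; a per-pair mean is available for
comparisons across node sets of different size.

## Change and hybridization indices

SCCI is the normalized difference `(C_fut − C_cur)/(C_fut + C_cur)`:
the simplest form with the required anchor behaviour (+1 pure gain,
−1 total loss, 0 corridor maintenance). Cells with zero current in both
scenarios are set to 0 (maintenance semantics), not nodata. Percent
connectivity change is the percent change of *mean* cumulative current
inside the range mask (mean-based; when summarizing many scenarios
the median is worth reporting alongside, as the two diverge under
skewed current distributions). Centroid shifts use the
suitability-weighted mean of cell centres, with azimuth clockwise from
grid north. The sympatry zone is the range intersection with a 50-km
buffer around its centroid; the joint resistance layer averages the
two species' SDMs inside the buffer and the pairwise solver runs on
all occurrences of both species indistinctly.

## Problem sizes and numerical choices

The recovery experiments in the suite use a 200×200 landscape
(100-m cells), 150 training presences, 3 pseudo-absence replicates and
an independent 1000-point evaluation sample — sizes at which the full
chain runs in minutes on one core while leaving the statistical
behaviour of each stage visible. Sparse solves use LU factorization
(effectively exact; the 10⁻⁸ conservation tolerance is dominated by
rounding); quantiles are linear-interpolation (type 7); curve fits
fall back to their initial guess with a warning if the optimizer fails
(relevant only for degenerate frequency profiles). Degenerate inputs
raise informative errors rather than returning silent defaults:
constant rasters cannot be normalized, flat DEMs have no drainage,
single-class datasets cannot be fitted, disconnected focal nodes name
their components.

## Known limitations

* The MEDI weighting and the SCCI closed form are derived from their
  required anchor behaviour rather than from a canonical equation;
  both are isolated behind single functions for easy replacement.
* The ENM models climate only; a virtual species with non-climatic
  preferences caps the achievable correlation between ensemble and
  truth (the fine-scale overlay exists precisely to close that gap).
* No reprojection: all layers must share one projected CRS and grid.
* Boyce-based member selection is noisy at small test-fold sizes; with
  few presences expect replicate-to-replicate variability in which
  models pass the strict gates.
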