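# Methods

This note records the models, conventions and numerical choices behind the
package, in the order the pipeline applies them.

## Binarization and patching

Otsu's threshold is computed once per whole image, never per patch, so all
patches of an image share one binarization; pixels strictly above the
threshold become the white (signal) phase.  Empty borders are trimmed to
the white bounding box before padding, which keeps the exterior background
component as small as possible.  Padding is black, added on the bottom and
right only, so pixel coordinates of the original image — and hence patch
origins — are preserved.  Tiles are taken row-major with stride equal to
the patch side (300 px by default), so they partition the padded image;
tiles containing no white pixel are discarded.  "Background" and
"micro-hole" are the same phase in a binary image: the distinction is
purely geometric (the background is usually the largest black component and
surfaces as the essential class, below).  Multi-channel images are rejected
rather than silently converted, because channel-mixing conventions would
silently change thresholds.

## Signed Euclidean distance transform

Distances are measured between pixel centres: a black pixel orthogonally
adjacent to a white pixel has value −1, not −0.5.  No half-pixel boundary
offset is applied; this is the plain reading of "distance to the opposite
phase" and makes the inscribed-radius recovery testable at ±1 px.  A
consequence is a small positive bias in recovered radii (the nearest
opposite pixel centre lies slightly outside the true disk boundary), which
stays below one pixel.  Single-phase patches yield an all-±∞ sentinel field
with a degeneracy flag instead of an error, so degenerate patches flow
through the pipeline as empty diagrams.

## Cubical persistence

The complex is the V-construction: pixels are 0-cells, orthogonally
adjacent pixels are joined by 1-cells, and 2×2 blocks whose four edges are
present are filled by 2-cells; a cell's filtration value is the maximum of
its vertices (lower-star rule).  Sublevel components are therefore
4-connected, and the test oracle uses the same convention.

Ties in the filtration value are broken by flat pixel index: all
computations use the *rank order* of pixel values, which makes every cell's
entry time unique.  Any valid tie-break yields the same diagram multiset
(asserted in tests by transposing inputs); pairs whose birth and death map
to equal values are zero-persistence artefacts of the order and are
discarded before any statistic.

H0 is computed by Kruskal-style union-find over the edges in rank order
with the elder rule: a merge kills the younger component and emits the pair
(younger component's birth value, edge value).  The birth pixel of a
component is its minimum vertex.

H1 uses planar duality rather than boundary-matrix reduction: a 1-cycle in
the sublevel complex encloses a bounded component of the not-yet-included
squares, so running the filtration backwards (from the largest value down)
turns loop deaths into dual-component births (at the enclosed region's
maximum face value) and loop births into dual merges (at the separating
edge's value).  One union-find pass over the dual face-adjacency graph —
with a single extra node for the unbounded face, which is the eternal elder
— yields all H1 pairs.  For 2-D cubical sublevel filtrations with field
coefficients this is equivalent to matrix reduction (the 2-element field
makes orientations irrelevant) and runs in near-linear time; a 300×300
patch takes well under a second.  The H1 birth pixel is the higher-valued
endpoint of the separating primal edge.

Exactly one H0 class never dies: the component of the global minimum.  It
is stored separately with death = +∞ and excluded from every statistic,
since on real trimmed samples the deepest SEDT minimum is almost always the
exterior background region, not a biological hole.  The generator's
`border` option reproduces this situation synthetically.

Correctness is established against an independent oracle
(`oracle_betti_curve`): for small fields the sublevel complex is built
explicitly and β0 is counted by 4-connected labelling, β1 by the Euler
formula β1 = β0 − (V − E + F).  The acceptance suite checks diagram
points-alive counts against the oracle at every distinct filtration value
of 100 random fields, exactly.

### Quadrant conventions

Boundary cases, which the underlying theory leaves free on a measure-zero
set: quadrant 1 is b ≥ 0 and d > 0; quadrant 2 is b < 0 and d > 0;
quadrant 3 is b < 0 and d ≤ 0.  The laws "no H0 in Q1", "no H1 in Q3" and
"Q4 empty" are theorems for SEDT filtrations (every white pixel has a
strictly smaller neighbour on the lattice path towards its nearest black
pixel, so white pixels never found components; loops born below 0 enclose
white pixels, so they die above 0) and are asserted at runtime: a violation
raises, because it can only be a bug.

## Persistence statistics

All statistics are computed on raw signed coordinates (H0-Q2 births are
negative; "more negative mean birth" = larger holes).  Only the two
threshold counts convert birth to radius r = −b; the threshold defaults to
2 px and is configurable.  Conventions: persistent entropy uses the natural
logarithm (so uniform lifetimes give ln n); quartiles use linear
interpolation between order statistics; standard deviations are population
ones (ddof = 0), so a single-point quadrant yields 0 rather than a missing
value.  Empty quadrants yield n = 0, total persistence 0, and NaN for
entropy and moments; NaNs propagate to the test and classifier layers,
which exclude those patches with a logged count.

The canonical panel has 28 statistics (per quadrant: count, entropy, five
birth moments, six death moments; plus the two H0 radius-split counts).
The computed table additionally carries the 75th birth percentile and the
total persistence per quadrant as extra columns.

## Permutation tests

The unpaired test statistic is |mean(A) − mean(B)|, making the test
two-sided to match the symmetric "identical distributions" null; a signed
one-sided variant is available (`absolute=False`).  Shuffles re-assign the
pooled patch values to groups of the original sizes; the pseudo p-value is
the proportion of shuffles at least as extreme as the observed value, ties
qualifying, with no add-one correction — p = 0 is reportable and means
"below 1/n_shuffles".  A useful exact fact: with m shuffles, this
procedure's null rejection rate at level α is (⌊αm⌋ + 1)/(m + 1) — about
0.0509 at m = 1000 — which the calibration tests account for by using
enough replicates.

The paired modality test forms per-patch differences d, flips each pair's
sign independently with probability ½ per shuffle, and compares
|mean(d)/sd(d)| two-tailed.  Zero-variance differences: all-zero d gives
statistic 0 and p = 1 (every shuffle ties); constant non-zero d gives an
infinite statistic, and infinite shuffled statistics count as ties.

BH adjustment is applied per family, one family per (comparison, modality)
pair, the paired modality comparison forming its own family.  Patches are
treated as exchangeable units; within-sample (per-animal) correlation is
ignored — a deliberate simplification that anti-conservatively narrows the
tests when patches within a sample are correlated, and the main statistical
caveat when interpreting real-data p-values.

## Classification

RBF-kernel SVC with C = 3 and the scale heuristic for the kernel width;
features are standardised with a `StandardScaler` fitted on training folds
only, inside the CV loop, because an RBF machine on raw heterogeneous
scales (counts vs entropies vs pixel distances) is degenerate.
Stratified k-fold (default 10) is re-randomised each repeat; metrics
(accuracy, precision, recall, F1 with the test condition "KO" as positive
class) are averaged over folds, then repeats.  The 10-feature panel uses
H0-Q2 count, entropy, mean/median/sd of births and deaths, the 25th birth
percentile and the 75th death percentile; the 20-feature panel adds the
same ten from H1-Q1.  IQRs, the 25th death percentile and the radius-split
counts are excluded as redundant with included features.

## Synthetic data

The generator emulates binarized bone patches: a white canvas with black
disks, hole count ~ Poisson(λ), radii ~ Normal(mean, sd) clipped at 1.5 px,
centres rejection-sampled to honour a minimum boundary-to-boundary gap.
The rasterization rule (black iff the pixel centre is within r of the disk
centre) makes each hole's largest inscribed circle exactly r, so recovery
tests run at ±1 px.  Group presets: the control-like group has λ = 40
holes of radius 3 ± 0.8 px at ≥ 8 px spacing on 300×300 canvases; the
test-like group halves the count, doubles the radius and doubles the
spacing (λ = 20, 6 ± 1.6 px, ≥ 16 px) — the direction and rough magnitude
of the pathological-vs-control contrast in the cortical-bone setting this
method targets.  Study-scale datasets use 50 patches per group and 3 sample
ids per group.

What the generator does *not* emulate: irregular (non-circular) hole
shapes, connected hole networks (quadrant-3 points appear only in dedicated
dumbbell fixtures), intensity noise and uneven illumination before
thresholding, spatial correlation between patches of one sample, and the
modality-specific texture of SHG vs TPaF.  Passing the synthetic suite
therefore demonstrates the correctness of the measurement chain and the
statistical machinery, not the biological effect sizes of any real imaging
study.

## Problem sizes and budgets

The default verification runs use: 100 random ≤15×15 fields for oracle
equivalence (every distinct filtration value checked), 4000 replicates for
null calibration of the permutation test (1000 shuffles each), 200
replicates of 28-statistic families for FDR control, 50 patches per group
at 300×300 for the end-to-end power check with 10 CV repeats, scaled down
from the 100 repeats the classifier defaults to.  These sizes were chosen
so the whole suite completes in a few minutes on one core while leaving
every Monte-Carlo bound several standard errors away from its threshold.

## Known limitations

- 2-D only; no anisotropic pixel spacing; no Manhattan/geodesic transforms.
- Persistence uses a single scalar filtration; original greyscale
  intensities beyond the threshold are not used.
- The exterior background is a black-phase component like any hole;
  trimming mitigates but does not remove it (it is the essential class).
- p-values on real data inherit the exchangeable-patches assumption above.
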