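# Methods

This note documents the models, algorithms and numerical choices behind
`phenoshoot`, and what its validation on synthetic data does and does not
demonstrate.

## Segmentation

Frames come from a chamber with a fixed homogeneous background, so
segmentation is background subtraction followed by color gating:

1. *(optional)* registration of the frame onto the plant-free background:
   ORB features matched with cross-checking, similarity transform
   (scale + rotation + translation) estimated by RANSAC. Off by default —
   synthetic frames are already aligned; enable it (`register=True`) for
   chambers with zoom changes. Fewer than three reliable matches raises
   `RegistrationError` and the caller may proceed unregistered.
2. frame differencing: foreground where the max-channel absolute
   difference exceeds `difference_threshold` (default 15/255; the
   threshold is an engineering default, chosen so faint plant edges
   survive while uniform background noise does not).
3. green-pixel superimposition: inside the rough foreground, only pixels
   whose hue falls in the green band (default [0.17, 0.45]) keep their
   values; soil, pot film and lighting residue are zeroed.
4. HSV binarization with the plant band hue 0.051–0.503, saturation
   0.102–0.804, value 0.000–0.786 (all in [0, 1]); exactly black pixels
   are never foreground.
5. morphological cleanup: erosion (disk r=1) removes specks, dilation
   (disk r=2) regrows the survivors, and the result is intersected with
   the input mask so true boundaries are not displaced — a
   reconstruction-style opening. Interior holes no larger than the
   dilation disk are filled, components under 50 px² dropped, and the
   largest 8-connected component kept. The composed `segment()`
   additionally intersects with the HSV mask at the end, so its output is
   always a subset of `hsv_binarize(image)`; a hole filled between two
   near-touching strokes is therefore reopened in the final mask and is
   instead resolved downstream in the skeleton graph (see pinhole loops).

A plain erosion-then-dilation with unequal radii would shift every
boundary outward by ~1 px, which on a 5-px-wide stroke plant costs tens of
percent of mask IoU; the intersection step is what keeps the pipeline
faithful to thin architectures.

## Skeleton graph

The mask is thinned with scikit-image's skeletonization, followed by a
local pass that deletes simple pixels inside any fully-set 2×2 block, so
the skeleton is strictly one pixel wide. Pixel adjacency is 8-connected,
with one refinement: a diagonal link between two skeleton pixels that also
share a set 4-neighbor is dropped. Without this, every staircase corner
forms a spurious 3-cycle and junction detection degenerates.

Graph construction: nodes are skeleton pixels of degree ≠ 2, edges are the
maximal degree-2 chains between them; edge length counts diagonal steps as
√2. Edge paths partition the skeleton pixels.

Pruning iterates to a fixpoint:

* **spurs** — edges with a degree-1 endpoint (never the bottom-most node)
  and length ≤ 10 px are removed. 10 px is the threshold at which boundary
  noise branches disappear while genuine just-emerged leaves (which
  elongate ≥ ~15 px/day) survive.
* **pinhole loops** — a tiny unresolved hole in the mask makes the
  skeleton encircle it; after collapse this is a pair of short parallel
  edges (or a short self-loop), of which the longer branch ≤ threshold is
  dropped.
* **junction clusters** — junction-junction edges ≤ 3 px (thinning
  artifacts at wide junctions) are contracted, re-routing paths
  pixel-exactly.
* **degree-2 collapse** — redundant nodes left by the above are removed
  and their edges concatenated.

Typing: base = bottom-most node (leftmost on ties); remaining degree-1
nodes are tips, degree-≥3 nodes junctions; tip-terminated edges are
leaves, the base-incident edge is the stem's base segment, and
junction-junction edges are inter-junctions. A pre-junction seedling is a
single base-tip edge; the tip rule counts it as one leaf (the first
blade), controllable via `seedling_counts_leaf`. Cyclic graphs (leaf
crossovers / self-occlusion) are refused by classification; the pipeline
logs such frames as unanalyzable. This is deliberate: measurements taken
across a crossover would be silently wrong.

Leaf tracking across days matches detections to known leaves by the
smaller of junction distance and tip distance (radius 20 px by default),
breaking ties by tip proximity; the first appearance day fixes a leaf's
emergence rank (bottom junction first on the first day), and a leaf absent
on one day keeps its rank and is flagged missing.

## Holistic phenotypes

Hull area is the area of the convex polygon of foreground pixel centers
(Qhull); the bounding-rectangle height is the row extent; the minimum
enclosing circle is computed on the hull vertices (shapely). Because pixel
centers are used, continuous-geometry comparisons carry a ~2%
discretization tolerance (a filled n×n square yields (n−1)²). View
selection takes the side view with the larger hull area; the equal-area
tie — undefined under two strict inequalities — resolves to 0°. All three
ratios are scale invariant up to discretization.

## Component phenotypes

Each leaf's ordered junction→tip path is fitted with a least-squares
polynomial of the dependent on the independent image coordinate, the
independent axis being the one with greater extent along the path (so
near-vertical leaves are fitted as x(y)). Numerical choices that matter:

* **Fit domain.** The polynomial is fitted over the centered, scaled
  abscissa u = (x − mean)/half-range. Raw pixel abscissae reach several
  hundred, where x⁶ ≈ 10¹⁶ makes high-order coefficients meaningless and
  second derivatives (curvature) pure noise.
* **Order.** Default maximum order 6, capped by point count and distinct
  abscissae. Order 4 systematically under-resolves the steep region near
  the collar and loses ~4% of arc length on realistic leaf shapes; order 6
  recovers it without overfitting the pixel staircase (the fit is a
  smoother, not an interpolator).
* **Collar mixing zone.** Inside the stroke overlap of stem and leaf the
  skeleton shortcuts across the wedge between the two center-lines. Path
  points within 2.5× the mask's stroke half-width (median distance
  transform along the skeleton, carried on the graph) of the junction are
  excluded from the fit; integration bounds are unchanged.
* **Collar re-anchoring.** The skeleton branch node sits a few pixels up
  the stem from the true collar, which pivots the junction-tip chord and
  biases chord-referenced quantities (enclosed area most of all). Before
  measurement the junction is moved to the fitted curve's closest approach
  to the extracted stem path, with the displacement bounded (12 px) and
  snapping only within 3 px of the stem.

Measurements: leaf length is the arc-length quadrature of the fitted curve
between junction and tip abscissae (relative tolerance 1e−6); the integral
leaf-skeleton area is exact polynomial integration of (curve − chord),
reported as an absolute value since a leaf dipping below its chord would
otherwise go negative. Curvature is evaluated analytically from the fit;
the apex is the path point (possibly several, ties within 1e−9 relative)
at maximal absolute perpendicular distance from the chord — the absolute
value matters because a downward-arching leaf would otherwise put the
"maximum" at an endpoint. The mid-leaf point is the 1-based index
max(1, ⌊n/2⌋) of the n-point path, evaluated on the fitted curve; a
finite-difference alternative (circumcircle through the mid point and its
two neighbors, Menger curvature) is available behind
`method="finite_difference"`. The leaf-junction angle
|atan((m₂−m₁)/(1+m₁m₂))| is folded into [0, π/2], with 1+m₁m₂=0 mapping
to π/2. The stem angle regresses the horizontal on the vertical
coordinate of the junctions, so a perfectly vertical stem has slope 0 and
φ = |atan m| measures deviation from vertical; it needs ≥ 2 junctions.

## Detection scoring

Ground truth follows the UNL-CPPD XML dialect (`plant` → `id`, `base{x,y}`,
`leaf{id, status, tip{x,y}, collar{x,y}}`, statuses alive/dead/missing;
coordinates serialized as integer pixels, so write∘read is the identity).
Detected tips are assigned to alive/dead ground-truth tips one-to-one by
optimal assignment over tip distances with pairs beyond 15 px
inadmissible; `missing` leaves are excluded from the matchable set and
from N_G. The assignment formulation (rather than nearest-first greedy)
guarantees agreement with brute-force enumeration on small instances.
Plant-level accuracy is the per-image mean of (N_d − N_f)/N_G; the
aggregate ratio (ΣN_d − ΣN_f)/ΣN_G is also provided, since published
per-sequence values are consistent with either up to rounding. A frame
with N_G = 0 makes the ratio undefined and is an error unless explicitly
excluded.

## Effects model

For each day and response, ordinary least squares on
y = μ + α_block + γ_genotype + ε under reference coding (first block and
first genotype fixed at zero — the "benchmark" parameterization).
Standard errors come from the residual variance; contrasts α_a − α_b and
γ_a − γ_b carry t-based 95% intervals with the residual degrees of
freedom. Days are fitted independently; no longitudinal correlation
structure and no multiple-testing correction are imposed. Rank-deficient
designs (e.g. a genotype confined to one block) raise an error naming the
aliased effects; `genotype_series` skips such days with a warning. The
identifiability constraint for blocks is reference coding as well — the
natural companion to the genotype benchmark.

## Synthetic data: what it emulates, and what it does not

The generator produces maize-like stick plants at 420×560 px (roughly
1/16 the linear resolution of a real chamber): a near-vertical stem
(|tilt| ≤ 0.12 rad), leaves emerging on alternating sides with leaf 1 on
day 1 and gaps of 2–3 days, collars spaced 22–30 px up the stem,
elongation 15–25 px/day to mature lengths of 90–130 px, stroke width
5 px, plant color HSV (0.33, 0.55, 0.55) inside the segmentation band and
background (0.60, 0.25, 0.92) outside it. Each leaf center-line is a
quadratic Bézier scaled so its arc length equals the scheduled length
exactly; chord length and the curve–chord enclosed area (2/3 of the
control-triangle area) are likewise closed-form, giving every downstream
measurement an analytic oracle. Specification sampling rejects layouts
whose center-lines come within 2.2 stroke widths of each other away from
the stem (the no-crossover guarantee) or leave the frame; an explicit
crossover builder exercises the cycle-refusal path.

The visible stem ends at the topmost emerged collar (the rolled
pseudostem of young maize). A consequence worth knowing: the topmost
collar has skeleton degree 2 and collapses, so the newest leaf's detected
path temporarily includes one internode until the next leaf emerges above
it — leaf counts stay exact, and only that one leaf per frame carries a
biased length.

Passing the synthetic suite shows the geometry pipeline is correct and
well-calibrated at this scale; it does not show robustness to blade
width variation, curled or senescent leaves, shadows, soil clutter,
anti-aliased edges or self-occlusion, none of which the renderer
emulates. Real-chamber imagery should be validated against
human-annotated ground truth.

## Validation suite sizes

The reproduction script and the acceptance tests run the full pipeline on
50 seeded plants × 20 days (1000 frames), 1000 random count vectors for
the accuracy formula, 100 random XML records, and 1000 Monte-Carlo
replicates for CI coverage (pooling all non-reference coefficients). These
sizes give stable statistics (e.g. the length-error median is computed
over ~4000 matched leaves) while keeping a full run to a few minutes on
one CPU.

## Known limitations

* Occluded and crossing leaves are detected and refused, not resolved.
* The whorl-top bias above affects the newest leaf until the next
  emergence; median statistics are unaffected.
* Enclosed-area recovery is chord-sensitive: a 2–3 px collar estimate
  error moves an individual leaf's area by ~10%; lengths are far less
  sensitive (≤ 4% per mature leaf on the synthetic suite).
* Top views are supported as a separate input channel for PAR; the
  synthetic top view is a schematic disk of the plant's lateral spread,
  not a projection.
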