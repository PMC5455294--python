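# Methods

## The measurement model

A seed is represented by its binary silhouette: a raster mask with a
physical pixel size plus the closed polygon contour in µm (both carried;
the polygon is authoritative for area/perimeter, the raster for
skeleton-based measures). Six descriptors are computed per seed:

* **surface** — shoelace area of the contour polygon. The raster estimate
  (pixel count × pixel_size²) is kept as an internal consistency check and
  a >5% disagreement is treated as a corrupt silhouette.
* **profile** — contour arc length. When a silhouette is built from a mask
  alone, the marching-squares contour is smoothed with a periodic Gaussian
  (σ = 2 vertices); this calibration holds a rasterised disc's perimeter
  within 2% of 2πr for radii ≥ ~8 px, suppressing the staircase bias that
  would otherwise inflate perimeters by up to ~8%.
* **rectangle a / b** — sides of the minimum-area oriented rectangle
  (rotating calipers over the convex hull). Object-oriented, not
  image-aligned, so the descriptor is rotation invariant; a is the longer
  side.
* **angle of curvature γ** — the total angular bending of the seed's long
  axis. The medial path is the longest geodesic through the
  distance-transform skeleton (`medial_axis`; plain thinning sits ~2 px off
  the true ridge and biases the later circle fit). An algebraic (Kåsa)
  circle is fitted to the path after trimming half a band-width of arc
  length from each end (raster skeletons fork near the end caps, and the
  fork segments leave the medial circle). γ is then the angular extent of
  the *full contour* around the fitted centre minus the two cap half-angles
  asin((w/2)/r), with the band half-width w/2 read off the distance
  transform peak — this sidesteps the end-erosion of skeleton paths, which
  would otherwise bias γ low by 5–15°. Paths whose sagitta is below 3 px
  are treated as straight (the circle fit is rank-deficient on a line) and
  γ falls back to the heading change between the first- and last-quarter
  chords. Recovered γ is within ±5° of truth across the renderable range
  (typically within ±1.5° away from the 0° boundary); compact blobs with no
  linear skeleton get γ = 0.
* **pits** — the number of pit-lattice cells crossed by the medial path
  ("middle row"). Lattice polylines are classified transverse vs
  longitudinal by comparing their midpoint's and endpoints' distances to
  the medial path; transverse boundaries are ordered along the fitted arc
  (each boundary angle mapped to the 2πk branch nearest the path's
  unwrapped angular span, which keeps horseshoe seeds ordered correctly)
  and each consecutive pair whose mid-cell probe lies inside the silhouette
  counts as one cell. Missing lattices raise a distinct error rather than
  returning zero.

Invariants maintained and tested: positivity, a ≥ b, the isoperimetric
inequality P² ≥ 4πS, rotation invariance within 2% (pits exact, γ ±5°),
scale equivariance across pixel sizes.

## The synthetic seed family

Seed bodies are modelled as constant-width bands whose medial axis is a
circular arc of length L subtending γ, with semicircular end caps — the
simplest family spanning the observed curvature range (0–~350°) with exact
closed forms:

    area = L·w + π(w/2)²        perimeter = 2L + πw

(the inner and outer arcs sum to 2γr = 2L regardless of γ). Two
self-overlap conditions are rejected explicitly: curvature radius r ≤ w/2,
and — for strongly curved bands — end caps colliding across the horseshoe
gap (2r·sin((360°−γ)/2) < w). Within those limits the closed forms are
exact for the polygon and hold within 2% for the raster at w/pixel ≥ 8.
The pit lattice partitions the band into n equal arc-length cells along the
middle row; two longitudinal boundaries (three transverse rows) are
cosmetic. The rectangle ground truth comes from a brute-force orientation
sweep (0.1° steps over ≥10⁴ contour samples), deliberately independent of
the rotating-calipers implementation it validates.

## Trait-table sampling from range cards

Each species' printed description gives, per trait, the quartet
(outlier-min, q25, q75, outlier-max) under the 1.5·IQR whisker convention.
Samples are drawn from a normal with mean (q25+q75)/2 and σ = IQR/1.349
(the normal IQR relation), truncated to the outlier bounds; pit counts are
rounded to integers ≥ 1. For two-sided cards the truncation sits at ±2.7σ,
so sampled quartiles reproduce the card core within 2% and the sample SD
sits ~3% below σ. Four descriptions print no lower outlier bound
(brochonii, triandra and alsinastrum angles; gussonei pits); those cards
store outlier-min = q25, making the sampler half-truncated there — sampled
lower quartiles then sit above the printed q25, which is the stated
convention's honest consequence, not a calibration target.

The cards describe only length, width, angle and pits. Surface and profile
are derived per seed from an arc-band proxy: an effective band width that
shrinks as the seed curls (for U-shaped seeds the box width reflects the
curl diameter, not the band thickness), a medial-axis length interpolating
between capsule and curled-arc geometry, the capsule closed forms, and
multiplicative log-normal scatter (4% / 3%), clipped to the isoperimetric
bound. No published values constrain these two columns (only SDs of the
real data are printed); they exist to give the six-trait statistics
realistic, partially redundant size variables — which they do: on sampled
tables surface and profile show low tolerance and small F-to-remove,
matching the qualitative pattern of the real tables.

What the generator does **not** emulate: measurement error of real SEM
segmentation, within-population substructure, non-normal or skewed trait
distributions, and any correlation between the four card traits beyond
what the key thresholds induce. Passing tests therefore demonstrate the
correctness of the machinery, not field-accuracy of identification rates.

## Discrimination statistics

All statistics are computed from the scatter matrices directly:
Λ = det **W**/det **T**; Rao's F with df1 = p(g−1),
s = sqrt((p²(g−1)²−4)/(p²+(g−1)²−5)) (s = 1 when degenerate), and
df2 = s[(N−1)−(p+g)/2] − (p(g−1)−2)/2 floor-truncated to an integer —
truncated df2 is also used inside F, matching the classic implementations
(with p = 1 the formula collapses exactly to one-way ANOVA). Partial Λ per
trait is the ratio of the full model's Λ to the model without the trait;
F-to-remove = ((1−Λp)/Λp)·((N−g−p+1)/(g−1)); tolerance is 1 − R² of the
trait on the other traits under the pooled within-group correlation
(tolerance + R² = 1 is asserted to 1e-9). Canonical variates solve
**B**a = λ**W**a, scaled to unit pooled within-group variance, signs fixed
so each variate's largest coefficient is positive (Λ = Π 1/(1+λᵢ) is
cross-checked on every fit). Classification uses linear discriminant
scores with equal priors by default (proportional available) and
resubstitution counting; percentages are rounded half-up to integers as in
the published tables. Singular within-group scatter raises an error that
points at the tolerance column.

UPGMA clusters D = sqrt(D²) by default (a flag selects D²; the choice is
recorded on the tree), with size-weighted averaging and deterministic
lexicographic tie-breaking, so the merge sequence is invariant to input row
order. Classical MDS double-centres −½D² and keeps the top-k eigenpairs,
padding with zeros (and warning) when fewer positive eigenvalues exist;
axis signs follow the same largest-coordinate-positive convention. The
"MDS of a correlation matrix of Mahalanobis distances" phrasing that
sometimes accompanies such plots is not a standard construction; this
package performs classical MDS on D.

## Nonparametric tests

Kruskal–Wallis H is computed from average ranks with the tie correction
1 − Σ(t³−t)/(N³−N) and referred to χ²(g−1); all-tied samples return
(H=0, p=1). Pairwise letter codes run the two-group test per trait at a
flat α = 0.05 with no multiple-testing correction by default (a per-pair
Holm option exists), matching the published tables' convention. A design
caveat, verified by full enumeration: at n ≤ 8 the χ² approximation tracks
the exact permutation p within 0.02 only in the significance tail
(p ≲ 0.06); mid-distribution it can sit ~0.1 off because the exact
distribution is granular (70 labelings for a 4/4 split). The letter-code
machinery only consumes the tail, and tests assert exactly that regime.
Quartiles use linear interpolation; whiskers are the most extreme data
within the 1.5·IQR fences.

## The identification key

The ten couplets are data (trait, comparator, threshold, outcomes),
validated acyclic with all ten species reachable; the longest route is
1→2→3→5→6→7 (six couplets). Couplet 4's printed predicates ("< 17" /
"≥ 18") leave pit count 17 unassigned; it is routed to *E. brochonii*,
consistent with couplet 5's "≤ 17", and the decision path carries a
warning. Key "length"/"width" map to rectangle a/b — the only measured
length/width descriptors. Parenthetical outlier values are excluded from
key logic and used only for the 0.5-credit band of the range-compatibility
score. All ten card midpoints identify themselves through the key (10/10).

On card-sampled seeds (50 per species) the key is 78–82% accurate and its
heaviest confusions are dominated by the classically confusable pairs
(hexandra–macropoda, campylosperma–hydropiper, gussonei–hungarica). Two
further confusions are structural consequences of threshold placement:
alsinastrum angle draws above couplet 6's 60° (its core reaches 56°) fall
to hexandra/macropoda, and campylosperma pit draws below couplet 8's 30
(its q25 is 31) fall toward hungarica — while alsinastrum–orthosperma
confusion is nearly impossible for the key itself, since alsinastrum pits
cannot reach couplet 2's 30. The confusion structure of the *key* is thus
close to, but not identical with, that of seed-trait overlap at large.

## Geodesy

Great-circle distances on a sphere of radius 6371 km; the published
"approximate" distances match this within 1%, so no ellipsoid is used. A
species sampled at three sites gets the mean of the three pairwise
distances (this, not the maximum, reproduces the published three-site
values). One bookkeeping note: the published per-population seed counts sum
to 1,262 with gussonei at 150, while the classification matrices use
gussonei n = 148 (total 1,260); the reference datasets keep each table's
own values.

## Problem sizes and numerical choices

Synthetic statistical tests use 10 species × 30–50 seeds; silhouette
round-trips use 2 µm/px rasters (masks ~200–500 px across) and 100
randomized parameter draws for the generator↔morphometry property, sizes
chosen to exercise every code path with comfortable margins over the
stated tolerances. Scatter matrices are guarded by a 1e12 condition-number
limit; circle fits are linear least squares; all randomness flows through
seeded `numpy.random.Generator`s, and trait sampling is reproducible
bit-for-bit under a fixed seed.
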