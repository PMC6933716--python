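# Methods

This note documents the models, conventions and numerical choices behind
`paniclepheno`, and what the synthetic-data generators do and do not
emulate.

## Imaging model and pre-processing

Frames are assumed to come from a black-interior chamber under constant
light, with the panicle held still while two cameras rotate around it
(one frame per 6°, 120 frames per session). Background removal is a
single fixed HSV threshold applied identically to every frame of every
session: hue 0–1, saturation 0–1, value 0.15–1, all intervals **closed**
(a pixel at exactly V = 0.15 is kept; the source ranges are quoted
inclusively). With the default ranges the rule reduces exactly to
V ≥ 0.15. Residual specks are removed as 8-connected components with
area < `min_component_px` (default 50 px); the original description
names only "isolated outliers" with an effect bound below 0.3 % of the
frame, so the per-image removed fraction is reported so users can verify
that bound on their own data. The order is fixed: segment, then denoise.
Alpha channels are dropped before conversion.

## Chamber model and alignment

Multi-view-stereo output has arbitrary scale and pose, so every cloud is
mapped into a canonical chamber frame before voxelization. The canonical
model places the board surface at z = 0 with the aperture center at the
origin; walls are the planes x ∈ {−60, +70}, y ∈ {−65, +75} (cm — each
checkerboard square edge is 1 cm, so the recovered scale is metric). The
wall rectangle is deliberately **not** centered on the aperture: a
rectangle of corner landmarks is symmetric under a 180° rotation about
its own center, and only an off-center aperture lets the hook position
break that tie.

Alignment proceeds in four steps.

1. **Plane recovery, frame-free.** The checkerboards lie on the convex
   hull of the scene (the chamber is a convex shell around the panicle),
   so hull facets are clustered into coplanar groups (normal dot
   > 0.999, offsets within 4× the inlier tolerance), each group is
   refitted by least squares with a median-absolute-deviation outlier
   guard (5× MAD), and groups with fewer than 50 supporting points are
   dropped. The inlier tolerance defaults to 2·10⁻³ of the bounding-box
   diagonal. This is deterministic — no RANSAC sampling — and exact for
   noise-free planes.
2. **Structure identification.** Among the recovered planes, the board
   is the unique plane whose normal parallels no other; the walls form
   two mutually perpendicular parallel pairs. Combinations over the
   top seven planes are searched so a spurious sixth plane cannot break
   the assignment.
3. **Corner landmarks.** The four board–wall–wall intersections are
   solved from the three plane equations each. A similarity transform
   (Umeyama closed form, rotation constrained to det +1) is fitted for
   every corner correspondence; correspondences within numerical
   tolerance of the best residual are kept and the one whose transform
   maps the apparatus (hook) centroid closest to the canonical hook
   position wins. Collinear or coincident landmarks raise a
   rank-deficiency error.
4. **Application.** p ↦ s·R·p + t on coordinates only; colors and
   labels are untouched. The landmark residual RMS is attached to the
   returned transform.

Component labels are computed geometrically in any frame: points within
tolerance of a recovered plane are checkerboard; of the rest, points
that are gray (max − min channel ≤ 30 of 255) **and** in the top 10 % of
the scene height along the board normal (oriented toward the bulk of the
non-plane points) are apparatus; the remainder is panicle. Both
thresholds are configurable on the chamber model.

## Voxelization and traits

The same bounding cube is used for every cloud of a study (default: min
corner (−28, −28, 2), edge 56 cm, centered over the aperture) with
resolution 1000 per edge by default. Binning is half-open with floor
indexing — voxel v = ⌊(p − min)/h⌋, h = edge/resolution — with
coordinates exactly on the max face clamped into the last cell; this is
the only convention making cells disjoint and exhaustive. Points outside
the cube raise an error naming the first offender, since after correct
alignment no panicle point can leave the cube; an out-of-bounds point
signals a failed alignment rather than data to be silently dropped.

A voxel is filled if at least one point maps to it; its color is the
arithmetic per-channel mean of its member points, kept on the 0–255
scale throughout for cross-session comparability. Traits: voxel count
|filled|; color sums Σ over filled voxels of the per-voxel mean, per
channel; R:G ratio as the ratio of channel **sums** (not the mean of
per-voxel ratios). A zero green sum makes the ratio undefined; it is
flagged (`None` + an explicit error on demand), never returned as
infinity.

## 2D pixel count

Regions are 8-connected (thin diagonal branch segments stay connected).
Solidity is area over convex-hull area; eccentricity comes from the
ellipse with the same second central moments of the pixel coordinates,
e = √(1 − λ₂/λ₁). A region is excluded iff (solidity > 0.7 **and**
eccentricity < 0.95) or area < 1000 px. The conjunction is a deliberate
reading of an ambiguous rule: a checkerboard square is both compact and
round, whereas individual panicle branches can be compact alone, and an
OR rule would delete them — e.g. a convex elongated blob (solidity 1,
eccentricity 0.98) is panicle under AND but garbage under OR. Both modes
exist behind `exclusion_mode`; AND is the default. Raising the area
floor, lowering the solidity bar or raising the roundness bar each
enlarge the excluded class and can only shrink the surviving total.

## Seed scans

Scan segmentation uses the fixed ranges hue 0–0.3, saturation 0.2–1,
value 0.5–1 (closed), tuned for yellowish seeds on a black scanner bed.
Opening uses a disk of radius 2 px (at 600-dpi-scale imagery; the
source names the operation but not the element), which removes
structures thinner than 4 px — branches — while seeds of minor axis
≥ 8 px survive. "Too thin" residue is quantified as a minor axis below
8 px (configurable; no number is given in the source). Projected surface
area is measured **before** opening: branch pixels are part of the
panicle's projected area even though they are not seeds; whether the
original analysis measured pre- or post-opening is unstated, so the
choice is documented here.

## Statistics

Pearson r is computed pairwise-complete; p is two-sided from
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom. Constant traits and
pairs with fewer than three complete observations are flagged undefined
rather than propagated as NaN. Raw p-values are reported by default
(matching the source analysis); Benjamini–Hochberg is available but off.
Clustering of genotype × week trajectories uses Euclidean distance with
Ward linkage — standard for magnitude-dominated trajectory clustering —
both configurable; missing cells are imputed by the genotype's own row
mean and flagged. Group comparisons are classical equal-variance Student
t-tests (Welch behind a flag) at α = 0.1, summarized by a compact letter
display via insert-and-absorb; two groups that are both constant and
equal are treated as indistinguishable, while unequal constants raise a
degenerate-test error.

## Synthetic data: what it emulates, and what it does not

`make_scene` builds a canonical-frame scene: five checkerboard patches
(20 × 20 squares of 1 cm, random colors with ~10 % forced to the
panicle's green so the 2D filter is exercised on color-identical
distractors, margins kept so patch edges never touch two planes), a gray
hook cylinder above the aperture, and a panicle of ellipsoidal seeds
(semi-axes 1.3 × 0.5 × 0.4 cm by default) placed along 5 drooping
branch curves, volumetrically sampled at `point_density` (60 pts/cm³
default; denser sampling tightens voxel-occupancy estimates). Seed
colors interpolate green (50,160,60) → yellow (210,180,60) with the
maturation stage; green branch stems keep the rendered silhouette
connected and sprawling, as in a real panicle. The weekly volume
multiplier scales the **whole** panicle geometry by its cube root, so
true volume is exactly proportional to the multiplier; the per-scene
truth volume is the rasterized union of the seed ellipsoids (cell 0.1 cm
by default), so overlapping seeds are not double counted. A separate
`layout_seed` lets scenes share one growth habit with independent point
sampling.

`render_views` is an orthographic splat renderer (disk radius 2 px at
6 px/cm on 320 × 320 frames): it reproduces silhouette geometry and
color, not photometry — no perspective, shading, blur or camera noise,
which is also why its per-view truth pixel counts are exact.
`make_scan` rejection-places non-overlapping ovals and connects them by
3-px-wide segments along the Euclidean minimum spanning tree of the
centers (MST edges cannot cross or pile up, so no junction ever exceeds
the connector width — the property that makes "opening removes all
connectors" provable rather than probabilistic).

`make_cohort` reproduces the validation design: 11 genotypes × (3
control + 2 heat-treated) replicates = 55 plants, weeks 1–3. Genotypes
split into designed growth groups ("modest": base volume 1.0, weekly
multipliers 1.0/1.9/2.6; "vigorous": base 4.2, multipliers
1.0/1.35/1.8), with 9 % geometric spacing between genotypes and 1.5 %
between replicates so every plant volume is distinct and orderings are
resolvable by the voxel stage. Heat treatment raises week-1 volume by
15 % and advances the color stage by 0.15 — accelerated early filling
and maturation. End-point seed number and weight are proportional to
final true volume times (1 + N(0, σ)), σ = 0.05 by default, so the
voxel-count ↔ seed-weight correlation is positive by construction and
exact (up to voxel discretization) at σ = 0.

Passing tests on these generators demonstrates the correctness of the
measurement chain — segmentation, alignment, binning, filtering,
statistics — under known geometry. They do not demonstrate robustness to
reconstruction noise, occlusion, specular highlights, non-planar
checkerboard mounting, or seeds touching in real scans; those belong to
the upstream reconstructor and to validation on real imagery.

## Problem sizes and numerical choices

The test suite and the acceptance script run the voxel stage at
resolution 200 and cohorts of 8 genotypes × 1 replicate (noiseless
dynamics) or the full 55-plant design (noisy correlations) with
point density 200 or 60 pts/cm³ respectively — sizes chosen so the full
sweep completes on a single CPU in a few minutes while leaving every
assertion's margin wide (e.g. adjacent plant volumes differ by ≥ 3 %
against a voxel-count sampling scatter of ~0.3 %). The full 1000³ grid
is exercised through the sparse voxelizer's contract (indices bounded by
the resolution) and remains the library default. Tolerances: similarity
recovery to 1e−6 (exact plane fits give ~1e−12 in practice); voxel-count
invariance under re-alignment to 1 % (covers boundary jitter of points
that land exactly on voxel faces); occupancy-based volume recovery to
2 % at ~20 samples per occupied voxel (the empty-cell probability e⁻²⁰
is negligible; boxes are voxel-aligned so no partial-cell bias enters).

## Known limitations

- Alignment requires all five reference planes; scenes missing a wall
  raise rather than degrade gracefully.
- Voxel occupancy measures the sampled shell/volume of the
  reconstruction; systematic differences in reconstruction density
  between genotypes would bias between-genotype comparisons, and only
  occupancy (not watertight volume) is reported.
- The 2D filter can legitimately delete panicle regions whose silhouette
  is compact (solidity near 0.7) — a documented weakness of the 2D
  method that the 3D pipeline avoids.
- The letter-display algorithm is exact for the pairwise significance
  pattern given; with many groups the display is not guaranteed minimal
  in the number of letters.
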