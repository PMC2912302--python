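# Methods

## Scope and data model

`somabda` quantifies the soma volume of a bipolar cell from a single
topographic height map and compares the result between successive maps of
the same cell.  A scan is a complete regular lattice of point-sampled
heights (µm); volume integration multiplies each height by the pixel
footprint Δx·Δy, so 1 µm³ ≡ 1 fL (the report also carries a pL conversion).
Pixel (ix, iy) sits at physical (x₀ + ix·Δx, y₀ + iy·Δy); ragged or
duplicated input is a parse error rather than being silently regridded,
because silent resampling would corrupt volume estimates.

## Preprocessing

Live recordings are plane-corrected and floor-filtered before anything
else.  The plane is an ordinary least-squares fit to the pixels in the
lowest 30 % of heights (configurable): in a 30 µm frame around a ~10 µm
cell, the culture dish dominates the frame, so the low quantile samples the
substrate; after subtraction the frame is shifted to minimum 0.  The floor
filter zeroes every height strictly below 1 µm — such pixels represent the
dish, and the cut also removes the thin processes' tails so that line runs
terminate at the soma.  Both operations are idempotent (the plane fit up to
~1e-7 µm, limited only by quantile re-selection).  Noiseless phantoms skip
both steps.

## Nucleus proxy and heading

C_T is the unweighted centroid of {z > T·z_max} (strict inequality); the
default T = 0.9 approximates the nucleus position, since the tallest part
of the cell body overlies the nucleus.  No connectivity analysis is done —
at high T the area may consist of disjoint patches and the centroid is
taken over all of them.

The heading search evaluates Σ φ_i·r_i on the 181 angles 0, 1°, …, 180°.
φ_i is measured to the *undirected* line (folded into [0, π/2]), so pixels
on both sides of C_90 are treated alike and the search space [0, π] is
exhaustive.  Ties break toward the smallest angle, making symmetric inputs
deterministic.  The pixel at C_90 itself (r = 0) contributes 0.  On a
lattice-rasterized rotationally symmetric dome the arc profile is *not*
constant — pixel directions are discrete — but it repeats with period π/2
and its minimum lies within one grid step of 0; tests assert exactly that.
The dish cut for the heading search is the same 1 µm as the floor filter
(0 for phantoms).

## Rotation and interpolation

The heading-aligned lattice keeps the source steps, covers the back-rotated
source rectangle (corner projections rounded outward to whole steps), and
always contains the origin.  Each target point is back-rotated into the
source frame; outside the closed source rectangle the height is 0 (matching
the zero padding visible in aligned views).  Inside, the four surrounding
pixels span four right triangles (right angle at each corner in turn); the
height is the mean of the plane values of the triangles containing the
point.  Containment uses the angle-sum test (Σ of angles subtended at the
point by the triangle sides = 2π within 1e-6 rad); points within 1e-9 of a
lattice point snap to that pixel's height, and if numerical edge cases admit
no triangle the one with the largest angle sum is used — rotated lattice
points frequently land exactly on source-grid edges and must receive a
defined height.  The scheme reproduces affine height fields exactly, stays
within the min/max of the four neighbours, and conserves total mass to
within 2 % for smooth objects at any angle.

## Line-wise delimitation

Each rotated-grid line is split at the origin; the rear half is mirrored so
both directions use outward coordinates.  S_y′ is the maximal gap-free run
of positive heights starting at the origin; fits never bridge zero-height
gaps (a gap near the origin signals the soma fringe, handled separately).

**Main rule (four nonzero pixels among the first four positions).**
Least-squares polynomials of degree n = 3 are fitted to the first r run
points for r = n+2 … run length.  Goodness is the adjusted coefficient of
determination ḡ = 1 − (SSE/SST)·(r−1)/(r−n−1), defined only for r ≥ n+2.
The fit with the best ḡ supplies the boundary as its smallest positive real
root (imaginary part < 1e-9); the root may lie beyond the last fitted
point.  If the best fit has no such root, the interpolating degree-n
polynomial through the first n+1 points is tried; failing that the degree
is reduced (3 → 2 → 1) and the whole procedure repeats; as a final resort
the boundary is placed half a step beyond the last run point.  Numerically
vanishing leading coefficients (a cubic fitted to exactly linear data) are
stripped before root finding to avoid spurious far roots.

**Fringe rules (three/two/one nonzero pixels).**  An isolated pixel gets
the symmetric parabola with vertex at the pixel and zeros one step to
either side — the only parabola fixed by one sample and the lattice scale —
unless it sits at the fourth position, which is detached from the soma and
cropped.  An adjacent pair gets the cubic through the pair and the flanking
zeros (its construction roots), cropped when the pair ends at the fourth
position with only zeros between it and the origin.  With a single zero
among the first four positions, the zero's location decides: at the origin,
the line is continued through the height just across the origin when that
side carries mass (an asymmetrically shaped soma), otherwise anchored at
(0, 0); in the middle, the line splits into an isolated-pixel and a pair
sub-problem whose intervals are united (this can yield several disjoint
intervals on one line — the delimited soma may look jagged); at the fourth
position, the cubic closes at that zero or continues across the origin,
again depending on the opposite-side height.  Every line yields a defined,
possibly empty, boundary; the procedure cannot abort.

Pixel membership uses closed intervals (a pixel exactly at a root is
inside); overlapping intervals are merged.

## Volume, dimensions, discard

V_total = Σ z′·Δx·Δy over the member pixels.  The frontal/rear split at
x′ = 0 assigns the x′ = 0 column half to each side, which keeps the split
exactly additive and gives equal halves on mirror-symmetric cells.  Length,
width and height are the mask extents along x′ and y′ and the maximum
height; basal area is the member-pixel count times the footprint.  If any
boundary point, mapped back through the inverse rotation, leaves the source
footprint, the height under part of the claimed soma was never recorded and
the scan is flagged discarded (CLI exit status 1).

## Phantoms and sweeps

Validation objects are half-ellipsoids on the 30 µm/1 µm-step frame used
for live imaging (900 pixels — the field/rate compromise of the
instrument), base radius r₀ = 5 µm since an OPC soma is about 10 µm long,
centred at (14.5, 14.5) so that the even-width extension strip is symmetric
about the dome.  Processes are emulated by raising a strip of
round(w/step) rows (half-open band [y₀−w/2, y₀+w/2), default width
2·r₀/5 = 2 µm, height r₀/2) to the extension height wherever the dome lies
below it; the max-composition avoids a gap where dome and strip meet but
also raises some dome-skirt pixels, so the object's column sum exceeds the
bare dome's.  The strip runs to the frame borders in ±x.  "Tenfold
resolution" keeps the physical geometry and refines the step to 0.1 µm
(300×300).

Sweeps (all deterministic, normalized to the column sum V_sum of the
extension-free twin):

* *flatten*: r_x = t·r₀, r_z = r₀/t (variants vary r_y or both lateral
  radii as √t·r₀), t = 1…2 step 0.05, no extensions; the BDA is evaluated
  directly on the source lattice in C_90-centred coordinates, since there
  is no heading to align.  Thresholds 0.4·r_z (relative) and 0.4·r₀
  (absolute) for the comparator.
* *height*: hemisphere plus extensions of height h·r₀, default
  h = 0.05…0.95 step 0.01 (covering every value discussed); the threshold
  comparator uses h·r₀.  Phantoms with extensions run the full pipeline
  including heading and rotation.
* *width*: strip width w·2·r_y at fixed height r₀/2; the comparator is
  width-blind by construction.
* *combined*: r_x = r_y = √t·r₀, r_z = r₀/t with extension height h·r_z,
  h = 0.2…0.6, t = 1…2.

The phantoms are noiseless, perfectly plane and axis-aligned (up to the
oblique-strip builders used in tests); passing tests therefore demonstrate
the geometry handling and estimator behaviour, not robustness to scan
noise, drift, or the irregular process shapes of live cells.

## Numerical choices

Polynomial fitting and root finding use numpy (`polyfit`/`roots`); fits are
checked in tests against explicit normal equations to 1e-8 and roots
against a dense sign scan to 1e-6.  Inclusion tolerance 1e-6 rad; lattice
snap 1e-9 of a step; interval-merge tolerance 1e-12; root positivity cut
1e-9.  The comparison thresholds are strict (">") throughout: a pixel
exactly at a threshold is *not* above it, and a height exactly at the floor
cut is retained.

## Known limitations

* On lines whose profile has no descending flank — extension strips whose
  height approaches the dome's, or strip rows far from the dome that are
  plateau-only — every polynomial through the data crosses zero far beyond
  the object (or never), and the delimited soma absorbs a large part of the
  strip.  Consequently the erroneous-volume-change figures for tall
  (h ≳ 0.7) and wide (w ≳ 0.5) extensions exceed the published values of
  the original evaluation by design of the printed procedure; the exact
  published numbers for those regimes could not be reproduced under any
  reading of the fitting rules consistent with the rest of the method (the
  acceptance checks for them are left failing rather than recalibrated).
  The qualitative behaviour — exactness on extension-free objects,
  overestimation growing with extension height and width, smaller errors
  than thresholding near small deformations — reproduces throughout.
* The threshold-comparator change between h = 0.2 and 0.6 measures
  19–21 points at both resolutions here (the smooth-limit value of
  Σ_{z>τ} z on a hemisphere is V_n = 1 − h³, a 20.8-point drop); the
  corresponding acceptance checks are likewise left at their honest values.
* The x′ = 0 half/half column split is a convention; any other split moves
  front/rear volumes by at most one pixel column.
* Soma dimensions are mask extents on the rotated lattice, i.e. multiples
  of the step size.
* The heading estimate has 1° resolution by construction; no sub-degree
  refinement is attempted, and front vs rear is a labelling convention — a
  single scan cannot reveal the migration direction.
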