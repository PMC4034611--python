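# Methods

## The ontogeny axis

All measurements are referred to one coordinate: cumulative arc length *s*
(mm) along the 3D curve traced by the aperture's anterior landmark (the
point of maximum local growth) from the protoconch–teleoconch boundary.
Arc length is the chord sum of the digitized polyline; phases are half-open
intervals `[0, spire_end)`, `[spire_end, constriction_end)`,
`[constriction_end, s_max]`, with default bounds 13 and 14 mm.  Projected
(2D) arc length uses an orthographic projection, which treats a long-working-
distance photograph as parallel projection; it is a lower bound on the 3D
length (Cauchy's projection inequality) and on realistic coiling geometry
correlates with it at r > 0.8, which is why photograph-based whorl-length
measurement works.

Growth rate is (s_end − s_start)/duration in mm/day.  Phase membership of a
growth record is decided by `s_start`, the mark position *before* the
experiment, because rates are analysed against pre-experiment position.
Records starting inside the constriction belong to neither analysed phase;
they are excluded from the two-phase correlation and logged.  (The analysed
phases are spire and tuba only; no rule for constriction starts is implied
by the two-phase design, so exclusion is the conservative choice.)

## Synthetic shells and their ground truth

The generator exists so that every estimator in the package can be checked
against analytic truth, at the scale and in the regimes of the real
organism.  The spire is a Raup-style logarithmic helicospiral

    x = r0 e^(αθ) cos θ,   y = −r0 e^(αθ) sin θ,   z = −(c/α) e^(αθ)

(dextral; sinistral flips y; α = 0 degenerates to a circular helix with
z = −cθ).  Speed, arc length, and the inverse θ(s) have closed forms, and
κ(s), τ(s) follow exactly from the first three parametric derivatives, so
the truth callbacks are exact, not fitted.  Defaults — r0 = 0.2 mm,
α = 0.05 rad⁻¹, c = 0.0175 mm, θ_max = 33.5 rad, ds = 0.01 mm — give a
~17.4 mm axis over ~5.3 whorls with κ falling from ~5 to ~1 mm⁻¹ and small
positive τ.  These are *illustrative* values reproducing the scale of a
3 × 3.5 mm diplommatinid shell; no species coiling parameters are published,
so they should not be read as measurements.

The three-phase structure is imposed by a `PhaseSchedule`.  With the tuba
rotation reversal enabled, the axis beyond `spire_end` is regrown by
integrating the Frenet–Serret equations (fixed-step RK4, 4 substeps per
sample, Gram–Schmidt re-orthonormalization each step) with the original
curvature but torsion multiplied by a cosine ramp from +1 to −1 across the
constriction.  This is a C1 continuation whose torsion sign change is
planted exactly; the generator makes no claim that a real tuba grows this
way — it provides the qualitative signature (handedness reversal) the
estimators must detect.

Aperture outlines are closed planar curves centred on the axis, normal to
the local tangent, drawn in the local Frenet frame.  Using the Frenet frame
(rather than a rotation-minimizing frame) is deliberate: successive frames
then twist about the growth direction at rate τ, so the planted segment
rotations carry the coiling handedness, and the infinitesimal rotation
triple is (0, κΔs, τΔs) — tilt-free growth with bending proportional to
segment length and twist carrying the torsion sign.  The planted perimeter
program is linear on the spire (slope 0.166 mm/mm, intercept 0.457 mm —
the published regression line is used as the generating line), dips by a
fraction (default 0.35) across the constriction via a C1 cosine ramp, and
regrows at the spire slope along the tuba.  The template shape morphs from
a slightly anisotropic rounded diamond to an ovate form across the
constriction; the anisotropy (1.15 : 0.95) keeps the first-harmonic ellipse
non-degenerate so shape normalization is stable.

Rib positions follow s_{i+1} = s_i + g(s_i) + ε with a piecewise-linear
trend g (default: rising to ~8 mm, dipping toward 10 mm where the tuba
detaches, peaking at the constriction ~13 mm, then low and flat) and
ε ~ N(0, 0.02 mm), resampled on non-positive draws with a bounded retry
budget.  The planted growth rate is v(s) = 0.2 + 0.05 s on the spire,
maximal through the constriction, declining along the tuba — an S-shaped
growth curve in time — with N(0, 0.1) mm/day rate noise.  The reference
study draws 30 spire and 35 tuba records, 35 rib series (per-shell density
multipliers in [0.8, 1.3], lengths in the last 1.5 mm of the axis), and
22 + 11 outlines (1% perimeter noise), mirroring the field study's sample
sizes.  One top-level seed feeds documented child streams (fixed offsets
per sub-generator), so partial pipelines are independently reproducible.

What the generator does *not* emulate: digitization noise on outline
coordinates (only perimeter-scale noise), mesh/surface geometry, whorl
overlap and aperture-previous-whorl contact, episodic growth in time, and
between-individual variation in coiling parameters.  Passing tests
therefore demonstrate the *estimators* are correct and calibrated on known
geometry of realistic scale — not that any biological conclusion holds for
real shells.

## Elliptic Fourier analysis

Outlines are standardized to start at the anterior landmark.  Coefficients
use the chord-length parameterization with period T = polygon perimeter;
because velocity is piecewise constant on edges, the Fourier integrals have
the classical closed form (sums over edges), extended to three coordinates.
The constant term is the chord-length-weighted midpoint mean (the exact
mean of the piecewise-linear curve).  Zero-length edges are dropped.

Smoothing-then-measuring follows the standard order: decompose (K = 5) →
reconstruct (100 uniformly spaced parameters, first sample at the anterior
phase) → perimeter as the chord sum including the closing chord.  A
100-point chord sum of a circle is 200·sin(π/100) ≈ 0.9998 of the true
circumference; this discretization is part of the measurement definition.

Normalization produces similarity-invariant coefficients: constant terms
dropped (translation); parameter phase shifted so the first harmonic starts
at its semi-major vertex; all coefficient vectors rotated into the
first-harmonic ellipse frame (semi-major axis → x, ellipse-plane normal →
z, right-handed) and divided by the semi-major axis length.  After
normalization the first cosine harmonic is exactly (1, 0, 0).  Two
ambiguities are resolved deterministically: the semi-major *direction*
(±) is chosen as the vertex nearer in parameter to the anterior landmark,
and a circular-degenerate first harmonic (semi-axes equal within 1e-6
relative) anchors the phase at the anterior landmark outright.  Shapes
whose first harmonic is near-circular therefore normalize stably but may
jump if noise crosses the degeneracy threshold — inherent to any
major-axis-based normalization.

Shape PCA runs on the mean-centred coefficient matrix (covariance PCA;
coefficients are commensurate after normalization).  A correlation-matrix
variant is available (`method="correlation"`); columns pinned by the
normalization are excluded from PC1–coefficient correlations, which are
reported with two-sided p-values at α = 0.05.

## Segment rotations

The anatomical frame of an aperture: x̂ from the outline centroid to the
anterior landmark (anteroposterior); ẑ the component of the outline-plane
normal (least-variance direction) orthogonal to x̂; ŷ = ẑ × x̂.  The sign
of ẑ is matched to the local growth direction (the chord between the
segment's bounding ribs on the axis).  The original procedure orients this
axis "dorsally, away from the previous whorl", but previous-whorl geometry
is not derivable from outline-and-axis inputs; the growth-direction rule is
deterministic, consistent across segments, and agrees with the planted
frames of the generator.  Rotation about ẑ is rotation of the aperture
plane about its own normal — the clockwise/anticlockwise rotation seen in
dorsal view.

For a segment pair, the scene is rigidly transformed so the NEW frame
coincides with the global axes (the anterior-point translation does not
affect angles), and the relative reorientation M = E_oldᵀE_new is factored
extrinsically as M = Rz(θz)·Ry(θy)·Rx(θx), reported in degrees.  Under this
convention an anticlockwise reorientation of the animal about its dorsal
axis gives θz > 0, and re-composing the three reported rotations in x→y→z
order carries the OLD frame onto the NEW frame exactly.  Near θy = ±90° the
factorization is degenerate; the triple is flagged and θx pinned to 0.
Frame alignment (not point-cloud fitting) is the primary route because
consecutive segments are not congruent shapes; a Kabsch rotation is
provided for validation on congruent clouds only.

## Curvature and torsion estimation

At each axis sample, windows of up to 100 points per side (cumulative chord
length as the local arc-length parameter, tricube weights on |Δs|/span) are
fitted per coordinate by weighted least squares: degree 2 for curvature,
degree 3 for torsion.  Centre derivatives give r′, r″, r‴ and the Frenet
formulas κ = |r′×r″|/|r′|³, τ = (r′×r″)·r‴/|r′×r″|².  Conventions: κ ≥ 0
always (κ = 0 is an orthocone); τ = 0 planispiral; τ > 0 right-handed
(dextral), τ < 0 left-handed — mirror reflection negates τ exactly.

Boundary points use shrunken asymmetric windows and are flagged
(`shrunken`); below 10 points per side they are flagged `low` but not
dropped.  Windows whose |r′×r″| vanishes (collinear) report τ = 0 with a
degeneracy flag.  The estimator's bias is O((window arc × κ)²): with
window arc L per side, errors stay below 1% only while L·κ ≲ 0.5, i.e.
sampling must satisfy roughly ds ≤ 0.01/κ at 100 points per side.  At a
tightly coiled apex (κ ≈ 5 mm⁻¹, ds = 0.01 mm) the 100-point window spans
a whole whorl and the estimate is meaningless — the support flags make
such regions inspectable rather than silently wrong, and the wild
fluctuation of torsion estimates near a constriction partly reflects this
estimator variance at small effective support.

## Statistics

Spearman rank correlation (average ranks for ties) with two-sided p: exact
by full permutation of one margin for n ≤ 8 (the combinatorial bound where
8! orderings are enumerable), t-approximation otherwise.  Pearson r with
the t-test on n − 2 df.  OLS with F = (n−2)R²/(1−R²), df (1, n−2), its p
identical to the slope t-test.  All p-values are two-sided; no normality
tests and no multiple-testing corrections are applied, matching the
analysis design this package reproduces.  The spire window for the
perimeter regression defaults to s ∈ [5, 11] mm and is configurable.  Rib
counts split strictly-before vs at-or-after the constriction; pooled
spacings are one row per inter-rib interval at the interval midpoint,
order-invariant over shells.

## Numerical choices and problem sizes

- Sampling step ds = 0.01 mm for study shells (~1700 points over 17 mm);
  closed-form recovery checks use ds = 0.005 mm (circle, helix) and
  0.002 mm (generic helicospiral) so the window-bias condition above holds
  with margin.  These sizes keep the full test suite under a minute of
  compute while leaving the estimators in their asymptotic regime.
- Monte-Carlo sizes: 200 replicates for planted-correlation detection,
  1000 for the Spearman type-I calibration (empirical rate 5% ± 1.5%),
  100 outlines for the invariance sweep, 1000 triples for the Euler
  round-trip.
- Seeds: a single integer seed; child streams by fixed multipliers.
- Tolerances: similarity invariance of normalized coefficients holds to
  1e-9 (observed ~1e-15); Euler round-trip to 1e-6° (observed ~1e-13);
  closed-form κ/τ recovery to 1% at full-support points.

## Known limitations

- The tuba continuation is a torsion-ramp model, not a biomechanical one;
  only its sign structure should be interpreted.
- EFA is not idempotent under re-decomposition of a reconstructed outline:
  re-parameterizing by the new chord length perturbs coefficients at the
  level of the curve's speed non-uniformity.  Projection idempotence holds
  exactly only for arc-length-parameterized harmonic curves (e.g. circles)
  in the dense-sampling limit.
- Perimeters measured after K = 5 smoothing are biased low for shapes with
  significant energy above the fifth harmonic (sharp re-entrants, heavy
  ornament on the outline itself).
- The rotation factorization is exact, but anatomical-frame *construction*
  from noisy outlines inherits noise through the centroid, the anterior
  landmark, and the fitted plane; on noiseless synthetic outlines recovered
  frames match planted frames to < 1°.
- No automatic rib detection or outline extraction from meshes/images:
  digitized positions are inputs by design.
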