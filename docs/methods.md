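# Methods

## Transformation model

The motion of every cine frame relative to the end-diastolic reference
frame (frame 0) is modelled as the sum of a global affine displacement
and a local B-spline free-form deformation (FFD), added *as
displacement fields*, `T(x) = x + T_global(x) + T_local(x)`. Additive
combination and functional composition differ for large affine parts;
the additive form is implemented throughout, and the dense displacement
field, the contour propagation and the strain computation all use it
consistently.

Conventions. Points are `(x, y)` in pixels, 0-based, pixel centres at
integers. The affine rotation matrix has first row `(cos θ, sin θ)`,
which rotates clockwise in the y-down image frame; this is kept as the
model's convention rather than "corrected". Physical pixel spacing
enters only in the strain module.

The FFD lattice covers the image plus one padding ring of control
points, so every in-image pixel has the full 4×4 cubic B-spline
support; padding control points are ordinary parameters. A point in
lattice cell `a0 = floor((x − origin)/δ)` with fraction
`u = (x − origin)/δ − a0` is supported by control points
`a0−1 .. a0+2` per axis. Evaluating a lattice point outside that
support raises an error; nothing is clamped silently. Default spacing
δ = 8 px (for 64-px frames this gives an 11×11 lattice; the clinically
used spacing is not documented anywhere authoritative, so it is plain
configuration). Grids serialize to JSON (shape, spacing, origin,
flattened displacements), making a registration result a portable
artifact.

## Objective

`Cost = C_sim + λ·C_ICP`.

* `C_sim`: mean of squared intensity differences between the reference
  frame and the target frame resampled at `T(x)` with an interpolating
  cubic spline (coefficients prefiltered once per frame). Out-of-image
  samples take the border value and are masked.
* `C_ICP`: the reference endo/epicardial contours are propagated
  through the current transform (they live in the domain the control
  mesh deforms, so they move with the mesh); each target contour point
  is matched to its nearest propagated point under
  `d = α₁·(squared Euclidean) + α₂·(squared curvature difference)`, and
  C_ICP is the **sum** of matched distances — more contour points mean
  a proportionally larger term. Contours are resampled to 64 points at
  uniform arc length before use so the term's magnitude is comparable
  across frames.
* `α₁, α₂` are reciprocals of the range (max − min) of their respective
  squared terms over all source–target point pairs, computed once from
  the frame-0 contour pair and frozen during the optimization (a
  stationary objective for the descent); per-iteration recomputation is
  a config flag. A component whose range is zero (or at floating-point
  noise level) carries no information and gets weight 0 with a warning.
* λ defaults to 1 and can be raised for large deformations; λ = 0 is
  exactly the intensity-only method.

### Matching policy

Three measured failure modes on the phantom shaped how the curvature
feature enters the *matching* step (the logged C_ICP always uses the
verbatim reciprocal-range weights):

1. **Curvature of a partially converged FFD contour is noise.** The
   control grid wiggles the propagated polygon at scales below its own
   spacing; curvature estimated from those wiggles reached 3× the true
   signal range and even changed sign. The propagated contour is
   therefore low-pass filtered (circular triangular kernel, half-width
   3 points) before curvature re-estimation.
2. **Raw reciprocal-range weighting lets curvature override position
   over arbitrary distances.** It prices a full-range curvature
   mismatch like a full-diameter positional miss, and since contraction
   shifts the *whole* curvature level by more than its along-contour
   variation, curvature-similarity matching systematically selects
   wrong material points and drags the FFD tangentially (measured mean
   endpoint error 6.4 px versus 0.15 px for λ = 0). Matching is
   therefore gated to a positional neighbourhood (3 px; the plain
   nearest neighbour is always retained so no point goes unmatched) and
   the curvature weight used in matching is rescaled so a full-range
   curvature mismatch costs as much as a gate-radius positional miss:
   `α₂(match) = α₁·α₂·gate²`. Inside the gate curvature does what it is
   for — disambiguating nearby candidates.
3. **Refresh granularity.** Curvatures and correspondences are
   refreshed once per outer iteration and held fixed through the
   gradient and the line search (standard closest-point majorization),
   so each step minimizes a stationary quadratic surrogate. Refreshing
   inside every cost evaluation breaks the majorization inequality and
   stalls the line search. Within the line search the frozen curvature
   term is a φ-independent constant, so accept/stop comparisons use
   `C_sim + λ·(positional part)` only — letting curvature re-estimation
   noise into those comparisons caused oscillating, non-converging
   runs.

With this policy the contour term halves the mean endpoint error of the
intensity-only method on the contraction phantom and improves landmark
tracking about five-fold on the weak-edge phantom — the qualitative
ordering the modified method claims, at phantom scale.

## Optimization

Constant-gain gradient descent `μ ← μ − a·g(μ)` with central
finite-difference gradients, per parameter group:

* **Global stage** (k, θ, Δx, Δy): FD steps 0.005 (k), 0.005 rad (θ),
  0.01 px (Δ); gains (0.3, 20, 200, 200), roughly inverse-curvature
  scaled on unit-range intensities so all four groups converge at
  comparable rates. Internally the affine is parameterized about the
  image centre (`x' = kR(x−c)+c+d`) and converted back to the
  origin-based form on return: rotation/scale about the origin corner
  alias with translation and produce an elongated valley that plain
  descent crawls along.
* **Local stage** (all control-point displacements): FD step 0.01 px,
  gain 400. The SSD gradient of one control point only involves the
  pixels in its 4δ×4δ support, so all perturbed window resamples (every
  control point × axis × sign) are evaluated in a single interpolation
  call per iteration. The contour surrogate is quadratic in the
  propagated points, so its central difference has a closed form.

A step that fails to decrease the (surrogate) cost halves the gain and
retries; the configured gain is restored at the next iteration, making
the safeguard a per-iteration backtracking rule — a permanently
collapsed gain after one steep stretch froze the λ > 0 runs. A
non-finite cost at gain underflow is an error; plain stagnation
terminates as converged. Stopping: cost decrease below 1e−6 of the
initial cost, or 200 (global) / 300 (local) iterations — desk-scale
defaults; the relative rule usually stops λ > 0 runs after a few dozen
iterations.

Frames are always registered **to frame 0**, never chained pairwise
(chaining accumulates error). Warm-starting frame t from frame t−1's
solution is an initialization aid only; the objective is unchanged, and
warm/cold starts agree on the converged intensity objective to ~1e−5 on
the phantom. Registration is deterministic given configuration — there
is no stochastic element beyond the phantom's seeded noise.

## Contour extraction

When contours are not supplied as CSV
(`frame,label,point_index,x,y`; curvature is always recomputed, never
read), a GVF snake extracts them: gradient vector flow diffused from a
gradient-magnitude edge map (explicit iteration, CFL-stable step,
stopping on relative change), then a closed active contour solved
semi-implicitly with the cyclic pentadiagonal tension/rigidity system,
the GVF force normalized to unit vectors (the diffused field's
direction is the signal; its decaying magnitude is not). Defaults:
μ = 0.2, tension 0.02, rigidity 0.1, step 1.0, force weight 1.0.
Edge-map construction matters: light smoothing (σ = 0.5) with the plain
gradient magnitude keeps the snake's equilibrium within ~0.2 px of the
phantom's true border; heavier blurring or squared magnitudes shift an
annular ridge measurably inward. The snake needs a user-supplied seed
contour for frame 0; automatic initialization is out of scope.

Per-point curvature is estimated by a local parabola fit (window
half-width 5) in a chord-aligned local frame — more noise-robust than
differentiating tangent angles — with the sign normalized so circles
are positive for either sampling orientation; it is rotation- and
translation-invariant and scales as 1/s under uniform scaling.

## Strain

Displacement fields map reference coordinates into frame t, so strain
is Lagrangian with respect to end diastole, evaluated on the fixed
frame-0 myocardium mask. `F = I + ∇u` by central differences in mm
(second-order one-sided at borders), `E = (FᵀF − I)/2`, and radial /
circumferential projections `r̂ᵀEr̂`, `t̂ᵀEt̂` from the LV centroid (the
mean of the frame-0 endocardial contour, fixed across the cycle),
reported in percent. Green strain is the default (finite-deformation
correct, objective under rotation); an engineering projection
`√(r̂ᵀFᵀFr̂) − 1` is available since "percent thickness change" reads as
engineering strain — for the phantom's deformations the two differ by
about the ratio seen in 10.5% vs 10.0% at a 1.1 stretch. Strain rate is
the time derivative of segment-mean strain (1/s), central differences
over the uniform frame interval.

AHA segmentation: 6×60° sectors for basal and mid levels (labels 1–6,
7–12), 4×90° for apical (13–16), counted counterclockwise from the
anterior RV-insertion angle, which is a required user input (its
clinical localization is not automated). The true apex (segment 17) has
no short-axis representation. The global mean curve is the plain mask
mean and hence exactly the area-weighted mean of the segment curves.

## Phantom

The validation substrate is a synthetic short-axis LV: a bright
myocardial annulus (default intensities cavity 0.25 / wall 0.85 /
background 0.10, sigmoid edges of width 1 px) between radii 12 and
20 px in a 64-px frame, deformed by a piecewise-linear-in-radius map
along each ray — cavity compresses linearly, wall moves and thickens,
the exterior relaxes to identity at a support radius — so both the
forward map and its inverse are closed-form. Frames are rendered by
evaluating the intensity model at the *exact inverse* position, which
makes the rendered motion identical to the stated field; Gaussian noise
(default σ = 0.01 of the intensity range) is added last from the seed.
Temporal modulation is a raised-cosine rise to peak at end systole
(one-third of the cycle) with a slower cosine recovery, zero again at
the cycle end. Defaults: 16 frames, peak endocardial excursion 25% of
the inner radius, 30% wall thickening, 1.4 mm/px and 50 ms metadata.

Two deliberate departures from a perfect annulus keep the phantom
honest about real data:

* an angular intensity **texture** on the wall (three smooth harmonics,
  ±25%): real frames are never rotationally symmetric, and on a
  symmetric annulus rotation is fundamentally unobservable to any
  intensity-driven method;
* a mild border **ellipticity** (±10% radius modulation): on exact
  circles contour curvature is constant, so the curvature feature would
  carry no information and its reciprocal-range weight would diverge.

Optional ingredients: rigid rotation and endo-to-epi twist (twist
excludes ellipticity — the closed-form inverse would be lost), a
flat-top hypokinetic sector scaling the local activation, and a
weak-edge arc that lowers the wall/background contrast to zero —
reproducing the weak-edge failure mode that motivates the contour term.
The ground truth exposes dense per-frame fields, exact advected
contours, two landmark trajectories (one at a high-deformation site,
one mid-wall on the weak edge) and the closed-form Green radial strain
of the programmed deformation.

What the phantom does **not** emulate: MR physics (bias fields, partial
volume, flow artifacts), papillary muscles, through-plane motion,
irregular heart rates. Passing the phantom suite therefore demonstrates
correctness of the algorithms under controlled, fully known conditions,
not clinical performance.

## Problem sizes and numerics

The test and acceptance experiments run on 64-px frames, 8–16 frame
cycles, δ = 8 px lattices and 64-point contours — sizes at which every
experiment has an exact analytic answer and the full suite completes in
minutes on one CPU. Key tolerances: B-spline identities to 1e−12;
FFD vectorized-vs-brute-force agreement to 1e−10; identity resampling
to 1e−9; affine recovery to 0.3 px / 0.5° / 0.01 under 2% noise;
nonrigid recovery below 0.8 px mean endpoint error (measured ≈ 0.15 px
intensity-only, ≈ 0.075 px contour-guided); objectivity of strain under
rigid motion below 0.5%.

## Known limitations

Single-resolution FFD (no pyramid, hook reserved); no diffeomorphic
guarantee — large λ with inconsistent contours can fold the grid;
per-point-argmin ICP matching is not a global assignment; tangential
sliding along contours is only weakly constrained (by intensity and the
curvature feature); 2D in-plane motion only.
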