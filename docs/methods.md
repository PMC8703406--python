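# Methods

## Model

The state space is M = ℝ² × SO(2) × ℝ with q = (x, y, θ, k).  A contour is
lifted to M by recording, at each point, its position, tangent direction
and signed curvature.  Admissible velocities lie in the rank-2
distribution Δ = span{X₁, X₂} with X₁ = (cos θ, sin θ, k, 0) and
X₂ = (0, 0, 0, 1); the controls (u₁, u₂) are the speed along the contour
and the curvature rate.  The cost is the sub-Riemannian length
∫√(u₁² + u₂²) dt for which X₁, X₂ form an orthonormal frame.

Two structural facts drive the implementation:

* The brackets X₃ = [X₁, X₂] = (0, 0, −1, 0) and
  X₄ = [X₁, X₃] = (−sin θ, cos θ, 0, 0) complete a global frame with
  det[X₁ X₂ X₃ X₄] ≡ 1 and growth vector (2, 3, 4) (an Engel-type
  structure).  `geometry` verifies both numerically: the determinant to
  1e−12 and the nested ranks by relative-threshold SVD.  These are the
  checkable hypotheses behind complete controllability; the analytic
  theorems themselves (Chow–Rashevskii, Filippov) are out of scope.
* The system is SE(2)-invariant, so every boundary-value problem is solved
  in the normalized frame q₀ = (0, 0, 0, k₀) and mapped back.

Curvature sign convention: k is the signed curvature of the planar
projection relative to the travel direction θ (positive = bending left
when moving forward), which is forced by θ̇ = k·u₁.  Angles (θ, α) are
stored unwrapped; wrapping happens only in comparisons and plots, never
inside an ODE.

## Extremals

The maximum principle gives two cases.

**Abnormal.**  The momenta satisfy h₁ = h₂ ≡ 0, which forces u₁ ≡ 0 on
non-trivial arcs: the extremal is a pure curvature motion
γ(t) = (0, 0, 0, k₀ + ∫u₂).  Unit-speed optimal arcs have u₂ = ±1, hence
γ(t) = (0, 0, 0, k₀ ± t).  `extremals.abnormal_state` implements the
closed form; `abnormal_state_general` accepts any piecewise-constant
bounded u₂.  The trivial covector a = b = c = d = 0 is excluded
(nontriviality); the dataclasses reject non-finite components at
construction.

**Normal.**  With u_i = h_i the Hamiltonian is H = (h₁² + h₂²)/2 and the
flow, written in frame momenta, is

    ẋ = h₁cos θ, ẏ = h₁sin θ, θ̇ = h₁k, k̇ = h₂,
    ḣ₁ = −h₂h₃, ḣ₂ = h₁h₃, ḣ₃ = h₁h₄, ḣ₄ = −k h₁(k h₃ + h₁).

The canonical-coordinate form of the same flow is covered through the
exact linear conversions h = h(q, p) and p = p(q, h) rather than a second
right-hand side; tests assert the equivalence (round trips, and the
agreement of the 8-dim and 7-dim integrations).  Unit-speed
parameterization fixes H = 1/2 and substitutes h₁ = cos α, h₂ = sin α,
yielding the 7-dim natural system and its decoupled vertical block

    α̇ = h₃, ḣ₃ = h₄cos α, ḣ₄ = −k cos α(k h₃ + cos α), k̇ = sin α.

Three independent first integrals are known: H and the canonical momenta
a, b (conserved because the flow is independent of x, y).  A closed-form
fourth integral is not known; this package provides *numerical evidence
only* for its existence (below) and deliberately claims no formula.  A
numerical Poisson-bracket check of the involution of H, a, b would be
supporting evidence, not proof, and is not implemented.

## Integration

All flows are integrated with DOP853 (adaptive, order 8, dense output),
defaults rtol = 1e−10, atol = 1e−12.  These tight defaults are chosen so
that hundreds of section returns stay faithful: over t ∈ [0, 50] the drift
of H, a and b stays below 1e−8 (measured on a 10× refinement of the sample
grid), and arcs are flagged if H drifts more.  A guard aborts integration
if any state magnitude exceeds 1e8 — the vector fields are
polynomial-trigonometric, so runaway growth means the trajectory left the
regime of interest, not stiffness.  Drift is reported as an absolute
deviation (a and b can legitimately be zero, making relative drift
meaningless).

Section crossings of k = 0 are located by the integrator's event detection
(root-finding on the continuous interpolant), filtered by the sign of
k̇ = sin α, and polished to |k| < 1e−10 by bracketed root refinement when
needed.  The search horizon is a generous multiple of the estimated return
period 2π/|h₃(0)|; exceeding it raises a timeout that carries the partial
result, which callers surface as a flagged partial orbit.

## Poincaré experiment

The vertical system has the periodic family α(t) = π/2 + t·h₃(0),
h₃ const, h₄ ≡ 0, k(t) = sin(t·h₃(0))/h₃(0).  The period is **measured**
as the empirical first one-sided return time rather than hard-coded: the
closed form implies 2π/|h₃(0)|, while a period formula |2π·h₃(0)| is
sometimes quoted; the two agree only at |h₃(0)| = 1, which is the
parameter the experiment actually uses, so measuring sidesteps the
discrepancy.  Tests pin the measured period to 2π at h₃(0) = 1 (and to π
at h₃(0) = 2, consistent with 2π/|h₃(0)|).

Crossings are one-sided (k̇ > 0) by default, so the periodic orbit is a
fixed point of the map; the periodic trajectory crosses k = 0 twice per
period with opposite signs, and whether a return map should count one or
both sides is a convention — a flag (`direction=0`) exposes two-sided
crossings, which doubles the point count without changing the qualitative
picture.

The headline experiment iterates the map n times from five deterministic
seeds on the section: the fixed point (π/2, 1, 0) and four perturbations,
(1.56, 0.94, 0.02), (1.55, 1.06, 0.05), (1.6, 1.14, 0.02),
(1.58, 1.24, 0.01).  No randomness is involved.  The default n = 200 keeps
the run at a few seconds while tracing each invariant curve densely;
n = 1000 is a flag and only adds points along the same curves.  Orbits are
plotted and chained in α mod 2π because α grows secularly (by ≈ 2π per
return).

**Orbit thickness.**  The claim "points fill thin closed curves" is
operationalized by a deterministic diagnostic: greedy nearest-neighbor
chaining orders the points into a closed tour, chord length parameterizes
it, a truncated Fourier series (≤ 8 harmonics per coordinate) is fitted by
least squares, and the statistic is (RMS residual)/(cloud diameter).
Points on a smooth closed curve score near 0 (a circle scores at machine
precision; curves that are not finite Fourier series in chord length, such
as ellipses, score ≲ 1e−3); uniform 3D scatter with a fixed seed scores
≈ 0.14.  The chaos threshold is set at 0.05, comfortably between the two
regimes; the four perturbed orbits at n = 200 score below 7e−4.

## Boundary-value solver and completion

`solve_bvp` normalizes the problem, then searches (α₀, h₃(0), h₄(0), T)
so that the natural-system endpoint matches the target, with residual
weights 1 on x, y, k and 1 on the shortest angular distance in θ (the
model prescribes no mismatch metric; equal weights are a transparent,
configurable default).  T is a free variable bounded below by 0.05; under
unit speed T equals the length, so converged solutions are sorted by T and
the first is the numerically shortest — optimality is not certified (no
conjugate/cut-point analysis).

The start grid is deterministic: α₀ ∈ 8 values spanning [−3π/4, 3π/4]
(both signs of u₁ = cos α, since geodesics may need planar cusps),
h₃(0), h₄(0) ∈ {−2, −0.5, 0, 0.5, 2}, T ∈ {0.5d, d, 2d, 4d} with d the
planar distance plus |Δk| floored at 0.1.  All 800 starts are screened by
a single cheap forward shot (rtol 1e−6); the best 6 are polished by
bounded trust-region least squares with finite-difference Jacobians
(forward shots at rtol 1e−9); each candidate is then re-verified at
rtol 1e−11 before being accepted, deduplicated (momentum distance
< 1e−3), and mapped back to the original frame.  Sign changes of cos α
along the arc (cusps of the planar projection) are counted and reported
rather than forbidden — the model gives no reason to exclude them.

`complete_contour` returns the densely resampled (x, y) projection of the
shortest converged arc.  On a circle with a 90° gap the completion stays
within 0.6% of the radius of the hidden arc with exact boundary data, and
within about 1% with estimated boundary data — well inside the 5% band the
tests enforce.  Note the planar circle is *not* a geodesic of this metric
(constant k with u₂ = 0 violates ḣ₄ = 0), so a small systematic deviation
is expected and observed.

## Synthetic fixtures and boundary estimation

`synth_occluded` builds circle/ellipse/Fourier-spline/line fixtures from
closed-form parameterizations, so boundary states and the hidden segment
are exact (curvature from the analytic formula
k = (x′y″ − y′x″)/|p′|³).  The generator emulates the geometry of an
occluded smooth contour — it does not emulate pixel rasterization, sensor
noise, or contour-extraction errors, so passing tests demonstrate the
geodesic machinery, not robustness to image-processing artifacts.  The
only randomness is the spline's harmonic coefficients (seeded, default
20211217).

`estimate_boundary_data` recovers (θ, k) at a polyline endpoint from a
9-sample window: a total-least-squares tangent oriented along the
traversal, then a quadratic fit in the tangent frame evaluated at the
endpoint.  The estimator is O(step²) on smooth curves (verified over three
step halvings).  A quadratic local fit is used instead of an algebraic
circle fit because it degrades gracefully to k = 0 on collinear data,
where circle fits are singular.

Rendering uses mathematical axes (y up); the raster row flip is isolated
in the PNG writer.  Renders are byte-deterministic for identical input.

## Problem sizes and numerical choices

Default experiment sizes — 200 map iterations per orbit, 20 round-trip
boundary problems in the acceptance-style tests, 1000-state samples for
the frame identities — were chosen as desk-scale runs that already
saturate the qualitative conclusions; flags expose larger runs.  Rank
tolerance is relative (1e−9 × largest singular value) so the exact-rank
claims are testable in floating point.  Dataclass constructors reject
non-finite inputs; equality of states compares θ modulo 2π.

## Known limitations

* Minimality of returned geodesics is numerical (shortest *found*), not
  certified; cut loci and conjugate points are out of scope.
* The fourth first integral is supported only by the thin-orbit evidence;
  no formula is claimed or searched for.
* The completion pipeline assumes boundary data of an isolated smooth
  contour; no isophote extraction, occlusion-mask inference, or learned
  components are included.
* Integration is by adaptive Runge-Kutta, not a symplectic scheme; the
  conservation targets are met by tolerance, not by structure
  preservation.
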