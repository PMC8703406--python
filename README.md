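# se2k — sub-Riemannian geodesics on SE(2) × ℝ

`se2k` is a geodesic toolkit for the curvature-extended model of contour
processing in the primary visual cortex (V1).  In the classical
Petitot–Citti–Sarti picture, V1 neurons detect local *position* and
*orientation* of image contours, and an occluded contour is completed by a
sub-Riemannian length minimizer in SE(2) = ℝ² × SO(2).  Physiological
evidence for curvature detectors motivates a four-dimensional extension:
the configuration space becomes

```
M = ℝ² × SO(2) × ℝ ∋ q = (x, y, θ, k)
```

with `k` the signed curvature of the contour.  Admissible motions satisfy
the control system

```
ẋ = u₁ cos θ,   ẏ = u₁ sin θ,   θ̇ = u₁ k,   k̇ = u₂,
```

i.e. q̇ = u₁X₁ + u₂X₂ with frame fields X₁ = (cos θ, sin θ, k, 0),
X₂ = (0, 0, 0, 1), and the cost is the sub-Riemannian length
l = ∫√(u₁² + u₂²) dt.  The package implements, with tests:

* **geometry** — the frame X₁…X₄ (X₃ = [X₁, X₂], X₄ = [X₁, X₃]), exact Lie
  brackets, the determinant identity det[X₁ X₂ X₃ X₄] ≡ 1, growth-vector
  (2, 3, 4) rank diagnostics, and the SE(2) symmetry/normalization.
* **extremals** — the Pontryagin-maximum-principle extremal systems: the
  normal Hamiltonian flow with H = (h₁² + h₂²)/2 in frame momenta
  hᵢ = ⟨p, Xᵢ⟩, its unit-speed form (h₁ = cos α, h₂ = sin α), the decoupled
  vertical sub-system in (α, h₃, h₄, k), the conserved quantities H, a, b,
  and the closed-form abnormal arcs (0, 0, 0, k₀ ± t).
* **integrate** — adaptive high-order integration (DOP853, rtol 1e-10) with
  first-integral drift monitoring and event-detected crossings of the
  section k = 0.
* **poincare** — the Liouville-integrability experiment: the closed-form
  periodic family α(t) = π/2 + t·h₃(0), k(t) = sin(t·h₃(0))/h₃(0), its
  first-return (Poincaré) map on k = 0, orbits of standard perturbed seeds,
  and a quantitative orbit-thickness diagnostic (thin closed curves ⇒
  evidence of a fourth first integral; scattered clouds ⇒ chaos).
* **completion** — two-point boundary-value solving by multi-start shooting
  over (α₀, h₃(0), h₄(0), T), and contour completion as the planar
  projection of the shortest converged geodesic.
* **synthio** — synthetic occluded-contour fixtures with exact ground
  truth, boundary-data estimation from raw polylines, CSV/JSON I/O,
  rendering, and the `se2k` command-line interface.

## Worked example: completing an occluded circle

```python
import math
from se2k import (OcclusionSpec, synth_occluded, BoundaryPair, solve_bvp,
                  complete_contour)

spec = OcclusionSpec("circle", {"radius": 2.0}, gap=(0.0, math.pi / 2), step=0.01)
contour = synth_occluded(spec)                  # visible polyline + exact truth
q0 = contour.boundary_data["gap_entry"]         # StateQ(2, 0, π/2, 0.5)
q1 = contour.boundary_data["gap_exit"]          # StateQ(0, 2, π,   0.5)

best = solve_bvp(BoundaryPair(q0, q1))[0]
print(f"geodesic length T = {best.duration:.6f}")
print(f"endpoint error    = {best.endpoint_error:.3e}")

completed = complete_contour(q0, q1)            # (n, 2) planar samples
```

Output:

```
geodesic length T = 3.137763
endpoint error    = 6.829e-11
max deviation from hidden arc = 0.0109  (0.54% of radius)
```

The boundary curvature 0.5 is the reciprocal of the osculating-circle
radius R = 2.  The geodesic's length (3.1378) is slightly below the hidden
quarter-arc's length (π ≈ 3.1416): the circle itself is *not* a geodesic of
this metric, but the minimizer tracks it to within 0.54% of the radius,
which is what makes these curves useful for completing circular-ish
occluded contours.

The same pipeline runs from the shell:

```sh
se2k synth --shape circle --radius 2 --gap 0,1.5708 --out contour.json
se2k complete --q0 2,0,1.5708,0.5 --q1 0,2,3.1416,0.5 --polyline completed.csv
se2k poincare --fig2 --n 200 --out-dir orbits --image orbits.png
```

The `poincare` command reproduces the integrability experiment: the
periodic seed (α, h₃, h₄) = (π/2, 1, 0) is a fixed point of the return map,
and the four perturbed seeds trace thin closed curves in (α mod 2π, h₃, h₄)
— the numerical signature that the normal Hamiltonian system possesses a
fourth independent first integral and is Liouville integrable.

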