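"""Control-theoretic geometry of the curvature-extended visual-cortex model.

The configuration space is the four-manifold M = R^2 x SO(2) x R with
coordinates q = (x, y, theta, k): planar position of a contour point, local
orientation of the contour, and its signed curvature.  Admissible motions of
a contour lift are spanned by two vector fields,

    X1 = (cos theta, sin theta, k, 0)   (advance along the contour),
    X2 = (0, 0, 0, 1)                   (change curvature in place),

so every admissible curve satisfies dq/dt = u1 X1 + u2 X2.  The iterated
Lie brackets X3 = [X1, X2] and X4 = [X1, X3] complete X1, X2 to a global
frame of the tangent bundle; the distribution span{X1, X2} therefore has
growth vector (2, 3, 4), an Engel-type bracket-generating structure, which
makes the system completely controllable.

The system is invariant under the roto-translation group SE(2) acting on
the (x, y, theta) components; this module also implements that action and
the normalizing transform that moves an arbitrary boundary state to
(0, 0, 0, k0), the standard reduction used by the boundary-value solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StateQ",
    "GroupElement",
    "wrap_angle",
    "angle_difference",
    "frame_field",
    "frame_matrix",
    "frame_determinant",
    "lie_bracket",
    "growth_vector",
    "apply_se2",
    "normalizing_transform",
]

_TWO_PI = 2.0 * math.pi


def wrap_angle(angle: float) -> float:
    """Wrap an angle to the interval [-pi, pi)."""
    return (angle + math.pi) % _TWO_PI - math.pi


def angle_difference(a: float, b: float) -> float:
    """Signed shortest angular distance a - b, in [-pi, pi)."""
    return wrap_angle(a - b)


def _require_finite(values, label: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{label} must have finite components, got {values!r}")


@dataclass(frozen=True)
class StateQ:
    """A point of M: planar position, orientation angle, signed curvature.

    ``theta`` is stored as an unwrapped real; two states are compared with
    ``theta`` taken modulo 2*pi (see :meth:`isclose`).  ``k`` is the signed
    curvature of the planar projection relative to the direction ``theta``
    (positive for counter-clockwise bending when moving forward, which is
    the convention forced by theta' = k * u1).
    """

    x: float
    y: float
    theta: float
    k: float

    def __post_init__(self) -> None:
        _require_finite([self.x, self.y, self.theta, self.k], "StateQ")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.theta, self.k], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StateQ":
        x, y, theta, k = np.asarray(arr, dtype=float)
        return cls(float(x), float(y), float(theta), float(k))

    def isclose(self, other: "StateQ", atol: float = 1e-9) -> bool:
        """Equality up to ``atol``, with theta compared modulo 2*pi."""
        return (
            abs(self.x - other.x) <= atol
            and abs(self.y - other.y) <= atol
            and abs(angle_difference(self.theta, other.theta)) <= atol
            and abs(self.k - other.k) <= atol
        )


@dataclass(frozen=True)
class GroupElement:
    """A roto-translation of the plane: rotation by ``phi`` about the origin
    followed by translation by ``(tx, ty)``."""

    tx: float
    ty: float
    phi: float

    def __post_init__(self) -> None:
        _require_finite([self.tx, self.ty, self.phi], "GroupElement")

    @classmethod
    def identity(cls) -> "GroupElement":
        return cls(0.0, 0.0, 0.0)

    def compose(self, other: "GroupElement") -> "GroupElement":
        """Group product self * other: apply ``other`` first, then ``self``."""
        c, s = math.cos(self.phi), math.sin(self.phi)
        tx = self.tx + c * other.tx - s * other.ty
        ty = self.ty + s * other.tx + c * other.ty
        return GroupElement(tx, ty, self.phi + other.phi)

    def inverse(self) -> "GroupElement":
        c, s = math.cos(self.phi), math.sin(self.phi)
        return GroupElement(-(c * self.tx + s * self.ty), -(-s * self.tx + c * self.ty), -self.phi)


def apply_se2(g: GroupElement, q: StateQ) -> StateQ:
    """Act with a roto-translation on a state: (x, y) is rotated by ``g.phi``
    about the origin and translated by ``(g.tx, g.ty)``; ``theta`` is
    incremented by ``g.phi``; the curvature ``k`` is untouched (it is an
    SE(2)-invariant of the contour)."""
    c, s = math.cos(g.phi), math.sin(g.phi)
    return StateQ(
        g.tx + c * q.x - s * q.y,
        g.ty + s * q.x + c * q.y,
        q.theta + g.phi,
        q.k,
    )


def normalizing_transform(q0: StateQ) -> GroupElement:
    """The group element ``g`` with ``apply_se2(g, q0) = (0, 0, 0, k0)``.

    Used to reduce a two-point boundary problem with arbitrary start state
    to the normalized start (0, 0, 0, k0).
    """
    c, s = math.cos(-q0.theta), math.sin(-q0.theta)
    return GroupElement(-(c * q0.x - s * q0.y), -(s * q0.x + c * q0.y), -q0.theta)


def frame_field(i: int, q: StateQ) -> np.ndarray:
    """Coordinate components of the frame field X_i at ``q``.

    X1, X2 span the distribution; X3 = [X1, X2] and X4 = [X1, X3] are the
    bracket-completions.  X2 and X3 are constant; X1 depends on (theta, k)
    and X4 on theta only.
    """
    if i == 1:
        return np.array([math.cos(q.theta), math.sin(q.theta), q.k, 0.0])
    if i == 2:
        return np.array([0.0, 0.0, 0.0, 1.0])
    if i == 3:
        return np.array([0.0, 0.0, -1.0, 0.0])
    if i == 4:
        return np.array([-math.sin(q.theta), math.cos(q.theta), 0.0, 0.0])
    raise ValueError(f"frame index must be in 1..4, got {i}")


def _frame_jacobian(i: int, q: StateQ) -> np.ndarray:
    """Exact Jacobian d(X_i)/d(x, y, theta, k) of the closed-form frame."""
    J = np.zeros((4, 4))
    if i == 1:
        J[0, 2] = -math.sin(q.theta)
        J[1, 2] = math.cos(q.theta)
        J[2, 3] = 1.0
    elif i == 4:
        J[0, 2] = -math.cos(q.theta)
        J[1, 2] = -math.sin(q.theta)
    elif i not in (2, 3):
        raise ValueError(f"frame index must be in 1..4, got {i}")
    return J


def lie_bracket(i: int, j: int, q: StateQ) -> np.ndarray:
    """Jacobi-Lie bracket [X_i, X_j] at ``q``, from the analytic Jacobians of
    the closed-form frame expressions (no finite differences)."""
    Xi = frame_field(i, q)
    Xj = frame_field(j, q)
    return _frame_jacobian(j, q) @ Xi - _frame_jacobian(i, q) @ Xj


def frame_matrix(q: StateQ) -> np.ndarray:
    """The 4x4 matrix whose columns are X1, X2, X3, X4 at ``q``."""
    return np.column_stack([frame_field(i, q) for i in (1, 2, 3, 4)])


def frame_determinant(q: StateQ) -> float:
    """det [X1 X2 X3 X4] at ``q``; identically 1 on all of M, which is the
    numerical witness that the frame is a global basis of the tangent space."""
    return float(np.linalg.det(frame_matrix(q)))


def growth_vector(q: StateQ, tol: float = 1e-9) -> tuple[int, int, int]:
    """Numerical ranks of span{X1,X2}, span{X1,X2,X3}, span{X1,..,X4} at ``q``.

    Rank is the number of singular values exceeding ``tol`` times the largest
    singular value.  Equals (2, 3, 4) at every point of M.
    """
    if tol <= 0:
        raise ValueError("rank tolerance must be positive")
    M = frame_matrix(q)

    def rank(cols: int) -> int:
        s = np.linalg.svd(M[:, :cols], compute_uv=False)
        return int(np.sum(s > tol * s[0]))

    return (rank(2), rank(3), rank(4))
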