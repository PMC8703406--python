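"""Extremal systems of the sub-Riemannian geodesic problem on SE(2) x R.

The Pontryagin maximum principle applied to the length (equivalently,
action) minimization problem yields two families of extremals:

* **Abnormal** (zero cost multiplier): pure curvature motions.  Naturally
  parameterized optimal abnormal arcs are t -> (0, 0, 0, k0 +/- t); the
  planar projection does not move at all.

* **Normal**: a Hamiltonian flow with H = (h1^2 + h2^2)/2, where
  h_i = <p, X_i> are the momenta along the frame fields.  Natural (unit
  speed) parameterization fixes the level H = 1/2, so h1 = cos(alpha),
  h2 = sin(alpha) for a polar angle alpha.  The vertical sub-system in
  (alpha, h3, h4, k) decouples from (x, y, theta) and is the object of the
  Poincare-map integrability experiment.

This module provides the right-hand sides of the three equivalent normal
systems (8-dim in h-coordinates, 7-dim in natural coordinates, 4-dim
reduced), the exact conversions between canonical Darboux momenta
(a, b, c, d) and frame momenta (h1..h4), the conserved quantities H, a, b,
the closed-form abnormal arcs, and the length/action functionals.

Array layouts used by the ODE drivers:

    normal8  : (x, y, theta, k, h1, h2, h3, h4)
    natural7 : (x, y, theta, k, alpha, h3, h4)
    reduced4 : (alpha, h3, h4, k)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import StateQ

__all__ = [
    "Costate",
    "HCoords",
    "NormalState",
    "NaturalState",
    "ReducedState",
    "ControlPair",
    "costate_to_h",
    "h_to_costate",
    "normal_rhs",
    "natural_rhs",
    "reduced_rhs",
    "normal_ode",
    "natural_ode",
    "reduced_ode",
    "hamiltonian",
    "first_integrals",
    "abnormal_state",
    "abnormal_state_general",
    "sr_length",
    "action",
    "controls_from_normal",
]


def _check_finite(values, label: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{label} must be finite, got {values!r}")


@dataclass(frozen=True)
class Costate:
    """Momentum covector in canonical Darboux coordinates (a, b, c, d)
    conjugate to (x, y, theta, k).  a and b are conserved along normal
    extremals (the system does not depend on x, y)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        _check_finite([self.a, self.b, self.c, self.d], "Costate")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=float)


@dataclass(frozen=True)
class HCoords:
    """Momenta along the frame fields, h_i = <p, X_i>.  On naturally
    parameterized normal extremals h1^2 + h2^2 = 1."""

    h1: float
    h2: float
    h3: float
    h4: float

    def __post_init__(self) -> None:
        _check_finite([self.h1, self.h2, self.h3, self.h4], "HCoords")

    def as_array(self) -> np.ndarray:
        return np.array([self.h1, self.h2, self.h3, self.h4], dtype=float)


@dataclass(frozen=True)
class NormalState:
    """Full state of the 8-dimensional normal Hamiltonian system."""

    q: StateQ
    h: HCoords

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.q.as_array(), self.h.as_array()])

    @classmethod
    def from_array(cls, arr) -> "NormalState":
        arr = np.asarray(arr, dtype=float)
        return cls(StateQ.from_array(arr[:4]), HCoords(*arr[4:8]))


@dataclass(frozen=True)
class NaturalState:
    """State of the naturally parameterized (unit-speed) normal system:
    h1 = cos(alpha), h2 = sin(alpha), with alpha unwrapped."""

    q: StateQ
    alpha: float
    h3: float
    h4: float

    def __post_init__(self) -> None:
        _check_finite([self.alpha, self.h3, self.h4], "NaturalState momenta")

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.q.as_array(), [self.alpha, self.h3, self.h4]])

    @classmethod
    def from_array(cls, arr) -> "NaturalState":
        arr = np.asarray(arr, dtype=float)
        return cls(StateQ.from_array(arr[:4]), float(arr[4]), float(arr[5]), float(arr[6]))

    def to_normal(self) -> NormalState:
        return NormalState(
            self.q,
            HCoords(math.cos(self.alpha), math.sin(self.alpha), self.h3, self.h4),
        )


@dataclass(frozen=True)
class ReducedState:
    """State of the decoupled vertical sub-system (alpha, h3, h4, k)."""

    alpha: float
    h3: float
    h4: float
    k: float

    def __post_init__(self) -> None:
        _check_finite([self.alpha, self.h3, self.h4, self.k], "ReducedState")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.h3, self.h4, self.k], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ReducedState":
        arr = np.asarray(arr, dtype=float)
        return cls(*(float(v) for v in arr[:4]))


@dataclass(frozen=True)
class ControlPair:
    """Controls (u1, u2): longitudinal speed along the contour and curvature
    rate.  Natural parameterization means u1^2 + u2^2 = 1."""

    u1: float
    u2: float

    def __post_init__(self) -> None:
        _check_finite([self.u1, self.u2], "ControlPair")


# ---------------------------------------------------------------------------
# momentum coordinate changes


def costate_to_h(q: StateQ, p: Costate) -> HCoords:
    """Frame momenta h_i = <p, X_i> from canonical momenta at the point q:

        h1 = a cos(theta) + b sin(theta) + c k,   h2 = d,
        h3 = -c,                                  h4 = -a sin(theta) + b cos(theta).
    """
    c, s = math.cos(q.theta), math.sin(q.theta)
    return HCoords(
        p.a * c + p.b * s + p.c * q.k,
        p.d,
        -p.c,
        -p.a * s + p.b * c,
    )


def h_to_costate(q: StateQ, h: HCoords) -> Costate:
    """Exact inverse of :func:`costate_to_h` at the same point q:

        a = (h1 + k h3) cos(theta) - h4 sin(theta),
        b = h4 cos(theta) + (h1 + k h3) sin(theta),
        c = -h3,  d = h2.
    """
    c, s = math.cos(q.theta), math.sin(q.theta)
    w = h.h1 + q.k * h.h3
    return Costate(w * c - h.h4 * s, h.h4 * c + w * s, -h.h3, h.h2)


# ---------------------------------------------------------------------------
# right-hand sides


def normal_ode(t: float, y) -> list[float]:
    """Vector field of the normal system in h-coordinates (8-dim layout)."""
    _x, _y, theta, k, h1, h2, h3, h4 = y
    ct, st = math.cos(theta), math.sin(theta)
    return [
        h1 * ct,
        h1 * st,
        h1 * k,
        h2,
        -h2 * h3,
        h1 * h3,
        h1 * h4,
        -k * h1 * (k * h3 + h1),
    ]


def natural_ode(t: float, y) -> list[float]:
    """Vector field of the unit-speed normal system (7-dim layout)."""
    _x, _y, theta, k, alpha, h3, h4 = y
    ca = math.cos(alpha)
    return [
        ca * math.cos(theta),
        ca * math.sin(theta),
        k * ca,
        math.sin(alpha),
        h3,
        h4 * ca,
        -k * ca * (k * h3 + ca),
    ]


def reduced_ode(t: float, y) -> list[float]:
    """Vector field of the decoupled (alpha, h3, h4, k) sub-system."""
    alpha, h3, h4, k = y
    ca = math.cos(alpha)
    return [h3, h4 * ca, -k * ca * (k * h3 + ca), math.sin(alpha)]


def normal_rhs(s: NormalState) -> np.ndarray:
    """Time derivative of the 8-dim normal state (x, y, theta, k, h1..h4)."""
    y = s.as_array()
    _check_finite(y, "NormalState")
    return np.array(normal_ode(0.0, y))


def natural_rhs(s: NaturalState) -> np.ndarray:
    """Time derivative of the 7-dim natural state (x, y, theta, k, alpha, h3, h4)."""
    y = s.as_array()
    _check_finite(y, "NaturalState")
    return np.array(natural_ode(0.0, y))


def reduced_rhs(s: ReducedState) -> np.ndarray:
    """Time derivative of the reduced state (alpha, h3, h4, k); identical to
    the vertical block of :func:`natural_rhs`."""
    return np.array(reduced_ode(0.0, s.as_array()))


# ---------------------------------------------------------------------------
# conserved quantities and controls


def hamiltonian(h: HCoords) -> float:
    """The maximized Hamiltonian H = (h1^2 + h2^2) / 2."""
    return 0.5 * (h.h1 * h.h1 + h.h2 * h.h2)


def first_integrals(s: NormalState) -> tuple[float, float, float]:
    """The three known independent first integrals (H, a, b) of the normal
    flow: the Hamiltonian and the two conserved canonical momenta."""
    p = h_to_costate(s.q, s.h)
    return (hamiltonian(s.h), p.a, p.b)


def controls_from_normal(s: NormalState) -> ControlPair:
    """Extremal controls of the normal case: u_i = h_i."""
    return ControlPair(s.h.h1, s.h.h2)


# ---------------------------------------------------------------------------
# abnormal extremals


def abnormal_state(k0: float, sgn: int, t: float) -> StateQ:
    """Naturally parameterized abnormal optimal arc at time t:
    (0, 0, 0, k0 + sgn * t).  Only the curvature coordinate moves."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if sgn not in (1, -1):
        raise ValueError("sgn must be +1 or -1")
    return StateQ(0.0, 0.0, 0.0, k0 + sgn * t)


def abnormal_state_general(k0: float, u2_values, times, t: float) -> StateQ:
    """General (not necessarily optimal) abnormal arc for a piecewise-constant
    curvature-rate control: (0, 0, 0, k0 + integral_0^t u2).

    ``u2_values[i]`` holds on ``[times[i], times[i+1])``.  The covector is
    constant and nonzero along such arcs; a trivial (all-zero) covector is
    excluded by the nontriviality condition of the maximum principle.
    """
    times = np.asarray(times, dtype=float)
    u2_values = np.asarray(u2_values, dtype=float)
    if times.ndim != 1 or len(times) != len(u2_values) + 1:
        raise ValueError("need len(times) == len(u2_values) + 1")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if t < times[0] or t > times[-1]:
        raise ValueError("t outside the control grid")
    upper = np.minimum(times[1:], t)
    lengths = np.clip(upper - times[:-1], 0.0, None)
    return StateQ(0.0, 0.0, 0.0, float(k0 + np.sum(u2_values * lengths)))


# ---------------------------------------------------------------------------
# cost functionals


def _control_arrays(controls, times):
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("need a time grid with at least two nodes")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    u = np.asarray(
        [(c.u1, c.u2) if isinstance(c, ControlPair) else tuple(c) for c in controls],
        dtype=float,
    )
    if u.shape != (len(times), 2):
        raise ValueError("controls must provide one (u1, u2) pair per grid node")
    return u, times


def sr_length(controls, times) -> float:
    """Sub-Riemannian length integral of sqrt(u1^2 + u2^2) over the grid
    (trapezoidal quadrature).  Equals the duration T for unit-speed arcs."""
    u, times = _control_arrays(controls, times)
    return float(np.trapezoid(np.hypot(u[:, 0], u[:, 1]), times))


def action(controls, times) -> float:
    """Action integral of (u1^2 + u2^2)/2; minimized by the same curves as
    the length once the duration is fixed (Cauchy-Schwarz)."""
    u, times = _control_arrays(controls, times)
    return float(np.trapezoid(0.5 * (u[:, 0] ** 2 + u[:, 1] ** 2), times))
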