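"""Two-point boundary-value solver for sub-Riemannian geodesics on
SE(2) x R, and contour completion via their planar projection.

Given boundary states q0, q1 (position, orientation, curvature) the solver
normalizes the problem with a roto-translation so that q0 = (0, 0, 0, k0),
then shoots naturally parameterized normal extremals from the normalized
start and adjusts the unknowns (alpha0, h3(0), h4(0), T) by multi-start
damped least squares until the endpoint matches q1.  Under natural
parameterization the duration T equals the sub-Riemannian length, so
sorting converged solutions by T puts the (numerically) shortest extremal
first; global optimality is not certified (no conjugate/cut-point
analysis).

The applied purpose is occluded-contour completion: the planar (x, y)
projection of the shortest arc between boundary data read off the visible
contour is the completed segment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .extremals import NaturalState
from .geometry import GroupElement, StateQ, angle_difference, apply_se2, normalizing_transform
from .integrate import ExtremalArc, IntegrationError, integrate_arc

__all__ = [
    "BoundaryPair",
    "ShootingSolution",
    "CompletionError",
    "shoot",
    "solve_bvp",
    "complete_contour",
]

_T_MIN = 0.05  # shortest admissible duration during optimization


@dataclass(frozen=True)
class BoundaryPair:
    """The two boundary states of the geodesic problem."""

    q0: StateQ
    q1: StateQ


@dataclass
class ShootingSolution:
    """One converged (or best-effort) extremal connecting the boundary pair.

    ``duration`` equals the sub-Riemannian length of the arc (natural
    parameterization); ``endpoint_error`` is the weighted residual norm in
    the normalized frame; ``cusps`` counts sign changes of the longitudinal
    control u1 = cos(alpha) along the arc (cusps of the planar projection,
    permitted and reported).
    """

    arc: ExtremalArc
    duration: float
    endpoint_error: float
    initial_momentum: tuple[float, float, float]
    converged: bool
    cusps: int = 0


class CompletionError(RuntimeError):
    """No extremal converged to the requested boundary data."""


def shoot(
    k0: float,
    momentum: tuple[float, float, float],
    T: float,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> StateQ:
    """Endpoint of the naturally parameterized normal extremal started at the
    normalized state (0, 0, 0, k0) with initial momentum (alpha0, h30, h40)."""
    if T <= 0:
        raise ValueError("duration must be positive")
    alpha0, h30, h40 = momentum
    y0 = np.array([0.0, 0.0, 0.0, k0, alpha0, h30, h40])
    arc = integrate_arc("natural7", y0, T, rtol=rtol, atol=atol, n_samples=2)
    return StateQ.from_array(arc.endpoint()[:4])


def _endpoint(k0, params, rtol, atol):
    alpha0, h30, h40, T = params
    y0 = np.array([0.0, 0.0, 0.0, k0, alpha0, h30, h40])
    arc = integrate_arc("natural7", y0, max(T, _T_MIN), rtol=rtol, atol=atol, n_samples=2)
    return arc.endpoint()[:4]


def _residual(end, target, weights):
    return np.array(
        [
            weights[0] * (end[0] - target[0]),
            weights[1] * (end[1] - target[1]),
            weights[2] * angle_difference(end[2], target[2]),
            weights[3] * (end[3] - target[3]),
        ]
    )


def _default_grid(target):
    """Deterministic multi-start grid over (alpha0, h30, h40, T).

    T guesses scale with d = planar distance + |curvature gap| (floored at
    0.1); the alpha0 sweep covers both signs of u1 = cos(alpha), since
    geodesics may need planar cusps.
    """
    d = max(math.hypot(target[0], target[1]) + abs(target[3]), 0.1)
    alphas = np.linspace(-0.75 * math.pi, 0.75 * math.pi, 8)
    hs = (-2.0, -0.5, 0.0, 0.5, 2.0)
    Ts = (0.5 * d, d, 2.0 * d, 4.0 * d)
    return [
        (a, h3, h4, T)
        for a, h3, h4, T in itertools.product(alphas, hs, hs, Ts)
    ]


def solve_bvp(
    bp: BoundaryPair,
    tol: float = 1e-6,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    grid=None,
    n_polish: int = 6,
    max_nfev: int = 120,
    screen_rtol: float = 1e-6,
    polish_rtol: float = 1e-9,
) -> list[ShootingSolution]:
    """Solve the two-point boundary problem q0 -> q1 by multi-start shooting.

    Every grid start is screened with one cheap forward integration; the
    most promising ``n_polish`` starts are refined by damped least squares
    over (alpha0, h30, h40, T).  Distinct converged solutions (endpoint
    error below ``tol``) are deduplicated, mapped back to the original
    frame, and returned sorted by duration (shortest first).  An empty list
    means no start converged.
    """
    g = normalizing_transform(bp.q0)
    q1n = apply_se2(g, bp.q1)
    k0 = bp.q0.k
    target = np.array([q1n.x, q1n.y, q1n.theta, q1n.k])

    if bp.q0.isclose(bp.q1, atol=1e-12):
        arc = integrate_arc("abnormal-closed-form", (k0, 1), _T_MIN, n_samples=2)
        arc.states = np.array([bp.q0.as_array(), bp.q0.as_array()])
        arc.times = np.array([0.0, 0.0])
        return [ShootingSolution(arc, 0.0, 0.0, (0.0, 0.0, 0.0), True)]

    if grid is None:
        grid = _default_grid(target)

    # 1) cheap screening of every start
    scored = []
    for params in grid:
        try:
            end = _endpoint(k0, params, screen_rtol, 1e-9)
        except IntegrationError:
            continue
        r = _residual(end, target, weights)
        scored.append((float(np.linalg.norm(r)), params))
    scored.sort(key=lambda item: item[0])

    # 2) damped least-squares polish of the best starts
    lb = [-np.inf, -np.inf, -np.inf, _T_MIN]
    ub = [np.inf, np.inf, np.inf, np.inf]
    solutions: list[ShootingSolution] = []
    for _, start in scored[:n_polish]:
        def fun(params):
            try:
                end = _endpoint(k0, params, polish_rtol, 1e-11)
            except IntegrationError:
                return np.full(4, 1e6)
            return _residual(end, target, weights)

        try:
            res = least_squares(
                fun,
                np.asarray(start, dtype=float),
                bounds=(lb, ub),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        sol = _build_solution(k0, res.x, target, weights, tol, g)
        if sol is not None:
            solutions.append(sol)

    # 3) deduplicate by momentum/duration distance, sort by length
    unique: list[ShootingSolution] = []
    for sol in solutions:
        key = np.array([*sol.initial_momentum, sol.duration])
        if any(
            np.linalg.norm(key - np.array([*u.initial_momentum, u.duration])) < 1e-3
            for u in unique
        ):
            continue
        unique.append(sol)
    unique.sort(key=lambda s: s.duration)
    return unique


def _build_solution(k0, params, target, weights, tol, g: GroupElement):
    """Verify a polished start at tight tolerance and package the arc mapped
    back to the original frame; returns None if verification diverges."""
    alpha0, h30, h40, T = params
    y0 = np.array([0.0, 0.0, 0.0, k0, alpha0, h30, h40])
    try:
        arc = integrate_arc("natural7", y0, float(T), rtol=1e-11, atol=1e-13, n_samples=201)
    except IntegrationError:
        return None
    err = float(np.linalg.norm(_residual(arc.endpoint()[:4], target, weights)))
    cos_a = np.cos(arc.states[:, 4])
    cusps = int(np.sum(np.abs(np.diff(np.sign(cos_a))) > 1))
    mapped = _transform_arc(arc, g.inverse())
    return ShootingSolution(
        mapped,
        float(T),
        err,
        (float(alpha0), float(h30), float(h40)),
        err < tol,
        cusps,
    )


def _transform_arc(arc: ExtremalArc, g: GroupElement) -> ExtremalArc:
    """Push the (x, y, theta) components of a natural-system arc by a
    roto-translation; the SE(2)-invariant components are untouched."""
    states = arc.states.copy()
    c, s = math.cos(g.phi), math.sin(g.phi)
    x, y = states[:, 0].copy(), states[:, 1].copy()
    states[:, 0] = g.tx + c * x - s * y
    states[:, 1] = g.ty + s * x + c * y
    states[:, 2] += g.phi
    return ExtremalArc(arc.system, arc.times, states, arc.drift, arc.tolerances, arc.sol)


def complete_contour(
    q0: StateQ,
    q1: StateQ,
    n_samples: int = 400,
    tol: float = 1e-6,
    **solver_options,
) -> np.ndarray:
    """Planar completion between two boundary states: the (x, y) projection
    of the shortest converged geodesic, densely resampled ((n_samples, 2))."""
    solutions = solve_bvp(BoundaryPair(q0, q1), tol=tol, **solver_options)
    converged = [s for s in solutions if s.converged]
    if not converged:
        raise CompletionError(
            f"no geodesic converged to the boundary data (best error: "
            f"{min((s.endpoint_error for s in solutions), default=math.inf):.3g})"
        )
    best = converged[0]
    g = normalizing_transform(q0)
    alpha0, h30, h40 = best.initial_momentum
    y0 = np.array([0.0, 0.0, 0.0, q0.k, alpha0, h30, h40])
    arc = integrate_arc("natural7", y0, best.duration, rtol=1e-11, atol=1e-13,
                        n_samples=n_samples)
    mapped = _transform_arc(arc, g.inverse())
    return mapped.states[:, :2].copy()
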