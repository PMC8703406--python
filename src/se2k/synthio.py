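"""Synthetic occluded-contour fixtures, boundary-data estimation, file I/O
and rendering.

A fixture is a smooth planar contour (circle, ellipse, random Fourier
"spline", or a degenerate straight line) with a parameter interval hidden
("occluded").  The generator returns the visible polyline, the *exact*
boundary states (position, tangent angle, signed curvature) at the two gap
endpoints, and the hidden ground-truth segment — so completion methods can
be scored against analytic truth.  A local least-squares estimator recovers
the same boundary data from raw point samples, emulating the realistic
setting where only pixels/polylines of the visible contour are available.

Randomness enters only through the Fourier-spline coefficients; fixtures
are reproducible from (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import StateQ

__all__ = [
    "Contour",
    "OcclusionSpec",
    "synth_occluded",
    "estimate_boundary_data",
    "read_contour",
    "write_contour",
    "render",
]

_TWO_PI = 2.0 * math.pi
DEFAULT_SEED = 20211217


@dataclass
class Contour:
    """A planar polyline with optional exact boundary states at the gap
    endpoints and the hidden ground-truth segment (synthetic fixtures)."""

    points: np.ndarray
    closed: bool = False
    boundary_data: dict = field(default_factory=dict)
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("a contour needs at least two (x, y) points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive contour points must be distinct")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=float)


@dataclass(frozen=True)
class OcclusionSpec:
    """Recipe for an occluded-contour fixture.

    ``shape`` is one of ``circle`` (params: radius, center), ``ellipse``
    (params: a, b, center), ``spline`` (params: radius, harmonics, amplitude)
    or ``line`` (params: length, origin, angle).  ``gap`` is the parameter
    interval to hide — the angular parameter for closed shapes, arc length
    for the line — and must lie strictly inside the parameter range.
    ``step`` is the parameter sampling step of the visible polyline.
    """

    shape: str
    params: dict
    gap: tuple[float, float]
    step: float = 0.02
    seed: int = DEFAULT_SEED


def _shape_functions(spec: OcclusionSpec):
    """Closed-form position/velocity/acceleration of the shape and its
    parameter range (t_max, closed)."""
    p = dict(spec.params)
    if spec.shape == "circle":
        R = float(p.get("radius", 1.0))
        cx, cy = p.get("center", (0.0, 0.0))

        def pos(t):
            return np.array([cx + R * np.cos(t), cy + R * np.sin(t)])

        def vel(t):
            return np.array([-R * np.sin(t), R * np.cos(t)])

        def acc(t):
            return np.array([-R * np.cos(t), -R * np.sin(t)])

        return pos, vel, acc, _TWO_PI, True

    if spec.shape == "ellipse":
        a, b = float(p.get("a", 2.0)), float(p.get("b", 1.0))
        cx, cy = p.get("center", (0.0, 0.0))

        def pos(t):
            return np.array([cx + a * np.cos(t), cy + b * np.sin(t)])

        def vel(t):
            return np.array([-a * np.sin(t), b * np.cos(t)])

        def acc(t):
            return np.array([-a * np.cos(t), -b * np.sin(t)])

        return pos, vel, acc, _TWO_PI, True

    if spec.shape == "spline":
        R = float(p.get("radius", 1.0))
        M = int(p.get("harmonics", 3))
        amp = float(p.get("amplitude", 0.04)) * R
        rng = np.random.default_rng(spec.seed)
        # random higher harmonics on top of the base circle, per coordinate
        coeffs = amp * rng.standard_normal((2, M, 2))  # (coord, harmonic, cos/sin)

        def series(t, deriv):
            out = np.zeros(2)
            base = {0: (np.cos(t), np.sin(t)),
                    1: (-np.sin(t), np.cos(t)),
                    2: (-np.cos(t), -np.sin(t))}[deriv]
            out[0] = R * base[0]
            out[1] = R * base[1]
            for j in range(M):
                m = j + 2
                c, s = np.cos(m * t), np.sin(m * t)
                if deriv == 0:
                    cm, sm = c, s
                elif deriv == 1:
                    cm, sm = -m * s, m * c
                else:
                    cm, sm = -m * m * c, -m * m * s
                out[0] += coeffs[0, j, 0] * cm + coeffs[0, j, 1] * sm
                out[1] += coeffs[1, j, 0] * cm + coeffs[1, j, 1] * sm
            return out

        return (lambda t: series(t, 0)), (lambda t: series(t, 1)), (lambda t: series(t, 2)), _TWO_PI, True

    if spec.shape == "line":
        L = float(p.get("length", 4.0))
        ox, oy = p.get("origin", (0.0, 0.0))
        ang = float(p.get("angle", 0.0))
        d = np.array([math.cos(ang), math.sin(ang)])

        def pos(t):
            return np.array([ox, oy]) + t * d

        def vel(t):
            return d.copy()

        def acc(t):
            return np.zeros(2)

        return pos, vel, acc, L, False

    raise ValueError(f"unknown shape {spec.shape!r}")


def _state_at(pos, vel, acc, t: float) -> StateQ:
    """Exact lifted state (x, y, theta, k) of a parametric curve at t."""
    P, V, A = pos(t), vel(t), acc(t)
    speed = float(np.hypot(V[0], V[1]))
    if speed == 0.0:
        raise ValueError("degenerate parameterization (zero velocity)")
    theta = math.atan2(V[1], V[0])
    k = float((V[0] * A[1] - V[1] * A[0]) / speed**3)
    return StateQ(float(P[0]), float(P[1]), theta, k)


def synth_occluded(spec: OcclusionSpec) -> Contour:
    """Generate an occluded-contour fixture with exact ground truth.

    The visible polyline is traversed in the direction of increasing
    parameter and ends at the gap entry, so ``estimate_boundary_data`` on
    its ``end`` (resp. ``start``) approximates the exact ``gap_entry``
    (resp. ``gap_exit``) state.  The hidden segment is sampled densely as
    ``truth``.
    """
    if spec.step <= 0:
        raise ValueError("sampling step must be positive")
    pos, vel, acc, t_max, closed = _shape_functions(spec)
    t0, t1 = spec.gap
    if not (0.0 <= t0 < t1) or (closed and t1 - t0 >= t_max) or (not closed and t1 >= t_max):
        raise ValueError(f"gap {spec.gap} must lie strictly inside the parameter range")

    if closed:
        ts = np.arange(t1, t0 + t_max + 0.5 * spec.step, spec.step)
        ts[-1] = t0 + t_max  # land exactly on the gap entry
    else:
        ts = np.arange(t1, t_max + 0.5 * spec.step, spec.step)
        ts[-1] = t_max
    visible = np.array([pos(t) for t in ts])

    truth_ts = np.linspace(t0, t1, max(int(math.ceil((t1 - t0) / (spec.step / 4))), 8))
    truth = np.array([pos(t) for t in truth_ts])

    boundary = {
        "gap_entry": _state_at(pos, vel, acc, t0),
        "gap_exit": _state_at(pos, vel, acc, t1),
    }
    return Contour(visible, closed=False, boundary_data=boundary, truth=truth)


def estimate_boundary_data(points, end: str, window: int = 9) -> StateQ:
    """Boundary state estimated from the first/last ``window`` samples of a
    polyline.

    The tangent angle comes from a total-least-squares line through the
    window oriented along the traversal direction (increasing index); the
    signed curvature from a local quadratic fit in the tangent frame, both
    evaluated at the endpoint.  Accuracy is O(step^2) on smooth curves.
    """
    pts = np.asarray(points, dtype=float)
    if window < 5:
        raise ValueError("window must cover at least 5 samples")
    if len(pts) < window:
        raise ValueError(f"need at least {window} points, got {len(pts)}")
    if end == "start":
        w, anchor = pts[:window], pts[0]
    elif end == "end":
        w, anchor = pts[-window:], pts[-1]
    else:
        raise ValueError("end must be 'start' or 'end'")

    centered = w - w.mean(axis=0)
    if float(np.max(np.abs(centered))) < 1e-14:
        raise ValueError("degenerate window: all samples coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if float(np.dot(direction, w[-1] - w[0])) < 0:
        direction = -direction
    theta0 = math.atan2(direction[1], direction[0])

    # local tangent frame at the endpoint; quadratic fit eta(xi)
    c, s = math.cos(theta0), math.sin(theta0)
    rel = w - anchor
    xi = rel[:, 0] * c + rel[:, 1] * s
    eta = -rel[:, 0] * s + rel[:, 1] * c
    if float(np.max(np.abs(xi))) < 1e-14:
        raise ValueError("degenerate window: zero tangential extent")
    coef = np.polyfit(xi, eta, 2)  # eta ~ coef[0] xi^2 + coef[1] xi + coef[2]
    slope, curv2 = float(coef[1]), 2.0 * float(coef[0])
    theta = theta0 + math.atan(slope)
    k = curv2 / (1.0 + slope * slope) ** 1.5
    return StateQ(float(anchor[0]), float(anchor[1]), theta, k)


# ---------------------------------------------------------------------------
# file I/O


def write_contour(contour: Contour, path) -> None:
    """Write a contour: ``.json`` keeps boundary data and truth; any other
    extension writes the plain ``x,y`` CSV of the visible points."""
    path = str(path)
    if path.endswith(".json"):
        payload = {
            "points": [[float(x), float(y)] for x, y in contour.points],
            "closed": bool(contour.closed),
            "boundary_data": {
                name: {"x": q.x, "y": q.y, "theta": q.theta, "k": q.k}
                for name, q in (contour.boundary_data or {}).items()
            },
            "truth": None
            if contour.truth is None
            else [[float(x), float(y)] for x, y in contour.truth],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    with open(path, "w", newline="") as fh:
        fh.write("x,y\n")
        for x, y in contour.points:
            fh.write(f"{x:.17g},{y:.17g}\n")


def read_contour(path) -> Contour:
    """Read a contour written by :func:`write_contour`; malformed CSV input
    raises an error naming the offending line."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        boundary = {
            name: StateQ(d["x"], d["y"], d["theta"], d["k"])
            for name, d in (payload.get("boundary_data") or {}).items()
        }
        truth = payload.get("truth")
        return Contour(
            np.asarray(payload["points"], dtype=float),
            closed=bool(payload.get("closed", False)),
            boundary_data=boundary,
            truth=None if truth is None else np.asarray(truth, dtype=float),
        )
    points = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "x,y":
            raise ValueError(f"{path}, line 1: expected header 'x,y', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}, line {lineno}: expected two columns, got {line!r}")
            try:
                points.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    return Contour(np.asarray(points, dtype=float))


# ---------------------------------------------------------------------------
# rendering


def render(contours, completed, path, size: int = 800, show_osculating: bool = True) -> None:
    """Deterministic raster of visible contours (solid) and completed
    segments (dashed), with optional osculating-circle glyphs of radius
    1/|k| at the stored boundary states.  Mathematical axes (y up); the
    raster row flip happens in the PNG writer."""
    if not contours and not completed:
        raise ValueError("nothing to render")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dpi = 100
    fig, ax = plt.subplots(figsize=(size / dpi, size / dpi), dpi=dpi)
    for contour in contours:
        ax.plot(contour.points[:, 0], contour.points[:, 1], "-", color="black", lw=1.5)
        if show_osculating:
            for q in (contour.boundary_data or {}).values():
                if q.k != 0.0:
                    r = 1.0 / abs(q.k)
                    cx = q.x - math.sin(q.theta) * (1.0 / q.k)
                    cy = q.y + math.cos(q.theta) * (1.0 / q.k)
                    circle = plt.Circle((cx, cy), r, fill=False, color="0.6", lw=0.8, ls=":")
                    ax.add_patch(circle)
    for poly in completed:
        poly = np.asarray(poly, dtype=float)
        ax.plot(poly[:, 0], poly[:, 1], "--", color="crimson", lw=1.5)
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.savefig(path, dpi=dpi, metadata={"Software": "se2k"})
    plt.close(fig)
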