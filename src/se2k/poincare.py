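"""Poincare-map experiment probing Liouville integrability of the reduced
extremal system.

The vertical sub-system in (alpha, h3, h4, k) admits a one-parameter family
of closed-form periodic trajectories,

    alpha(t) = pi/2 + t h3(0),  h3 = h3(0),  h4 = 0,  k(t) = sin(t h3(0)) / h3(0),

crossing the hyperplane k = 0 transversally.  Seeding first-return maps to
that section with small perturbations of the periodic initial point and
iterating many times produces orbits of the Poincare map in (alpha, h3, h4).
Orbits confined to thin closed curves are the numerical signature of an
additional conserved quantity (hence Liouville integrability of the full
normal Hamiltonian flow); scattered clouds would indicate chaos.  A
quantitative "thickness" diagnostic operationalizes the visual judgement.

The headline experiment iterates the map from four fixed perturbed seeds
(plus the periodic fixed point) — no randomness is involved.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .extremals import ReducedState, reduced_rhs
from .integrate import DEFAULT_ATOL, DEFAULT_RTOL, SectionTimeout, section_crossings

__all__ = [
    "PeriodicOrbit",
    "PoincareOrbit",
    "FIG_SEEDS",
    "CHAOS_THICKNESS_THRESHOLD",
    "periodic_orbit",
    "check_transversality",
    "poincare_orbit",
    "fig2_experiment",
    "orbit_thickness",
]

_TWO_PI = 2.0 * math.pi

#: the five standard seeds of the integrability experiment: the periodic
#: fixed point ("red") and four nearby perturbations, given as
#: (alpha0, h3_0, h4_0) on the section k = 0
FIG_SEEDS: dict[str, tuple[float, float, float]] = {
    "red": (math.pi / 2, 1.0, 0.0),
    "orange": (1.56, 0.94, 0.02),
    "green": (1.55, 1.06, 0.05),
    "black": (1.6, 1.14, 0.02),
    "blue": (1.58, 1.24, 0.01),
}

#: orbits with thickness below this are "curve-like" (consistent with an
#: extra first integral); uniform 3D scatter calibrates well above it
CHAOS_THICKNESS_THRESHOLD = 0.05


@dataclass(frozen=True)
class PeriodicOrbit:
    """A member of the closed-form periodic family, parameterized by the
    initial vertical momentum h3(0) != 0."""

    h30: float
    period: float
    state_at: Callable[[float], ReducedState]


@dataclass
class PoincareOrbit:
    """Ordered first-return points of one trajectory on the section k = 0.

    ``points`` holds raw (alpha, h3, h4) with alpha unwrapped;
    ``points_mod`` wraps alpha into [0, 2*pi).  ``complete`` is False when
    the integration timed out before all requested returns.
    """

    seed_state: ReducedState
    times: np.ndarray
    points: np.ndarray
    n: int
    complete: bool = True

    @property
    def points_mod(self) -> np.ndarray:
        pts = self.points.copy()
        pts[:, 0] = np.mod(pts[:, 0], _TWO_PI)
        return pts


def periodic_orbit(h30: float) -> PeriodicOrbit:
    """Closed-form periodic trajectory with parameter h3(0) = ``h30``.

    The period is measured empirically as the first one-sided (dk/dt > 0)
    return time of the flow to k = 0, rather than taken from a formula.
    """
    if h30 == 0:
        raise ValueError("h30 = 0 degenerates the periodic family (k' identically 1)")

    def state_at(t: float) -> ReducedState:
        return ReducedState(
            math.pi / 2 + t * h30, h30, 0.0, math.sin(t * h30) / h30
        )

    seed = state_at(0.0)
    (event,) = section_crossings(seed, 1, direction=1)
    return PeriodicOrbit(h30, float(event.t), state_at)


def check_transversality(s: ReducedState, k_tol: float = 1e-6) -> tuple[bool, float]:
    """Whether the flow is transversal to the section k = 0 at ``s``.

    Returns (flag, witness) where the witness is the k-component of the
    vector field, dk/dt = sin(alpha); transversality means it is nonzero.
    """
    if abs(s.k) > k_tol:
        raise ValueError(f"state is not on the section k=0 (|k|={abs(s.k):.3g})")
    witness = float(reduced_rhs(s)[3])
    return (abs(witness) > 1e-12, witness)


def poincare_orbit(
    seed: ReducedState,
    n: int,
    direction: int = 1,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> PoincareOrbit:
    """Iterate the first-return map ``n`` times from a seed on the section.

    Only one-sided crossings (dk/dt > 0 by default) are recorded, so the
    periodic trajectory appears as a fixed point.  On timeout the partial
    orbit is returned with ``complete=False``.
    """
    if n < 1:
        raise ValueError("need n >= 1 map iterations")
    ok, witness = check_transversality(seed)
    if not ok:
        raise ValueError(f"seed is tangent to the section (dk/dt = {witness:.3g})")
    complete = True
    try:
        events = section_crossings(seed, n, direction=direction, rtol=rtol, atol=atol)
    except SectionTimeout as exc:
        events = exc.events
        complete = False
    times = np.array([ev.t for ev in events])
    points = np.array([[ev.state.alpha, ev.state.h3, ev.state.h4] for ev in events])
    points = points.reshape(-1, 3)
    return PoincareOrbit(seed, times, points, len(events), complete)


def fig2_experiment(
    n: int = 200,
    out_dir=None,
    image_path=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> dict[str, PoincareOrbit]:
    """Run the five-seed integrability experiment (n map iterations each).

    Returns the orbits keyed by color name; optionally writes one CSV per
    orbit (``iter,t,alpha,alpha_mod_2pi,h3,h4``) under ``out_dir`` and a 3D
    scatter of all orbits in (alpha mod 2*pi, h3, h4) to ``image_path``.
    The default n = 200 keeps the experiment desk-scale; the qualitative
    picture matches longer runs (n = 1000) with proportionally more points
    per curve.
    """
    if n < 1:
        raise ValueError("need n >= 1 map iterations")
    orbits: dict[str, PoincareOrbit] = {}
    for name, (alpha0, h30, h40) in FIG_SEEDS.items():
        seed = ReducedState(alpha0, h30, h40, 0.0)
        orbits[name] = poincare_orbit(seed, n, rtol=rtol, atol=atol)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        for name, orbit in orbits.items():
            _orbit_to_csv(orbit, os.path.join(out_dir, f"orbit_{name}.csv"))
    if image_path is not None:
        plot_orbits(orbits, image_path)
    return orbits


def _orbit_to_csv(orbit: PoincareOrbit, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("iter", "t", "alpha", "alpha_mod_2pi", "h3", "h4"))
        for i, (t, p) in enumerate(zip(orbit.times, orbit.points), start=1):
            writer.writerow(
                [i, f"{t:.12g}", f"{p[0]:.12g}", f"{p[0] % _TWO_PI:.12g}",
                 f"{p[1]:.12g}", f"{p[2]:.12g}"]
            )


def plot_orbits(orbits: dict[str, PoincareOrbit], path) -> None:
    """3D scatter of map orbits in (alpha mod 2*pi, h3, h4), one color per
    orbit (the periodic orbit collapses to a single dot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for name, orbit in orbits.items():
        pts = orbit.points_mod
        ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=4, color=name, label=name)
    ax.set_xlabel(r"$\alpha\ \mathrm{mod}\ 2\pi$")
    ax.set_ylabel(r"$h_3$")
    ax.set_zlabel(r"$h_4$")
    ax.legend(loc="upper left", fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def orbit_thickness(points, n_harmonics: int = 8) -> float:
    """Dimensionless scatter of an orbit about its best closed curve.

    The points (rows of (alpha mod 2*pi, h3, h4)) are ordered by greedy
    nearest-neighbor chaining, parameterized by cumulative chord length,
    and fitted per-coordinate with a truncated Fourier series (a smooth
    closed curve).  Returned is (RMS residual distance) / (point-cloud
    diameter): near 0 for points on a 1D invariant curve, order 0.1+ for
    scattered/chaotic clouds.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (m, 3) array")
    m = len(pts)
    if m < 20:
        raise ValueError("need at least 20 points for a thickness estimate")

    # greedy nearest-neighbor chaining into a closed tour
    order = [0]
    remaining = set(range(1, m))
    current = 0
    while remaining:
        rem = np.fromiter(remaining, dtype=int)
        d = np.linalg.norm(pts[rem] - pts[current], axis=1)
        current = int(rem[np.argmin(d)])
        order.append(current)
        remaining.discard(current)
    chained = pts[order]

    # chord-length parameterization over the closed tour
    seg = np.linalg.norm(np.diff(np.vstack([chained, chained[:1]]), axis=0), axis=1)
    total = float(np.sum(seg))
    diameter = float(np.max(np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)))
    if total == 0.0 or diameter == 0.0:
        return 0.0
    s = 2.0 * math.pi * np.concatenate([[0.0], np.cumsum(seg[:-1])]) / total

    K = max(1, min(n_harmonics, m // 4))
    cols = [np.ones_like(s)]
    for j in range(1, K + 1):
        cols.append(np.cos(j * s))
        cols.append(np.sin(j * s))
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, chained, rcond=None)
    resid = chained - A @ coef
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return rms / diameter
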