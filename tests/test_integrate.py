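"""ODE driver: conservation, cross-system agreement, equivariance, time
reversal, and section-crossing event detection."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from se2k.extremals import ReducedState, natural_ode, normal_ode
from se2k.geometry import GroupElement, StateQ, apply_se2
from se2k.integrate import (
    ExtremalArc,
    SectionTimeout,
    arc_to_csv,
    events_to_csv,
    integrate_arc,
    invariant_drift,
    section_crossings,
)

TWO_PI = 2.0 * math.pi


def random_natural_init(rng, span=1.0):
    return np.array(
        [0.0, 0.0, rng.uniform(-1, 1), rng.uniform(-span, span),
         rng.uniform(0, TWO_PI), rng.uniform(-span, span), rng.uniform(-span, span)]
    )


def test_straight_line_arc():
    arc = integrate_arc("natural7", np.zeros(7), 5.0)
    np.testing.assert_allclose(arc.endpoint(), [5, 0, 0, 0, 0, 0, 0], atol=1e-12)
    drift = invariant_drift(arc)
    assert all(v < 1e-12 for v in drift.values())


def test_periodic_reduced_arc_returns_to_start():
    arc = integrate_arc("reduced4", [math.pi / 2, 1.0, 0.0, 0.0], TWO_PI)
    end = arc.endpoint()
    np.testing.assert_allclose(
        end, [math.pi / 2 + TWO_PI, 1.0, 0.0, 0.0], atol=1e-9
    )


def test_first_integral_conservation_long_horizon():
    rng = np.random.default_rng(5)
    for _ in range(6):
        alpha = rng.uniform(0, TWO_PI)
        y0 = np.array(
            [0, 0, rng.uniform(-1, 1), rng.uniform(-1, 1),
             math.cos(alpha), math.sin(alpha), rng.uniform(-1, 1), rng.uniform(-1, 1)]
        )
        arc = integrate_arc("normal8", y0, 50.0)
        assert arc.drift["H"] < 1e-8
        assert arc.drift["a"] < 1e-8
        assert arc.drift["b"] < 1e-8
        assert not arc.drift_flag


def test_normal_and_natural_systems_agree():
    rng = np.random.default_rng(6)
    for _ in range(3):
        y_nat = random_natural_init(rng)
        alpha = y_nat[4]
        y_nor = np.concatenate(
            [y_nat[:4], [math.cos(alpha), math.sin(alpha)], y_nat[5:]]
        )
        a1 = integrate_arc("natural7", y_nat, 20.0)
        a2 = integrate_arc("normal8", y_nor, 20.0)
        np.testing.assert_allclose(a1.states[:, :4], a2.states[:, :4], atol=1e-6)


def test_reduced_block_decouples_from_natural():
    rng = np.random.default_rng(16)
    y_nat = random_natural_init(rng)
    a_nat = integrate_arc("natural7", y_nat, 15.0)
    a_red = integrate_arc("reduced4", [y_nat[4], y_nat[5], y_nat[6], y_nat[3]], 15.0)
    vertical = a_nat.states[:, [4, 5, 6, 3]]
    np.testing.assert_allclose(vertical, a_red.states, atol=1e-7)


def test_time_reversal_returns_to_start():
    rng = np.random.default_rng(7)
    y0 = random_natural_init(rng)
    arc = integrate_arc("natural7", y0, 10.0)
    back = solve_ivp(
        lambda t, y: -np.asarray(natural_ode(t, y)),
        (0.0, 10.0),
        arc.endpoint(),
        method="DOP853",
        rtol=1e-10,
        atol=1e-12,
    )
    np.testing.assert_allclose(back.y[:, -1], y0, atol=1e-7)


def test_flow_commutes_with_se2_action():
    rng = np.random.default_rng(8)
    g = GroupElement(0.7, -1.2, 0.9)
    y0 = random_natural_init(rng)
    q_pushed = apply_se2(g, StateQ.from_array(y0[:4]))
    y0_pushed = np.concatenate([q_pushed.as_array(), y0[4:]])
    end_then_push = apply_se2(
        g, StateQ.from_array(integrate_arc("natural7", y0, 8.0).endpoint()[:4])
    )
    push_then_end = StateQ.from_array(
        integrate_arc("natural7", y0_pushed, 8.0).endpoint()[:4]
    )
    assert end_then_push.isclose(push_then_end, atol=1e-8)


def test_tolerance_halving_convergence():
    rng = np.random.default_rng(9)
    y0 = random_natural_init(rng)
    loose = integrate_arc("natural7", y0, 10.0, rtol=2e-8, atol=2e-10)
    tight = integrate_arc("natural7", y0, 10.0, rtol=1e-8, atol=1e-10)
    assert np.max(np.abs(loose.endpoint() - tight.endpoint())) < 10 * 2e-8 * (
        1 + np.max(np.abs(tight.endpoint()))
    )


def test_drift_detector_flags_perturbed_arc():
    arc = integrate_arc("normal8", [0, 0, 0, 0, 1, 0, 0.3, 0.1], 10.0)
    noisy = ExtremalArc(
        "normal8",
        arc.times,
        arc.states + 1e-3 * np.sin(np.arange(arc.states.size).reshape(arc.states.shape)),
        sol=None,
    )
    drift = invariant_drift(noisy)
    assert max(drift.values()) > 1e-4


def test_invariant_drift_rejects_reduced_arc():
    arc = integrate_arc("reduced4", [0.3, 1.0, 0.0, 0.0], 1.0)
    with pytest.raises(ValueError):
        invariant_drift(arc)


def test_integrate_arc_input_validation():
    with pytest.raises(ValueError):
        integrate_arc("natural7", np.zeros(7), -1.0)
    with pytest.raises(ValueError):
        integrate_arc("nope", np.zeros(7), 1.0)
    with pytest.raises(ValueError):
        integrate_arc("natural7", np.full(7, np.nan), 1.0)


def test_abnormal_closed_form_arc():
    arc = integrate_arc("abnormal-closed-form", (2.0, -1), 0.5, n_samples=6)
    np.testing.assert_allclose(arc.states[-1], [0, 0, 0, 1.5], atol=0)
    assert arc.columns == ("x", "y", "theta", "k")


def test_periodic_seed_one_sided_return():
    events = section_crossings(ReducedState(math.pi / 2, 1.0, 0.0, 0.0), 1, direction=1)
    assert events[0].t == pytest.approx(TWO_PI, abs=1e-8)
    s = events[0].state
    np.testing.assert_allclose(
        [s.alpha, s.h3, s.h4], [math.pi / 2 + TWO_PI, 1.0, 0.0], atol=1e-8
    )
    assert abs(s.k) < 1e-10
    assert events[0].direction == 1


def test_two_sided_crossings_interleave():
    events = section_crossings(ReducedState(math.pi / 2, 1.0, 0.0, 0.0), 2, direction=0)
    # k(t) = sin t first crosses zero downward at t = pi, then upward at 2*pi
    assert events[0].t == pytest.approx(math.pi, abs=1e-8)
    assert events[0].direction == -1
    assert events[1].t == pytest.approx(TWO_PI, abs=1e-8)
    assert events[1].direction == 1
    for ev in events:
        assert abs(ev.state.k) < 1e-10


def test_equilibrium_seed_rejected():
    with pytest.raises(ValueError):
        section_crossings(ReducedState(0.0, 0.0, 0.0, 0.0), 1)


def test_section_timeout_carries_partial_result():
    with pytest.raises(SectionTimeout) as err:
        section_crossings(
            ReducedState(math.pi / 2, 1.0, 0.0, 0.0), 5, direction=1, t_limit=7.0
        )
    assert len(err.value.events) == 1


def test_csv_serialization_round_trip(tmp_path):
    arc = integrate_arc("natural7", np.zeros(7), 1.0, n_samples=5)
    path = tmp_path / "arc.csv"
    arc_to_csv(arc, path)
    header, *rows = path.read_text().strip().split("\n")
    assert header == "t,x,y,theta,k,alpha,h3,h4"
    assert len(rows) == 5
    events = section_crossings(ReducedState(math.pi / 2, 1.0, 0.0, 0.0), 1)
    epath = tmp_path / "events.csv"
    events_to_csv(events, epath)
    assert epath.read_text().startswith("t,alpha,h3,h4,k,direction")
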