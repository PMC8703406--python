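"""Extremal right-hand sides, momentum coordinate changes, conserved
quantities, abnormal arcs, and the cost functionals."""

import math

import numpy as np
import pytest

from se2k.extremals import (
    ControlPair,
    Costate,
    HCoords,
    NaturalState,
    NormalState,
    ReducedState,
    abnormal_state,
    abnormal_state_general,
    action,
    controls_from_normal,
    costate_to_h,
    first_integrals,
    h_to_costate,
    hamiltonian,
    natural_rhs,
    normal_rhs,
    reduced_rhs,
    sr_length,
)
from se2k.geometry import StateQ, frame_field


def random_pairs(n, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        q = StateQ(*rng.uniform(-3, 3, 4))
        yield q, rng.uniform(-3, 3, 4)


@pytest.mark.parametrize(
    "q, p, expected",
    [
        (StateQ(0, 0, 0.0, 0.0), (1, 2, 3, 4), (1, 4, -3, 2)),
        (StateQ(0, 0, math.pi / 2, 1.0), (1, 0, 2, 0), (2, 0, -2, -1)),
    ],
)
def test_costate_to_h_examples(q, p, expected):
    h = costate_to_h(q, Costate(*p))
    np.testing.assert_allclose(h.as_array(), expected, atol=1e-14)


def test_h_to_costate_examples():
    q = StateQ(0, 0, 0.0, 0.0)
    p = h_to_costate(q, HCoords(1, 4, -3, 2))
    np.testing.assert_allclose(p.as_array(), (1, 2, 3, 4), atol=1e-14)
    zero = h_to_costate(StateQ(1, 1, 0.7, -2.0), HCoords(0, 0, 0, 0))
    np.testing.assert_allclose(zero.as_array(), 0.0, atol=0)


def test_momentum_round_trips():
    for q, vals in random_pairs(100, seed=11):
        p = Costate(*vals)
        back = h_to_costate(q, costate_to_h(q, p))
        np.testing.assert_allclose(back.as_array(), p.as_array(), atol=1e-12)
        h = HCoords(*vals)
        back_h = costate_to_h(q, h_to_costate(q, h))
        np.testing.assert_allclose(back_h.as_array(), h.as_array(), atol=1e-12)


@pytest.mark.parametrize(
    "state, expected",
    [
        # straight line: all momentum derivatives vanish
        ((0, 0, 0.0, 0.0, 1, 0, 0, 0), (1, 0, 0, 0, 0, 0, 0, 0)),
        # h1 = 0 kills every h-derivative except the curvature drive
        ((0, 0, 0.9, 3.0, 0, 1, 0, 0), (0, 0, 0, 1, 0, 0, 0, 0)),
        # hand-substituted generic point
        ((0, 0, 0.0, 1.0, 1, 0, 1, 1), (1, 0, 1, 0, 0, 1, 1, -2)),
    ],
)
def test_normal_rhs_examples(state, expected):
    s = NormalState.from_array(state)
    np.testing.assert_allclose(normal_rhs(s), expected, atol=1e-14)


@pytest.mark.parametrize(
    "state, expected",
    [
        ((0, 0, 0.0, 0.0, 0.0, 0, 0), (1, 0, 0, 0, 0, 0, 0)),
        # the periodic-family initial point: pure curvature growth
        ((0, 0, 0.0, 0.0, math.pi / 2, 1, 0), (0, 0, 0, 1, 1, 0, 0)),
    ],
)
def test_natural_rhs_examples(state, expected):
    s = NaturalState.from_array(state)
    np.testing.assert_allclose(natural_rhs(s), expected, atol=1e-15)


def test_natural_matches_normal_by_chain_rule():
    """The unit-speed system is the H=1/2 normal flow in polar momenta:
    q-block and (h3, h4) agree directly, and alpha' = h1 h2' - h2 h1'."""
    rng = np.random.default_rng(21)
    for _ in range(100):
        x, y, th, k, h3, h4 = rng.uniform(-2, 2, 6)
        alpha = rng.uniform(-6, 6)
        nat = NaturalState(StateQ(x, y, th, k), alpha, h3, h4)
        dn = natural_rhs(nat)
        dm = normal_rhs(nat.to_normal())
        np.testing.assert_allclose(dn[:4], dm[:4], atol=1e-13)
        np.testing.assert_allclose(dn[5:], dm[6:], atol=1e-13)
        h1, h2 = math.cos(alpha), math.sin(alpha)
        alpha_dot = h1 * dm[5] - h2 * dm[4]
        np.testing.assert_allclose(dn[4], alpha_dot, atol=1e-13)


def test_reduced_is_vertical_block_of_natural():
    rng = np.random.default_rng(22)
    for _ in range(100):
        alpha, h3, h4, k = rng.uniform(-3, 3, 4)
        red = reduced_rhs(ReducedState(alpha, h3, h4, k))
        nat = natural_rhs(NaturalState(StateQ(0, 0, 0, k), alpha, h3, h4))
        np.testing.assert_allclose(red, [nat[4], nat[5], nat[6], nat[3]], atol=1e-15)
    np.testing.assert_allclose(
        reduced_rhs(ReducedState(math.pi / 2, 1, 0, 0)), (1, 0, 0, 1), atol=1e-15
    )
    np.testing.assert_allclose(reduced_rhs(ReducedState(0, 0, 0, 0)), 0.0, atol=0)


@pytest.mark.parametrize(
    "h, expected", [((1, 0, 9, -2), 0.5), ((0, 0, 1, 1), 0.0), ((3, 4, 0, 0), 12.5)]
)
def test_hamiltonian(h, expected):
    assert hamiltonian(HCoords(*h)) == pytest.approx(expected, abs=1e-15)


def test_first_integrals_substitution():
    s = NormalState(StateQ(0, 0, 0.0, 0.0), HCoords(1, 0, 0, 0))
    np.testing.assert_allclose(first_integrals(s), (0.5, 1.0, 0.0), atol=1e-15)
    s2 = NormalState(StateQ(0, 0, 0.0, 0.0), HCoords(0, 1, 0, 2))
    np.testing.assert_allclose(first_integrals(s2), (0.5, 0.0, 2.0), atol=1e-15)


def test_abnormal_closed_form():
    assert abnormal_state(0.0, 1, 1.0) == StateQ(0, 0, 0, 1.0)
    assert abnormal_state(5.0, -1, 0.0) == StateQ(0, 0, 0, 5.0)
    assert abnormal_state(2.0, -1, 0.5) == StateQ(0, 0, 0, 1.5)
    with pytest.raises(ValueError):
        abnormal_state(0.0, 1, -0.1)
    with pytest.raises(ValueError):
        abnormal_state(0.0, 2, 0.1)


def test_abnormal_satisfies_control_system_exactly():
    """d/dt (0,0,0,k0 +/- t) equals u1 X1 + u2 X2 with (u1, u2) = (0, +/-1)."""
    for sgn in (1, -1):
        for t in (0.0, 0.5, 1.0, 2.0):
            q = abnormal_state(0.7, sgn, t)
            assert (q.x, q.y, q.theta) == (0.0, 0.0, 0.0)
            rhs = 0.0 * frame_field(1, q) + sgn * frame_field(2, q)
            np.testing.assert_array_equal(rhs, [0.0, 0.0, 0.0, float(sgn)])


def test_abnormal_general_step_control():
    times = [0.0, 1.0, 2.0, 3.0]
    u2 = [1.0, -0.5, 2.0]
    q = abnormal_state_general(1.0, u2, times, 2.5)
    assert q == StateQ(0, 0, 0, 1.0 + 1.0 - 0.5 + 1.0)
    with pytest.raises(ValueError):
        abnormal_state_general(0.0, u2, times, 4.0)
    with pytest.raises(ValueError):
        abnormal_state_general(0.0, [1.0], [0.0, 0.0], 0.0)


def test_nontrivial_covector_required():
    with pytest.raises(ValueError):
        Costate(0.0, float("inf"), 0.0, 0.0)


def test_length_and_action_quadrature():
    ts = np.linspace(0.0, 2.0, 41)
    straight = [ControlPair(1.0, 0.0)] * len(ts)
    assert sr_length(straight, ts) == pytest.approx(2.0, abs=1e-14)
    assert action(straight, ts) == pytest.approx(1.0, abs=1e-14)
    ts1 = np.linspace(0.0, 1.0, 11)
    const = [ControlPair(3.0, 4.0)] * len(ts1)
    assert sr_length(const, ts1) == pytest.approx(5.0, abs=1e-14)
    assert action(const, ts1) == pytest.approx(12.5, abs=1e-14)
    # naturally parameterized arcs: length = T, action = T/2
    T = 3.7
    tsT = np.linspace(0.0, T, 30)
    unit = [ControlPair(math.cos(0.3 * t), math.sin(0.3 * t)) for t in tsT]
    assert sr_length(unit, tsT) == pytest.approx(T, abs=1e-12)
    assert action(unit, tsT) == pytest.approx(T / 2, abs=1e-12)
    with pytest.raises(ValueError):
        sr_length(straight, np.array([0.0]))
    with pytest.raises(ValueError):
        sr_length(const, np.array([0.0, 0.0]))


def test_controls_from_normal():
    s = NormalState(StateQ(0, 0, 0, 0), HCoords(math.cos(0.4), math.sin(0.4), 7, -1))
    u = controls_from_normal(s)
    assert math.hypot(u.u1, u.u2) == pytest.approx(1.0, abs=1e-15)
    zero = controls_from_normal(NormalState(StateQ(0, 0, 0, 0), HCoords(0, 0, 1, 1)))
    assert (zero.u1, zero.u2) == (0.0, 0.0)
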