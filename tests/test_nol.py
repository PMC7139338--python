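"""Nonlinear schedule and random opposition-based learning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from nolhho.hho import HawkPopulation, linear_energy_factor
from nolhho.nol import (nonlinear_energy_factor, opposite_point,
                        rol_transform, select_survivors)

T = 500


def test_schedule_endpoints():
    assert nonlinear_energy_factor(0, T) == pytest.approx(2.0)
    assert nonlinear_energy_factor(T, T) == pytest.approx(0.0, abs=1e-12)
    assert nonlinear_energy_factor(T / 2, T) == pytest.approx(1.9630, abs=1e-4)
    with pytest.raises(ValueError):
        nonlinear_energy_factor(-1, T)
    with pytest.raises(ValueError):
        nonlinear_energy_factor(T + 1, T)


def test_schedule_strictly_decreasing_and_dominant():
    ts = np.linspace(0, T, 2001)
    vals = np.array([nonlinear_energy_factor(t, T) for t in ts])
    # non-increasing everywhere; strictly decreasing once (t/T)^5 is
    # representable above double-precision rounding of exp
    assert np.all(np.diff(vals) <= 0)
    coarse = np.array([nonlinear_energy_factor(t, T)
                       for t in np.linspace(0.05 * T, T, 41)])
    assert np.all(np.diff(coarse) < 0)
    interior = ts[1:-1]
    lin = np.array([linear_energy_factor(t, T) for t in interior])
    assert np.all(vals[1:-1] > lin)


def test_schedule_crosses_one_after_halfway():
    """The E1 = 1 crossing happens past T/2: exploration persists into
    the second half of the run, unlike the linear schedule."""
    t_star = brentq(lambda t: nonlinear_energy_factor(t, T) - 1.0, 0, T)
    assert t_star / T > 0.5


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
def test_opposite_point_involution(xs):
    x = np.array(xs)
    lower, upper = np.zeros_like(x), np.ones_like(x)
    opp = opposite_point(x, lower, upper)
    np.testing.assert_allclose(opposite_point(opp, lower, upper), x,
                               atol=1e-12)
    mid = (lower + upper) / 2
    np.testing.assert_allclose(opposite_point(mid, lower, upper), mid)


def test_opposite_point_example():
    assert opposite_point(np.array([0.2]), np.zeros(1),
                          np.ones(1))[0] == pytest.approx(0.8)


def test_rol_reduces_to_opposition_at_r_one(scripted_rng):
    x = np.array([0.2, 0.7, 0.5])
    lower, upper = np.zeros(3), np.ones(3)

    class OnesRNG:
        def random(self, shape=None):
            return np.ones(shape) if shape is not None else 1.0

    out = rol_transform(x, lower, upper, OnesRNG())
    np.testing.assert_allclose(out, opposite_point(x, lower, upper))

    class ZerosRNG:
        def random(self, shape=None):
            return np.zeros(shape) if shape is not None else 0.0

    # r = 0 gives a + b, clamped to the upper bound wherever a > 0
    lo = np.array([0.5, 0.0])
    hi = np.array([1.0, 1.0])
    out = rol_transform(np.array([0.9, 0.9]), lo, hi, ZerosRNG())
    np.testing.assert_allclose(out, [1.0, 1.0])


def test_rol_containment_and_determinism(rng):
    lower = np.array([-3.0, 0.0, 1.0])
    upper = np.array([-1.0, 2.0, 4.0])
    for _ in range(200):
        x = rng.uniform(lower, upper, size=(50, 3))
        out = rol_transform(x, lower, upper, rng)
        assert np.all(out >= lower) and np.all(out <= upper)
    a = rol_transform(x, lower, upper, np.random.default_rng(3))
    b = rol_transform(x, lower, upper, np.random.default_rng(3))
    np.testing.assert_array_equal(a, b)


def test_rol_per_dimension_vs_scalar(rng):
    x = np.tile(np.array([[0.5, 0.5, 0.5, 0.5]]), (1, 1))
    lower, upper = np.zeros(4), np.ones(4)
    per_dim = rol_transform(x, lower, upper, np.random.default_rng(0))
    # per-dimension factors give unequal coordinates almost surely
    assert len(np.unique(np.round(per_dim, 12))) > 1
    scalar = rol_transform(x, lower, upper, np.random.default_rng(0),
                           scalar_rand=True)
    assert len(np.unique(np.round(scalar, 12))) == 1


def _sphere(x):
    return np.sum(np.atleast_2d(x) ** 2, axis=1)


def _make_pop(pos):
    fit = _sphere(pos)
    i = int(np.argmin(fit))
    return HawkPopulation(pos.copy(), fit, pos[i].copy(), float(fit[i]))


def test_select_survivors_elitism():
    pos = np.array([[0.5, 0.5], [0.6, 0.6]])
    pop = _make_pop(pos)
    worse = pos + 10.0
    out = select_survivors(pop, worse, _sphere)
    np.testing.assert_array_equal(np.sort(out.positions, axis=0),
                                  np.sort(pos, axis=0))
    better = pos * 0.1
    out = select_survivors(pop, better, _sphere)
    np.testing.assert_array_equal(np.sort(out.positions, axis=0),
                                  np.sort(better, axis=0))
    assert out.rabbit_fitness == _sphere(better).min()


def test_select_survivors_never_degrades_mean(rng):
    for _ in range(1000):
        pos = rng.uniform(-5, 5, size=(8, 3))
        pop = _make_pop(pos)
        mirrored = rol_transform(pos, np.full(3, -5.0), np.full(3, 5.0), rng)
        before_mean = pop.fitnesses.mean()
        before_best = pop.rabbit_fitness
        out = select_survivors(pop, mirrored, _sphere)
        assert out.fitnesses.mean() <= before_mean + 1e-12
        assert out.rabbit_fitness <= before_best + 1e-12


def test_select_survivors_shape_check():
    pop = _make_pop(np.zeros((3, 2)))
    with pytest.raises(ValueError):
        select_survivors(pop, np.zeros((2, 2)), _sphere)
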