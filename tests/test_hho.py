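"""Core optimizer: energy machinery, move operators, and the run loop."""

import numpy as np
import pytest

from nolhho import benchmarks as B
from nolhho.hho import (HHOConfig, HawkPopulation, SearchDomain,
                        escape_energy, exploitation_move, exploration_move,
                        initialize_population, levy_step, linear_energy_factor,
                        mantegna_sigma, run)
from nolhho.nol import nonlinear_energy_factor


def _sphere(x):
    x = np.atleast_2d(x)
    return np.sum(x * x, axis=1)


@pytest.fixture
def unit_domain():
    return SearchDomain(np.zeros(2), np.ones(2))


def test_domain_validation():
    with pytest.raises(ValueError):
        SearchDomain(np.ones(3), np.zeros(3))
    d = SearchDomain(np.array([-1.0, 0.0]), np.array([1.0, 2.0]))
    assert d.dim == 2
    np.testing.assert_array_equal(d.clamp(np.array([5.0, -5.0])),
                                  np.array([1.0, 0.0]))


def test_initialize_population(unit_domain, rng):
    cfg = HHOConfig(n_hawks=30, seed=9)
    pop = initialize_population(unit_domain, cfg, rng, _sphere)
    assert pop.positions.shape == (30, 2)
    assert np.all(pop.positions >= 0) and np.all(pop.positions <= 1)
    assert pop.rabbit_fitness == pop.fitnesses.min()

    pop2 = initialize_population(unit_domain, cfg,
                                 np.random.default_rng(77), _sphere)
    pop3 = initialize_population(unit_domain, cfg,
                                 np.random.default_rng(77), _sphere)
    np.testing.assert_array_equal(pop2.positions, pop3.positions)

    single = initialize_population(
        unit_domain, HHOConfig(n_hawks=1), rng, _sphere)
    np.testing.assert_array_equal(single.rabbit_position, single.positions[0])


def test_escape_energy_endpoints_and_envelope(rng):
    assert linear_energy_factor(500, 500) == 0.0
    assert linear_energy_factor(0, 500) == 2.0
    assert escape_energy(500, 500, rng) == 0.0
    with pytest.raises(ValueError):
        escape_energy(-1, 500, rng)
    # symmetry about 0 and |E| <= E1(t) over many draws
    t, T = 100, 500
    e1 = linear_energy_factor(t, T)
    draws = np.array([escape_energy(t, T, rng) for _ in range(100_000)])
    assert np.all(np.abs(draws) <= e1 + 1e-12)
    assert abs(draws.mean()) < 0.01
    # uniform on (-E1, E1): variance should be E1^2/3
    assert draws.var() == pytest.approx(e1 ** 2 / 3, rel=0.02)


def test_schedule_split_linear_vs_nonlinear():
    """The linear envelope kills exploration after T/2; the nonlinear
    one keeps E1 >= 1 well beyond it."""
    T = 500
    for t in range(T // 2 + 1, T + 1):
        assert linear_energy_factor(t, T) < 1.0
    assert nonlinear_energy_factor(0.75 * T, T) > 1.0
    assert nonlinear_energy_factor(0.75 * T, T) > linear_energy_factor(0.75 * T, T)


def test_exploration_move_reductions(scripted_rng, unit_domain):
    pos = np.full((4, 2), 0.25)
    pop = HawkPopulation(pos.copy(), _sphere(pos), pos[0].copy(),
                         float(_sphere(pos)[0]))
    # first branch (q >= 0.5) with r1 = 0 collapses to X_rand = p
    srng = scripted_rng([0.9, 0.0, 0.3])
    out = exploration_move(pos[0], pop, unit_domain, srng)
    np.testing.assert_allclose(out, pos[0])
    # second branch (q < 0.5) with r3 = 0 gives rabbit - mean exactly
    pop.rabbit_position = np.array([0.8, 0.8])
    srng = scripted_rng([0.1, 0.0, 0.5])
    out = exploration_move(pos[0], pop, unit_domain, srng)
    np.testing.assert_allclose(out, np.array([0.8, 0.8]) - pos.mean(axis=0))


def test_exploration_branch_frequency_and_containment(unit_domain, rng,
                                                      scripted_rng):
    """Strategy selection is a fair coin; outputs stay inside the box."""
    pos = rng.random((10, 2))
    pop = HawkPopulation(pos, _sphere(pos), pos[0].copy(), 0.1)
    n = 20_000
    hits = 0
    for k in range(n):
        q = rng.random()
        hits += q >= 0.5
        out = exploration_move(pos[0], pop, unit_domain,
                               scripted_rng([q], seed=k))
        assert np.all(out >= 0) and np.all(out <= 1)
    assert hits / n == pytest.approx(0.5, abs=0.01)


def test_exploitation_hard_besiege_reduction(scripted_rng, unit_domain):
    pos = np.array([[0.2, 0.6], [0.4, 0.1]])
    pop = HawkPopulation(pos.copy(), _sphere(pos), np.array([0.3, 0.3]), 0.18)
    # r >= 0.5 and |E| < 0.5 -> hard besiege; with E = 0 the hawk lands
    # exactly on the rabbit
    out = exploitation_move(pos[0], 1.0, pop, 0.0, unit_domain,
                            lambda x: float(_sphere(x)[0]),
                            scripted_rng([0.9]))
    np.testing.assert_allclose(out, pop.rabbit_position)


def test_exploitation_dive_is_greedy(unit_domain, rng):
    """Dive branches never return a point worse than the incumbent."""
    obj = lambda x: float(_sphere(x)[0])
    for _ in range(1000):
        pos = rng.random((5, 2))
        pop = HawkPopulation(pos.copy(), _sphere(pos),
                             pos[np.argmin(_sphere(pos))].copy(),
                             float(_sphere(pos).min()))
        E = rng.uniform(-1, 1)
        fx = obj(pos[0])
        # force a dive branch with first draw r < 0.5
        from conftest import ScriptedRNG
        srng = ScriptedRNG([0.2], seed=int(rng.integers(2 ** 31)))
        out = exploitation_move(pos[0], fx, pop, E, unit_domain, obj, srng)
        assert obj(out) <= fx + 1e-12


def test_levy_step_scale_and_tails(rng):
    assert mantegna_sigma(1.5) == pytest.approx(0.6966, abs=1e-4)
    with pytest.raises(ValueError):
        levy_step(3, 0.5, rng)
    steps = np.concatenate([levy_step(100, 1.5, rng) for _ in range(1000)])
    med = np.median(np.abs(steps))
    heavy = np.mean(np.abs(steps) > 10 * med)
    # a Gaussian with matched median would essentially never exceed 10x
    assert heavy > 1e-3


def test_run_sphere_and_invariants():
    spec = B.get_spec("F1", dim_override=2)
    res = run(spec, HHOConfig(seed=4))
    assert res.best_fitness <= 1e-10
    assert np.all(np.diff(res.trace) <= 0)
    res2 = run(spec, HHOConfig(seed=4))
    assert res.best_fitness == res2.best_fitness
    np.testing.assert_array_equal(res.best_position, res2.best_position)
    assert res.to_json()  # serializable


def test_run_nol_variant_and_early_stop():
    spec = B.get_spec("F9", dim_override=5)
    res = run(spec, HHOConfig.nol(seed=11), f_target=1e-3)
    assert res.best_fitness <= 1e-3
    assert res.n_iterations_run <= 500
    # positions respect the box throughout: final best inside bounds
    assert np.all(res.best_position >= spec.lower)
    assert np.all(res.best_position <= spec.upper)


def test_config_validation():
    with pytest.raises(ValueError):
        HHOConfig(n_hawks=0)
    with pytest.raises(ValueError):
        HHOConfig(schedule="exponential")
    cfg = HHOConfig.nol()
    assert cfg.schedule == "nonlinear" and cfg.rol
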