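"""Harris hawks optimization (HHO).

A population ("hawks") chases the best solution found so far (the
"rabbit").  Each iteration every hawk draws an escape energy
``E = (2 r - 1) * E1(t)``; when ``|E| >= 1`` the hawk explores (two
equal-probability global moves), otherwise it exploits with one of four
equal-probability besiege strategies, two of which add Levy-flight rapid
dives accepted greedily.  The envelope ``E1`` decays from 2 to 0 over the
run: linearly for the baseline algorithm, or along a nonlinear
slow-early/fast-late curve when the improved schedule is selected.  A
random opposition-based learning (ROL) step can additionally mirror the
whole population each iteration and keep the best half of the union.

Minimization convention throughout; callers negate to maximize.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .benchmarks import ObjectiveSpec

__all__ = [
    "SearchDomain", "HHOConfig", "HawkPopulation", "RunResult",
    "linear_energy_factor", "energy_factor", "escape_energy",
    "initialize_population", "exploration_move", "exploitation_move",
    "levy_step", "run",
]


@dataclass(frozen=True)
class SearchDomain:
    """A box-constrained continuous search space."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("bound shapes differ")
        if not np.all(self.lower < self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    @classmethod
    def from_spec(cls, spec: ObjectiveSpec) -> "SearchDomain":
        return cls(spec.lower, spec.upper)


@dataclass(frozen=True)
class HHOConfig:
    """Optimizer configuration.

    Defaults (30 hawks, 500 iterations) are the standard benchmarking
    protocol.  ``schedule`` selects the E1 envelope; ``rol`` switches on
    the random opposition-based learning step.  ``schedule="nonlinear"``
    together with ``rol=True`` is the improved (NOL) variant.
    """

    n_hawks: int = 30
    n_iterations: int = 500
    levy_beta: float = 1.5
    seed: int = 0
    schedule: str = "linear"
    rol: bool = False
    rol_scalar_rand: bool = False  # per-individual scalar r instead of per-dim

    def __post_init__(self):
        if self.n_hawks < 1 or self.n_iterations < 1:
            raise ValueError("n_hawks and n_iterations must be positive")
        if self.schedule not in ("linear", "nonlinear"):
            raise ValueError("schedule must be 'linear' or 'nonlinear'")

    @classmethod
    def nol(cls, **kw) -> "HHOConfig":
        """The improved configuration: nonlinear schedule + ROL."""
        kw.setdefault("schedule", "nonlinear")
        kw.setdefault("rol", True)
        return cls(**kw)


@dataclass
class HawkPopulation:
    """Positions and fitnesses of the flock plus the incumbent rabbit."""

    positions: np.ndarray        # (n_hawks, dim)
    fitnesses: np.ndarray        # (n_hawks,)
    rabbit_position: np.ndarray  # (dim,)
    rabbit_fitness: float

    @property
    def n_hawks(self) -> int:
        return self.positions.shape[0]

    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def refresh_rabbit(self) -> None:
        """Elitist rabbit update: adopt the best hawk if it improved."""
        i = int(np.argmin(self.fitnesses))
        if self.fitnesses[i] < self.rabbit_fitness:
            self.rabbit_fitness = float(self.fitnesses[i])
            self.rabbit_position = self.positions[i].copy()


@dataclass
class RunResult:
    """Outcome of one optimization run."""

    best_fitness: float
    best_position: np.ndarray
    trace: np.ndarray            # per-iteration rabbit fitness, non-increasing
    n_iterations_run: int
    config: HHOConfig
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "best_fitness": self.best_fitness,
            "best_position": self.best_position.tolist(),
            "trace": self.trace.tolist(),
            "n_iterations_run": self.n_iterations_run,
            "seed": self.seed,
            "config": {
                "n_hawks": self.config.n_hawks,
                "n_iterations": self.config.n_iterations,
                "levy_beta": self.config.levy_beta,
                "schedule": self.config.schedule,
                "rol": self.config.rol,
            },
        })


# --- escape-energy machinery --------------------------------------------

def linear_energy_factor(t: float, T: int) -> float:
    """Baseline envelope E1(t) = 2 (1 - t/T): linear decay from 2 to 0."""
    return 2.0 * (1.0 - t / T)


def energy_factor(t: float, T: int, schedule: str = "linear") -> float:
    """Dispatch the E1 envelope by schedule kind."""
    if schedule == "linear":
        return linear_energy_factor(t, T)
    from .nol import nonlinear_energy_factor
    return nonlinear_energy_factor(t, T)


def escape_energy(t: float, T: int, rng: np.random.Generator,
                  schedule: str = "linear") -> float:
    """Draw one escape energy E = (2 r - 1) E1(t), r ~ U(0,1).

    Redrawn per hawk per iteration; |E| <= E1(t) <= 2.
    """
    if not 0 <= t <= T:
        raise ValueError("iteration index outside [0, T]")
    return (2.0 * rng.random() - 1.0) * energy_factor(t, T, schedule)


# --- move operators -----------------------------------------------------

def exploration_move(hawk: np.ndarray, population: HawkPopulation,
                     domain: SearchDomain, rng: np.random.Generator) -> np.ndarray:
    """One of two equal-probability global moves (used when |E| >= 1).

    Either perch relative to a random flock member, or relative to the
    rabbit and the flock mean with a random offset inside the box.
    """
    if rng.random() >= 0.5:
        x_rand = population.positions[rng.integers(population.n_hawks)]
        r1, r2 = rng.random(), rng.random()
        new = x_rand - r1 * np.abs(x_rand - 2.0 * r2 * hawk)
    else:
        r3, r4 = rng.random(), rng.random()
        new = ((population.rabbit_position - population.mean_position())
               - r3 * (domain.lower + r4 * (domain.upper - domain.lower)))
    return domain.clamp(new)


def levy_step(dim: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Mantegna Levy flight step, scaled by the conventional 0.01 factor."""
    if not 1.0 < beta <= 2.0:
        raise ValueError("levy beta must lie in (1, 2]")
    sigma = mantegna_sigma(beta)
    u = rng.standard_normal(dim) * sigma
    v = rng.standard_normal(dim)
    return 0.01 * u / np.abs(v) ** (1.0 / beta)


def mantegna_sigma(beta: float) -> float:
    """Closed-form Mantegna scale for the numerator normal draw."""
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def exploitation_move(hawk: np.ndarray, hawk_fitness: float,
                      population: HawkPopulation, E: float,
                      domain: SearchDomain,
                      objective: Callable[[np.ndarray], float],
                      rng: np.random.Generator,
                      levy_beta: float = 1.5) -> np.ndarray:
    """One of four equal-probability besiege strategies (used when |E| < 1).

    The escape chance r and |E| cross at 0.5 to select soft besiege, hard
    besiege, or their rapid-dive versions.  Dive branches are greedy: the
    hawk only moves to Y or the Levy dive Z when that improves on its own
    current objective value.
    """
    rabbit = population.rabbit_position
    r = rng.random()
    if r >= 0.5 and abs(E) < 0.5:
        # hard besiege
        new = rabbit - E * np.abs(rabbit - hawk)
    elif r >= 0.5:
        # soft besiege
        J = 2.0 * (1.0 - rng.random())
        new = (rabbit - hawk) - E * np.abs(J * rabbit - hawk)
    else:
        base = hawk if abs(E) >= 0.5 else population.mean_position()
        J = 2.0 * (1.0 - rng.random())
        Y = domain.clamp(rabbit - E * np.abs(J * rabbit - base))
        if objective(Y) < hawk_fitness:
            return Y
        Z = domain.clamp(
            Y + rng.random(domain.dim) * levy_step(domain.dim, levy_beta, rng))
        if objective(Z) < hawk_fitness:
            return Z
        return hawk.copy()
    return domain.clamp(new)


# --- run loop -----------------------------------------------------------

def initialize_population(domain: SearchDomain, config: HHOConfig,
                          rng: np.random.Generator,
                          objective: Callable[[np.ndarray], np.ndarray],
                          x0: Optional[np.ndarray] = None) -> HawkPopulation:
    """Uniform initialization in the box with fitnesses and rabbit set.

    ``x0`` optionally supplies informed starting positions (clamped to
    the box); rows beyond ``x0`` are drawn uniformly.
    """
    pos = rng.uniform(domain.lower, domain.upper,
                      size=(config.n_hawks, domain.dim))
    if x0 is not None:
        x0 = np.atleast_2d(np.asarray(x0, dtype=float))
        k = min(len(x0), config.n_hawks)
        pos[:k] = domain.clamp(x0[:k])
    fit = np.atleast_1d(np.asarray(objective(pos), dtype=float))
    i = int(np.argmin(fit))
    return HawkPopulation(pos, fit, pos[i].copy(), float(fit[i]))


def _resolve_objective(objective, domain):
    if isinstance(objective, ObjectiveSpec):
        if domain is None:
            domain = SearchDomain.from_spec(objective)
        return objective.evaluator, objective.stochastic, domain
    if domain is None:
        raise ValueError("a SearchDomain is required for a bare callable")
    return objective, False, domain


def run(objective: Union[ObjectiveSpec, Callable], config: HHOConfig,
        domain: Optional[SearchDomain] = None,
        rng: Optional[np.random.Generator] = None,
        f_target: Optional[float] = None,
        x0: Optional[np.ndarray] = None) -> RunResult:
    """Execute one optimization run.

    Parameters
    ----------
    objective
        An :class:`~nolhho.benchmarks.ObjectiveSpec`, or a batch-capable
        callable ``f(x) -> value(s)`` together with an explicit ``domain``.
    config
        Optimizer settings, including schedule kind and the ROL switch.
    rng
        Optional generator; by default one is seeded from ``config.seed``.
    f_target
        Early-stop threshold: the run ends as soon as the rabbit fitness
        reaches this value or below (used by the code-set builder, whose
        admissibility condition is exactly fitness zero).
    x0
        Optional informed initial positions (see
        :func:`initialize_population`).
    """
    evaluator, stochastic, domain = _resolve_objective(objective, domain)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    if stochastic:
        def batch_obj(x):
            return evaluator(x, rng)
    else:
        def batch_obj(x):
            return evaluator(x)

    T = config.n_iterations
    pop = initialize_population(domain, config, rng, batch_obj, x0=x0)
    trace = np.empty(T)
    n_run = 0
    if f_target is not None and pop.rabbit_fitness <= f_target:
        return RunResult(pop.rabbit_fitness, pop.rabbit_position.copy(),
                         trace[:0].copy(), 0, config, config.seed)

    if config.rol:
        from .nol import rol_transform, select_survivors

    for t in range(T):
        e1 = energy_factor(t, T, config.schedule)
        for i in range(pop.n_hawks):
            E = (2.0 * rng.random() - 1.0) * e1
            if abs(E) >= 1.0:
                pop.positions[i] = exploration_move(
                    pop.positions[i], pop, domain, rng)
            else:
                pop.positions[i] = exploitation_move(
                    pop.positions[i], float(pop.fitnesses[i]), pop, E,
                    domain, batch_obj, rng, config.levy_beta)
        pop.positions = domain.clamp(pop.positions)
        pop.fitnesses = np.atleast_1d(
            np.asarray(batch_obj(pop.positions), dtype=float))
        pop.refresh_rabbit()
        if config.rol:
            mirrored = rol_transform(pop.positions, domain.lower,
                                     domain.upper, rng,
                                     scalar_rand=config.rol_scalar_rand)
            pop = select_survivors(pop, mirrored, batch_obj)
        trace[t] = pop.rabbit_fitness
        n_run = t + 1
        if f_target is not None and pop.rabbit_fitness <= f_target:
            break

    return RunResult(pop.rabbit_fitness, pop.rabbit_position.copy(),
                     trace[:n_run].copy(), n_run, config, config.seed)
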