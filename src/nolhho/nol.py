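"""Nonlinear energy scheduling and random opposition-based learning.

These are the two modifications that turn baseline HHO into NOL-HHO:

* a nonlinear envelope for the escape-energy factor E1 that decays
  slowly early (preserving global exploration deep into the run) and
  fast late (sharpening the final local search), replacing the linear
  ``2 (1 - t/T)``;
* a random opposition-based learning (ROL) step that mirrors every hawk
  through the box, ``x_j -> a_j + b_j - r_j x_j`` with fresh uniform
  ``r_j`` per dimension, then keeps the N best of the 2N original and
  mirrored individuals (elitist union selection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .hho import HawkPopulation

__all__ = [
    "RolParams", "nonlinear_energy_factor", "opposite_point",
    "rol_transform", "select_survivors",
]


@dataclass(frozen=True)
class RolParams:
    """ROL options: per-dimension random factors and clamp-to-bounds."""

    per_dimension_scaling: bool = True
    clamp_policy: str = "clamp"


def nonlinear_energy_factor(t: float, T: int, b_ini: float = 0.0,
                            b_fin: float = 2.0) -> float:
    """Slow-early/fast-late envelope for the escape-energy factor.

    E1(t) = b_fin - (b_fin - b_ini) * (1 - exp((t/T)^5)) / (1 - e)

    with endpoints E1(0) = b_fin = 2 and E1(T) = b_ini = 0, strictly
    decreasing in between, and dominating the linear envelope pointwise:
    exploration (|E| >= 1) remains possible well past the halfway point,
    where the linear schedule has already shut it off.
    """
    if not 0 <= t <= T:
        raise ValueError("iteration index outside [0, T]")
    s = (t / T) ** 5
    return b_fin - (b_fin - b_ini) * (1.0 - np.exp(s)) / (1.0 - np.e)


def opposite_point(x: np.ndarray, lower: np.ndarray,
                   upper: np.ndarray) -> np.ndarray:
    """Classical opposition: a + b - x elementwise (an involution)."""
    return np.asarray(lower) + np.asarray(upper) - np.asarray(x, dtype=float)


def rol_transform(x: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                  rng: np.random.Generator,
                  scalar_rand: bool = False) -> np.ndarray:
    """Random opposition: a_j + b_j - r_j x_j, clamped into the box.

    ``r_j ~ U(0,1)`` is drawn independently per dimension (and per row
    for a batch); with ``scalar_rand=True`` a single factor per
    individual is used instead.  With all r = 1 this reduces to the
    classical opposite point.
    """
    x = np.asarray(x, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if scalar_rand:
        shape = x.shape[:-1] + (1,)
    else:
        shape = x.shape
    r = rng.random(shape)
    return np.clip(lower + upper - r * x, lower, upper)


def select_survivors(current: HawkPopulation, mirrored_positions: np.ndarray,
                     objective: Callable[[np.ndarray], np.ndarray]) -> HawkPopulation:
    """Keep the N best of the union of current and mirrored individuals.

    Evaluates the mirrored positions, merges them with the current flock,
    and retains the N fittest.  The rabbit is refreshed afterwards, so
    both the best-so-far and the population mean fitness can only improve
    or stay put across this step.
    """
    mirrored_positions = np.atleast_2d(np.asarray(mirrored_positions, dtype=float))
    if mirrored_positions.shape != current.positions.shape:
        raise ValueError("mirrored population must match the flock shape")
    mfit = np.atleast_1d(np.asarray(objective(mirrored_positions), dtype=float))
    all_pos = np.vstack([current.positions, mirrored_positions])
    all_fit = np.concatenate([current.fitnesses, mfit])
    n = current.n_hawks
    keep = np.argpartition(all_fit, n - 1)[:n]
    pop = HawkPopulation(all_pos[keep], all_fit[keep],
                         current.rabbit_position, current.rabbit_fitness)
    pop.refresh_rabbit()
    return pop
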