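"""Classical benchmark objectives F1-F23 for swarm-optimizer testing.

The suite is the standard collection used throughout the metaheuristics
literature: seven unimodal functions (F1-F7), six scalable multimodal
functions (F8-F13), and ten fixed-dimension multimodal functions
(F14-F23).  All functions are minimized; every evaluator accepts either a
single point of shape ``(dim,)`` or a batch of shape ``(m, dim)`` and
reduces over the last axis.

F7 (the quartic function) carries additive uniform noise and therefore
takes an explicit ``rng``; all other evaluators ignore it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ObjectiveSpec", "make_suite", "evaluate", "suite_manifest"]

SCALABLE_IDS = tuple(f"F{i}" for i in range(1, 14))


@dataclass(frozen=True)
class ObjectiveSpec:
    """One benchmark objective with its domain and known optimum.

    Attributes
    ----------
    id : str
        Conventional identifier, ``"F1"`` .. ``"F23"``.
    name : str
        Human-readable function name.
    dim : int
        Dimensionality (30 by default for F1-F13, fixed for F14-F23).
    lower, upper : ndarray
        Per-dimension box bounds.
    f_min : float
        Global optimum value (double-precision value at the optimizer,
        e.g. ~8.88e-16 for Ackley at the origin).
    evaluator : callable
        ``evaluator(x, rng=None) -> float | ndarray``; pure except F7.
    minimizer : ndarray or None
        A known global minimizer, when one has a closed form.
    scalable : bool
        Whether ``dim`` may be overridden.
    """

    id: str
    name: str
    dim: int
    lower: np.ndarray
    upper: np.ndarray
    f_min: float
    evaluator: Callable[..., np.ndarray]
    minimizer: Optional[np.ndarray] = None
    scalable: bool = False
    stochastic: bool = False

    def __post_init__(self) -> None:
        if not np.all(self.lower < self.upper):
            raise ValueError(f"{self.id}: lower bound must be < upper bound")


def _as2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def _ret(v: np.ndarray, squeeze: bool):
    return float(v[0]) if squeeze else v


# --- scalable functions -------------------------------------------------

def _sphere(x, rng=None):
    x, s = _as2d(x)
    return _ret(np.sum(x * x, axis=1), s)


def _schwefel_2_22(x, rng=None):
    x, s = _as2d(x)
    a = np.abs(x)
    return _ret(a.sum(axis=1) + a.prod(axis=1), s)


def _schwefel_1_2(x, rng=None):
    x, s = _as2d(x)
    c = np.cumsum(x, axis=1)
    return _ret(np.sum(c * c, axis=1), s)


def _schwefel_2_21(x, rng=None):
    x, s = _as2d(x)
    return _ret(np.max(np.abs(x), axis=1), s)


def _rosenbrock(x, rng=None):
    x, s = _as2d(x)
    v = np.sum(100.0 * (x[:, 1:] - x[:, :-1] ** 2) ** 2 + (x[:, :-1] - 1.0) ** 2, axis=1)
    return _ret(v, s)


def _step(x, rng=None):
    x, s = _as2d(x)
    return _ret(np.sum(np.floor(x + 0.5) ** 2, axis=1), s)


def _quartic_noise(x, rng=None):
    x, s = _as2d(x)
    i = np.arange(1, x.shape[1] + 1)
    base = np.sum(i * x ** 4, axis=1)
    if rng is not None:
        base = base + rng.random(x.shape[0])
    return _ret(base, s)


def _schwefel_sine(x, rng=None):
    x, s = _as2d(x)
    return _ret(np.sum(-x * np.sin(np.sqrt(np.abs(x))), axis=1), s)


def _rastrigin(x, rng=None):
    x, s = _as2d(x)
    return _ret(np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0, axis=1), s)


def _ackley(x, rng=None):
    x, s = _as2d(x)
    n = x.shape[1]
    v = (-20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x, axis=1) / n))
         - np.exp(np.sum(np.cos(2.0 * np.pi * x), axis=1) / n) + 20.0 + np.e)
    return _ret(v, s)


def _griewank(x, rng=None):
    x, s = _as2d(x)
    i = np.sqrt(np.arange(1, x.shape[1] + 1))
    v = np.sum(x * x, axis=1) / 4000.0 - np.prod(np.cos(x / i), axis=1) + 1.0
    return _ret(v, s)


def _u_penalty(x, a, k, m):
    return np.where(x > a, k * (x - a) ** m,
                    np.where(x < -a, k * (-x - a) ** m, 0.0))


def _penalized_1(x, rng=None):
    x, s = _as2d(x)
    n = x.shape[1]
    y = 1.0 + (x + 1.0) / 4.0
    v = (np.pi / n) * (10.0 * np.sin(np.pi * y[:, 0]) ** 2
                       + np.sum((y[:, :-1] - 1.0) ** 2
                                * (1.0 + 10.0 * np.sin(np.pi * y[:, 1:]) ** 2), axis=1)
                       + (y[:, -1] - 1.0) ** 2)
    v = v + np.sum(_u_penalty(x, 10.0, 100.0, 4), axis=1)
    return _ret(v, s)


def _penalized_2(x, rng=None):
    x, s = _as2d(x)
    v = 0.1 * (np.sin(3.0 * np.pi * x[:, 0]) ** 2
               + np.sum((x[:, :-1] - 1.0) ** 2
                        * (1.0 + np.sin(3.0 * np.pi * x[:, 1:]) ** 2), axis=1)
               + (x[:, -1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[:, -1]) ** 2))
    v = v + np.sum(_u_penalty(x, 5.0, 100.0, 4), axis=1)
    return _ret(v, s)


# --- fixed-dimension functions ------------------------------------------

_FOX_A = np.array([
    [-32, -16, 0, 16, 32] * 5,
    [-32] * 5 + [-16] * 5 + [0] * 5 + [16] * 5 + [32] * 5,
], dtype=float)


def _foxholes(x, rng=None):
    x, s = _as2d(x)
    j = np.arange(1, 26)
    d = np.sum((x[:, :, None] - _FOX_A[None, :, :]) ** 6, axis=1)
    v = 1.0 / (1.0 / 500.0 + np.sum(1.0 / (j + d), axis=1))
    return _ret(v, s)


_KOW_A = np.array([0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627,
                   0.0456, 0.0342, 0.0323, 0.0235, 0.0246])
_KOW_B = 1.0 / np.array([0.25, 0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16])


def _kowalik(x, rng=None):
    x, s = _as2d(x)
    b = _KOW_B[None, :]
    num = x[:, 0:1] * (b ** 2 + b * x[:, 1:2])
    den = b ** 2 + b * x[:, 2:3] + x[:, 3:4]
    return _ret(np.sum((_KOW_A[None, :] - num / den) ** 2, axis=1), s)


def _camel6(x, rng=None):
    x, s = _as2d(x)
    x1, x2 = x[:, 0], x[:, 1]
    v = (4.0 * x1 ** 2 - 2.1 * x1 ** 4 + x1 ** 6 / 3.0
         + x1 * x2 - 4.0 * x2 ** 2 + 4.0 * x2 ** 4)
    return _ret(v, s)


def _branin(x, rng=None):
    x, s = _as2d(x)
    x1, x2 = x[:, 0], x[:, 1]
    v = ((x2 - 5.1 / (4 * np.pi ** 2) * x1 ** 2 + 5.0 / np.pi * x1 - 6.0) ** 2
         + 10.0 * (1.0 - 1.0 / (8.0 * np.pi)) * np.cos(x1) + 10.0)
    return _ret(v, s)


def _goldstein_price(x, rng=None):
    x, s = _as2d(x)
    x1, x2 = x[:, 0], x[:, 1]
    a = 1 + (x1 + x2 + 1) ** 2 * (19 - 14 * x1 + 3 * x1 ** 2
                                  - 14 * x2 + 6 * x1 * x2 + 3 * x2 ** 2)
    b = 30 + (2 * x1 - 3 * x2) ** 2 * (18 - 32 * x1 + 12 * x1 ** 2
                                       + 48 * x2 - 36 * x1 * x2 + 27 * x2 ** 2)
    return _ret(a * b, s)


_H3_ALPHA = np.array([1.0, 1.2, 3.0, 3.2])
_H3_A = np.array([[3, 10, 30], [0.1, 10, 35], [3, 10, 30], [0.1, 10, 35]], dtype=float)
_H3_P = 1e-4 * np.array([[3689, 1170, 2673], [4699, 4387, 7470],
                         [1091, 8732, 5547], [381, 5743, 8828]])
_H6_A = np.array([[10, 3, 17, 3.5, 1.7, 8],
                  [0.05, 10, 17, 0.1, 8, 14],
                  [3, 3.5, 1.7, 10, 17, 8],
                  [17, 8, 0.05, 10, 0.1, 14]], dtype=float)
_H6_P = 1e-4 * np.array([[1312, 1696, 5569, 124, 8283, 5886],
                         [2329, 4135, 8307, 3736, 1004, 9991],
                         [2348, 1451, 3522, 2883, 3047, 6650],
                         [4047, 8828, 8732, 5743, 1091, 381]])


def _hartman(x, A, P, rng=None):
    x, s = _as2d(x)
    e = np.sum(A[None, :, :] * (x[:, None, :] - P[None, :, :]) ** 2, axis=2)
    return _ret(-np.sum(_H3_ALPHA[None, :] * np.exp(-e), axis=1), s)


_SHEKEL_A = np.array([[4, 4, 4, 4], [1, 1, 1, 1], [8, 8, 8, 8], [6, 6, 6, 6],
                      [3, 7, 3, 7], [2, 9, 2, 9], [5, 5, 3, 3], [8, 1, 8, 1],
                      [6, 2, 6, 2], [7, 3.6, 7, 3.6]], dtype=float)
_SHEKEL_C = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])


def _shekel(x, m, rng=None):
    x, s = _as2d(x)
    d = np.sum((x[:, None, :] - _SHEKEL_A[None, :m, :]) ** 2, axis=2)
    return _ret(-np.sum(1.0 / (d + _SHEKEL_C[None, :m]), axis=1), s)


def _box(dim: int, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    return np.full(dim, lo, dtype=float), np.full(dim, hi, dtype=float)


# Ackley's double-precision value at the origin is not exactly zero.
_ACKLEY_FLOOR = float(_ackley(np.zeros(2)))


def _schwefel_sine_min(dim: int) -> float:
    # -418.9829 per dimension at x_i = 420.9687, reported to 4 decimals
    return round(-418.9829 * dim, 4)


def make_suite(dim_override: Optional[int] = None) -> list[ObjectiveSpec]:
    """Build the 23-function suite in the conventional F1..F23 order.

    Parameters
    ----------
    dim_override : int, optional
        Replacement dimension for the scalable functions F1-F13 (used for
        high-dimensional sweeps).  The fixed-dimension functions F14-F23
        are unaffected.
    """
    if dim_override is not None and dim_override < 1:
        raise ValueError("dim_override must be a positive integer")
    d = 30 if dim_override is None else int(dim_override)

    specs = [
        ObjectiveSpec("F1", "Sphere", d, *_box(d, -100, 100), 0.0, _sphere,
                      np.zeros(d), scalable=True),
        ObjectiveSpec("F2", "Schwefel 2.22", d, *_box(d, -10, 10), 0.0,
                      _schwefel_2_22, np.zeros(d), scalable=True),
        ObjectiveSpec("F3", "Schwefel 1.2", d, *_box(d, -100, 100), 0.0,
                      _schwefel_1_2, np.zeros(d), scalable=True),
        ObjectiveSpec("F4", "Schwefel 2.21", d, *_box(d, -100, 100), 0.0,
                      _schwefel_2_21, np.zeros(d), scalable=True),
        ObjectiveSpec("F5", "Rosenbrock", d, *_box(d, -30, 30), 0.0,
                      _rosenbrock, np.ones(d), scalable=True),
        ObjectiveSpec("F6", "Step", d, *_box(d, -100, 100), 0.0, _step,
                      np.zeros(d), scalable=True),
        ObjectiveSpec("F7", "Quartic with noise", d, *_box(d, -1.28, 1.28),
                      0.0, _quartic_noise, np.zeros(d), scalable=True,
                      stochastic=True),
        ObjectiveSpec("F8", "Schwefel sine", d, *_box(d, -500, 500),
                      _schwefel_sine_min(d), _schwefel_sine,
                      np.full(d, 420.9687448209954), scalable=True),
        ObjectiveSpec("F9", "Rastrigin", d, *_box(d, -5.12, 5.12), 0.0,
                      _rastrigin, np.zeros(d), scalable=True),
        ObjectiveSpec("F10", "Ackley", d, *_box(d, -32, 32), _ACKLEY_FLOOR,
                      _ackley, np.zeros(d), scalable=True),
        ObjectiveSpec("F11", "Griewank", d, *_box(d, -600, 600), 0.0,
                      _griewank, np.zeros(d), scalable=True),
        ObjectiveSpec("F12", "Penalized 1", d, *_box(d, -50, 50), 0.0,
                      _penalized_1, -np.ones(d), scalable=True),
        ObjectiveSpec("F13", "Penalized 2", d, *_box(d, -50, 50), 0.0,
                      _penalized_2, np.ones(d), scalable=True),
        ObjectiveSpec("F14", "Shekel's Foxholes", 2,
                      *_box(2, -65.536, 65.536), 0.998003837794449,
                      _foxholes, np.array([-32.0, -32.0])),
        ObjectiveSpec("F15", "Kowalik", 4, *_box(4, -5, 5),
                      3.0748610201359075e-4, _kowalik,
                      np.array([0.192833, 0.190836, 0.123117, 0.135766])),
        ObjectiveSpec("F16", "Six-hump Camel", 2, *_box(2, -5, 5),
                      -1.0316284534898774, _camel6,
                      np.array([0.08984201368301331, -0.7126564032704135])),
        ObjectiveSpec("F17", "Branin", 2, np.array([-5.0, 0.0]),
                      np.array([10.0, 15.0]), 0.39788735772973816, _branin,
                      np.array([np.pi, 2.275])),
        ObjectiveSpec("F18", "Goldstein-Price", 2, *_box(2, -2, 2), 3.0,
                      _goldstein_price, np.array([0.0, -1.0])),
        ObjectiveSpec("F19", "Hartman 3", 3, *_box(3, 0, 1),
                      -3.8627797869493365,
                      lambda x, rng=None: _hartman(x, _H3_A, _H3_P),
                      np.array([0.11458923, 0.55564889, 0.85254695])),
        ObjectiveSpec("F20", "Hartman 6", 6, *_box(6, 0, 1),
                      -3.3223680114155156,
                      lambda x, rng=None: _hartman(x, _H6_A, _H6_P),
                      np.array([0.20168952, 0.15001069, 0.47687398,
                                0.27533243, 0.31165162, 0.65730054])),
        ObjectiveSpec("F21", "Shekel 5", 4, *_box(4, 0, 10),
                      -10.153199679058231,
                      lambda x, rng=None: _shekel(x, 5),
                      np.array([4.00003715, 4.00013327, 4.00003714, 4.0001333])),
        ObjectiveSpec("F22", "Shekel 7", 4, *_box(4, 0, 10),
                      -10.402940566818663,
                      lambda x, rng=None: _shekel(x, 7),
                      np.array([4.00057291, 4.00069020, 3.99948971, 3.99960615])),
        ObjectiveSpec("F23", "Shekel 10", 4, *_box(4, 0, 10),
                      -10.536409816692023,
                      lambda x, rng=None: _shekel(x, 10),
                      np.array([4.00074671, 4.00059326, 3.99966290, 3.99950981])),
    ]
    return specs


def get_spec(fid: str, dim_override: Optional[int] = None) -> ObjectiveSpec:
    """Return a single objective by id; dim_override only for F1-F13."""
    if dim_override is not None and fid not in SCALABLE_IDS:
        raise ValueError(f"{fid} has a fixed dimension")
    for spec in make_suite(dim_override):
        if spec.id == fid:
            return spec
    raise KeyError(f"unknown benchmark id: {fid}")


def evaluate(spec: ObjectiveSpec, point: Sequence[float],
             rng: Optional[np.random.Generator] = None) -> float:
    """Evaluate one objective at one point (no clamping is performed)."""
    point = np.asarray(point, dtype=float)
    if point.shape[-1] != spec.dim:
        raise ValueError(
            f"{spec.id} expects dimension {spec.dim}, got {point.shape[-1]}")
    return spec.evaluator(point, rng)


def suite_manifest(specs: Optional[list[ObjectiveSpec]] = None) -> pd.DataFrame:
    """Tabulate the suite (id, name, dim, bounds, f_min) for reports."""
    specs = make_suite() if specs is None else specs
    return pd.DataFrame({
        "id": [s.id for s in specs],
        "name": [s.name for s in specs],
        "dim": [s.dim for s in specs],
        "lower": [float(s.lower[0]) for s in specs],
        "upper": [float(s.upper[0]) for s in specs],
        "f_min": [s.f_min for s in specs],
    })


def manifest_json(path, specs=None) -> None:
    suite_manifest(specs).to_json(path, orient="records", indent=2)
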