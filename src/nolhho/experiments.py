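"""Benchmarking protocol: repeated runs, statistics and the bound grid.

The standard protocol runs each optimizer with 30 search agents for 500
iterations, repeated over 30 independently seeded runs per objective,
and reports the mean (AVG) and standard deviation (STD) of the per-run
best objective values.  A Wilcoxon rank-sum test at the 5% level
compares paired algorithms.  The bound grid drives the code-set builder
over a range of (n, d) cells and tabulates achieved set sizes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import builder as builder_mod
from .benchmarks import ObjectiveSpec, get_spec, make_suite
from .builder import BuilderConfig
from .dna import default_gc_weight, write_fasta
from .hho import HHOConfig, run

__all__ = [
    "ALGORITHMS", "ExperimentReport", "run_repeats", "run_benchmark_table",
    "run_dimension_sweep", "wilcoxon_compare", "run_bound_grid",
    "reference_baselines",
]

ALGORITHMS = {
    "HHO": dict(schedule="linear", rol=False),
    "NOL-HHO": dict(schedule="nonlinear", rol=True),
}

# Counter stride separating per-run seed streams; runs are seeded as
# master_seed * stride + counter so repeated protocols are bit-identical.
_SEED_STRIDE = 100_003


@dataclass
class ExperimentReport:
    """AVG/STD per (algorithm, function[, dim]) plus raw per-run values."""

    table: pd.DataFrame                 # columns: algorithm,id,dim,avg,std,runs
    raw: dict = field(default_factory=dict)   # (algorithm,id,dim) -> ndarray
    seeds: dict = field(default_factory=dict)

    def avg(self, algorithm: str, fid: str, dim: Optional[int] = None) -> float:
        t = self.table
        sel = (t.algorithm == algorithm) & (t.id == fid)
        if dim is not None:
            sel &= t.dim == dim
        return float(t.loc[sel, "avg"].iloc[0])

    def values(self, algorithm: str, fid: str,
               dim: Optional[int] = None) -> np.ndarray:
        if dim is None:
            keys = [k for k in self.raw if k[0] == algorithm and k[1] == fid]
            if len(keys) != 1:
                raise KeyError((algorithm, fid))
            return self.raw[keys[0]]
        return self.raw[(algorithm, fid, dim)]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _scientific(x: float) -> str:
    return f"{x:.2E}"


def run_repeats(spec: ObjectiveSpec, algorithm: str, runs: int = 30,
                agents: int = 30, iterations: int = 500,
                seed: int = 0) -> tuple[np.ndarray, list[int]]:
    """Independent seeded runs of one algorithm on one objective."""
    opts = ALGORITHMS[algorithm]
    best = np.empty(runs)
    seeds = []
    for k in range(runs):
        run_seed = (seed * _SEED_STRIDE + k) % (2 ** 31)
        cfg = HHOConfig(n_hawks=agents, n_iterations=iterations,
                        seed=run_seed, **opts)
        best[k] = run(spec, cfg).best_fitness
        seeds.append(run_seed)
    return best, seeds


def run_benchmark_table(algorithms: Sequence[str] = ("HHO", "NOL-HHO"),
                        suite: Optional[Iterable[ObjectiveSpec]] = None,
                        runs: int = 30, agents: int = 30,
                        iterations: int = 500, seed: int = 0) -> ExperimentReport:
    """AVG/STD of best fitness per (algorithm, function) over seeded runs."""
    suite = list(make_suite() if suite is None else suite)
    rows, raw, seeds = [], {}, {}
    for algorithm in algorithms:
        for spec in suite:
            vals, s = run_repeats(spec, algorithm, runs, agents, iterations,
                                  seed)
            key = (algorithm, spec.id, spec.dim)
            raw[key], seeds[key] = vals, s
            rows.append(dict(algorithm=algorithm, id=spec.id, dim=spec.dim,
                             avg=vals.mean(), std=vals.std(ddof=0),
                             avg_sci=_scientific(vals.mean()),
                             std_sci=_scientific(vals.std(ddof=0)),
                             runs=runs))
    return ExperimentReport(pd.DataFrame(rows), raw, seeds)


def run_dimension_sweep(algorithms: Sequence[str] = ("HHO", "NOL-HHO"),
                        function_ids: Sequence[str] = tuple(
                            f"F{i}" for i in range(1, 14)),
                        dims: Sequence[int] = (100, 500, 1000),
                        runs: int = 30, agents: int = 30,
                        iterations: int = 500, seed: int = 0) -> ExperimentReport:
    """The high-dimensional protocol for the scalable functions F1-F13."""
    reports = []
    raw, seeds = {}, {}
    for dim in dims:
        suite = [get_spec(fid, dim_override=dim) for fid in function_ids]
        rep = run_benchmark_table(algorithms, suite, runs, agents,
                                  iterations, seed)
        reports.append(rep.table)
        raw.update(rep.raw)
        seeds.update(rep.seeds)
    return ExperimentReport(pd.concat(reports, ignore_index=True), raw, seeds)


def wilcoxon_compare(results_a: np.ndarray,
                     results_b: np.ndarray) -> tuple[float, bool]:
    """Two-sided rank-sum p-value and a tie-degeneracy flag.

    Exact null distribution for small untied samples, normal
    approximation otherwise; two samples that are completely tied with
    each other carry no rank information and are reported as p = 1 with
    the tie flag set.
    """
    a = np.asarray(results_a, dtype=float)
    b = np.asarray(results_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must have equal run counts")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0, True
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue), False


def run_bound_grid(n_range: Sequence[int] = range(4, 11),
                   d_range: Optional[Sequence[int]] = None,
                   budget: Optional[dict] = None, seed: int = 0,
                   fasta_dir=None, exact_limit: int = 5) -> pd.DataFrame:
    """Build code sets over an (n, d) grid and tabulate their sizes.

    ``budget`` overrides :class:`BuilderConfig` fields per cell (keyed by
    (n, d)) or globally (key "all").  Cells with n <= exact_limit are
    additionally verified against the exact clique oracle.
    """
    budget = budget or {}
    rows = []
    for n in n_range:
        ds = d_range if d_range is not None else range(3, n + 1)
        for d in ds:
            if d > n:
                continue
            kw = dict(n=n, d=d, w=default_gc_weight(n), seed=seed)
            kw.update(budget.get("all", {}))
            kw.update(budget.get((n, d), {}))
            code = builder_mod.grow_code_set(BuilderConfig(**kw))
            exact_size = None
            if n <= exact_limit:
                exact_size = len(builder_mod.exhaustive_best(n, d, kw["w"]))
            if fasta_dir is not None and len(code):
                write_fasta(code.words, f"{fasta_dir}/code_n{n}_d{d}.fasta")
            rows.append(dict(n=n, d=d, w=kw["w"], size=len(code),
                             rate=code.rate if len(code) else 0.0,
                             exact=exact_size))
    return pd.DataFrame(rows)


def reference_baselines() -> pd.DataFrame:
    """Literature AVG/STD columns for other optimizers (display only).

    These published values for GA, PSO, BBO, FPA, GWO, BAT, FA, MFO and
    DE under the same 30-agent/500-iteration protocol are shipped frozen
    for side-by-side tables; they are never recomputed here.
    """
    ref = importlib.resources.files("nolhho.data") / "reference_baselines.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
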