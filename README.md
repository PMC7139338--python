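# nolhho

Harris hawks optimization with a **n**onlinear escape-energy schedule and
random **o**pposition-based **l**earning (NOL-HHO), applied to the design
of constrained DNA data-storage codes.

## What problem this solves

DNA data storage encodes digital information in synthetic
oligonucleotides.  Sequences used as codewords must avoid homopolymers
(no two adjacent bases equal — the *No-runlength* constraint), hold a
fixed GC content `w` (thermodynamic stability), and stay mutually
distinguishable (pairwise Hamming distance ≥ `d`, limiting nonspecific
hybridization and providing substitution-error resilience).  The central
combinatorial question is the maximum size `A^GC,NL(n, d, w)` of such a
code for word length `n`; every explicitly constructed set certifies a
lower bound, and larger bounds mean higher code rate
`R = log₄(M)/n` — more information per synthesized base.

This package implements, for practitioners of both swarm optimization
and DNA coding theory:

* the baseline HHO optimizer — escape energy `E = (2r−1)·E1(t)` routing
  each hawk between two exploration moves (`|E| ≥ 1`) and four besiege
  moves with greedy Levy-flight dives (`|E| < 1`);
* the two NOL improvements — the nonlinear envelope
  `E1(t) = 2 − 2(1 − e^{(t/T)^5})/(1 − e)` that keeps exploration alive
  past the halfway point where the linear `2(1 − t/T)` has already shut
  it off, and per-iteration random opposition
  `x̂_j = a_j + b_j − r_j x_j` with elitist union selection;
* the classical 23-function benchmark suite (sphere … Shekel-10) and the
  30-agents × 500-iterations × 30-runs evaluation protocol with rank-sum
  comparison;
* a code-set builder that grows `A^GC,NL(n, d, w)` sets word by word,
  each word found by a NOL-HHO search over `[0, 4]^n` with floor
  decoding and a penalty fitness whose zero level is exactly
  admissibility, wrapped in a perturbation ("ruin-and-recreate") outer
  loop; plus two independent oracles — an exact branch-and-bound
  maximum-clique search for small `n` and a randomized greedy baseline.

See `docs/methods.md` for the full model description and design
rationale.

## Worked example

Certify the exact maximum for length-4 codes at distance 3 and rebuild
it with the optimizer:

```python
>>> from nolhho import exhaustive_best, grow_code_set, BuilderConfig, code_rate
>>> exact = exhaustive_best(4, 3, 2)          # branch-and-bound oracle
>>> len(exact)
12
>>> code = grow_code_set(BuilderConfig(n=4, d=3, seed=7, target_size=12))
>>> len(code), sorted(code.words)[:3]
(12, ['ACTG', 'AGCT', 'ATGC'])
>>> round(code_rate(len(code), 4), 3)
0.448
```

Twelve words is the true maximum of `A^GC,NL(4, 3, 2)`: the oracle
proves no thirteenth word fits, and the builder reaches the same size
from scratch.  The rate says each of the four bases carries 0.448
quaternary symbols of payload after the constraints take their share.

Benchmark the two optimizer variants on 30-dimensional Rastrigin:

```python
>>> from nolhho.benchmarks import get_spec
>>> from nolhho.experiments import run_benchmark_table
>>> rep = run_benchmark_table(["HHO", "NOL-HHO"], [get_spec("F9")],
...                           runs=5, seed=1)
>>> rep.table[["algorithm", "id", "avg_sci", "std_sci"]]
  algorithm  id   avg_sci   std_sci
0       HHO  F9  0.00E+00  0.00E+00
1   NOL-HHO  F9  0.00E+00  0.00E+00
```

Both reach the exact global optimum 0 in every run here; the penalized
functions F12/F13 and the code-set sizes are where the NOL variant
separates from the baseline.

A CLI wraps the same operations:

```sh
nolhho build --n 5 --d 3 --seed 1 --out code.fasta
nolhho verify --in code.fasta --d 3
nolhho exact --n 4 --d 3
nolhho bench --algo nolhho --functions F9,F10,F11 --runs 5
```

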