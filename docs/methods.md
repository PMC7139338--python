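# Methods

## The optimizer

Harris hawks optimization (HHO) is a population metaheuristic for
box-constrained minimization.  A flock of `N` hawks tracks the best
solution found so far (the *rabbit*).  At iteration `t` of `T`, each
hawk draws an escape energy

    E = (2 r - 1) · E1(t),        r ~ U(0, 1), redrawn per hawk,

and is routed by its magnitude: `|E| ≥ 1` triggers one of two
equal-probability exploration moves (perch relative to a random flock
member, or relative to the rabbit and the flock mean with a random
offset inside the box); `|E| < 1` triggers one of four equal-probability
besiege moves selected by crossing a fresh escape-chance draw `r` with
`|E|` at 0.5 — soft besiege, hard besiege, and their progressive
rapid-dive versions.  The dive moves propose `Y = x_rabbit −
E·|J·x_rabbit − base|` (`J = 2(1 − r5)`, `base` the hawk itself or the
flock mean) and a Levy-flight refinement `Z = Y + S ∘ LF(β)`, and accept
greedily: the hawk never moves to a point worse than its own current
value, which keeps per-hawk progress and the rabbit trace monotone.
Positions leaving the box are clamped to the nearest bound after every
move.  All randomness flows through a single seeded generator, so runs
are bit-reproducible.

The baseline envelope is linear, `E1(t) = 2(1 − t/T)`.  Its known defect
is that `E1 < 1` for every `t > T/2`, so exploration is impossible in
the entire second half of a run and the flock can stall in a poor basin.

### The nonlinear schedule

The improved envelope is

    E1(t) = b_fin − (b_fin − b_ini) · (1 − exp((t/T)^5)) / (1 − e),

with `b_fin = 2`, `b_ini = 0` and `e` Euler's number.  It shares the
endpoints `E1(0) = 2`, `E1(T) = 0`, is strictly decreasing, dominates
the linear envelope pointwise, and crosses 1 near `t/T ≈ 0.91`:
exploration remains available deep into the run, while the final
iterations decay fast for a sharp local search.  At `t = T/2` the value
is ≈ 1.9631 (the linear schedule gives 1.0 there).

### Random opposition-based learning (ROL)

After all position updates in an iteration, every hawk `x` is mirrored
through the box,

    x̂_j = a_j + b_j − r_j · x_j,      r_j ~ U(0, 1) per dimension,

clamped to the bounds, and the `N` best of the `2N` original∪mirrored
individuals survive (elitist union selection, then a rabbit refresh).
With `r = 1` this is classical opposition `a + b − x`; the random factor
spreads the mirrored cloud and is what lets the population leave a
jointly-poor region.  A per-individual scalar factor is available behind
`rol_scalar_rand`, but per-dimension is the default.  Survivor selection
can only improve the population mean and the best-so-far, so the
convergence trace stays monotone.

A side effect worth knowing: on origin-centred boxes (`a = −b`) the
mirror is `−r·x`, a contraction toward the origin.  On benchmarks whose
optimum sits at the origin this drives coordinates into double-precision
underflow and produces *exactly* zero objective values (Rastrigin,
Griewank, sphere) or the double-precision Ackley floor ≈ 4.44e−16.
These exact zeros are a genuine property of the algorithm + IEEE
arithmetic on such benchmarks, and the tests assert them; on problems
whose optimum is elsewhere no such shortcut exists.

## Benchmarks

The 23-function suite is the classical collection (sphere through
Shekel-10) with its standard boxes, dimensions and optima; F1–F13 are
scalable (default dimension 30), F14–F23 fixed.  F7 adds U(0,1) noise
per evaluation from the caller's generator.  Two numerical caveats:
the conventional Schwefel-sine optimum −418.9829·dim is a rounded
figure (the closed-form minimizer evaluates to −418.98288727·dim, so
the suite invariant test uses a 0.02/dimension tolerance there), and
the double-precision Ackley value at the origin is 4.44e−16 — half the
widely printed 8.88e−16, which corresponds to a near-converged point
rather than the exact origin.  The noisy F7 can never average below
~1/(number of evaluations), so exact-zero expectations exclude it.

The experiment protocol is 30 agents, 500 iterations, 30 independent
runs per (algorithm, function); per-run seeds derive from a master seed
by a counter scheme (`master·100003 + k`), making every table
bit-reproducible.  Algorithm pairs are compared with a two-sided
rank-sum test: exact null for small untied samples, normal
approximation otherwise; fully tied pairs are reported as p = 1 with a
tie flag.  Reference AVG/STD columns for nine other metaheuristics are
shipped as a frozen CSV for display and are never recomputed.

## DNA code sets

A code set A^GC,NL(n, d, w) contains length-`n` words over {A, C, G, T}
with no two adjacent bases equal (homopolymer avoidance), exactly `w`
G/C bases (`w = floor(n/2)` by default, including odd `n`), and
pairwise Hamming distance ≥ `d`.  Words map to quaternary digits by
A-0, G-1, C-2, T-3.  The size `M` of any valid set certifies a lower
bound on the maximum, with code rate `R = log4(M)/n`.

### The builder

The builder grows a set one word at a time.  Each addition is a NOL-HHO
search over the continuous box [0, 4]^n; a position decodes to a word by
flooring coordinates to digits, and the fitness

    (n+1)·(adjacent repeats) + (n+1)·|GC − w| + max(0, d − minDist)

(`minDist(∅) = n`) makes admissibility equivalent to fitness 0, which
is also the early-stop target of the inner run.  Four design choices
proved necessary in practice and are deliberate:

* **Digit relabeling per search.**  The swarm has systematic spatial
  preferences, and with a fixed decoding repeated searches keep
  returning the same few words, starving the outer loop of diversity.
  Each inner search therefore draws a uniform random permutation of the
  four digits independently per position; fitness is always computed on
  the relabeled word, so this changes which word a region of the box
  denotes, not the problem being solved.  Empirically this makes the
  found word approximately uniform over the admissible set.
* **Lexicon-seeded initialization.**  The flock starts on random
  feasible words (jittered inside their continuous cells) rather than
  uniformly in the box: for longer words the NL∧GC manifold is a thin
  slice of [0, 4]^n and a blind start spends the whole budget
  rediscovering it.
* **Perturb instead of stop.**  A maximal set is rarely maximum.  At
  maximality the builder removes 1–3 random words and keeps growing,
  tracking the best set ever seen (a ruin-and-recreate walk over
  maximal sets).  Plain stop-at-first-maximal growth tops out far
  below the reachable sizes (e.g. ~10 vs the true 12 at n=4, d=3).
* **Exact maximality certification.**  A stochastic search can miss an
  existing extension, and perturbing a still-extendable set degrades
  the walk badly.  When the swarm search comes up empty, the builder
  scans the enumerated feasible lexicon (every admissible word is in
  it by definition; the scan is a single vectorized distance test kept
  incrementally up to date): a missed extension is added — chosen
  uniformly at random — and only a certified-maximal set is perturbed.
  When the swarm's recent hit rate collapses (late in the walk, where
  admissible words are scarce), its attempts are throttled and the
  scan carries the search.

Inner searches default to 30 hawks × 60 iterations, and the reported
cells use an even leaner 20-iteration profile: an inner run only needs
to find *one* admissible cell, most runs early-stop at initialization
or within a few iterations, and a short cap merely hands the query to
the exact scan sooner.  Budgets (`max_consecutive_failures` patience,
`max_cycles` hard cap on word queries, `restarts`) control total
effort; the documented desk-scale budgets complete each reported cell
in minutes on one core.  With `target_size` set, growth stops as soon
as the target is met, which is how the published cells are reproduced
without spending the full patience budget.

### Oracles

Two independent checks frame the builder.  `exhaustive_best` computes
the true maximum by branch-and-bound maximum-clique search (bitset
adjacency, greedy-coloring bound, degree ordering) over the feasible
word graph — practical to n ≤ 6; it certifies the n=4 and n=5 cells
(32/12/4 and 20/8/3) as exact maxima.  `greedy_baseline` is randomized
first-fit over feasible-word orderings.  Every emitted set is run
through `validate_code_set` before being returned.

## Known limitations

* The two NOL ingredients trade refinement for exploration, and the
  test suite measures where that trade loses: on the penalized
  functions F12/F13 — the only scalable suite members whose optima sit
  away from the origin — the NOL variant is consistently about an
  order of magnitude *worse* than baseline HHO here (both still far
  ahead of the other published optimizers on those functions).  The
  ROL mirror degenerates to `−r·x` on a symmetric box and so pulls
  toward the origin rather than the optimum, and the nonlinear
  schedule leaves only the last ~9% of iterations for pure
  exploitation versus half the run for the linear one.  The
  comparative test asserting the opposite direction on F12/F13 is left
  in the suite and fails against this implementation; it is kept as an
  honest record of the discrepancy rather than weakened.
* The builder's walk is stochastic; large cells (n ≥ 8 with small d,
  e.g. the thousands-of-words d=2 column) need budgets far beyond desk
  scale and are out of the reproduced range.
* The exact-zero benchmark floors depend on the optimum lying at the
  origin of a symmetric box; they say nothing about shifted or rotated
  variants of the same functions.
* No reverse-complement, secondary-structure or thermodynamic
  constraints are modelled — the code-set definition is purely
  combinatorial (NL + GC + Hamming).
* Maximization problems must be negated by the caller; constraint
  handling beyond box clamping is out of scope.
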