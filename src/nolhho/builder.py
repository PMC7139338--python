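"""Construction of constrained DNA-storage code sets.

The builder grows A^GC,NL(n, d, w) sets one codeword at a time.  Each
addition is found by the NOL-HHO optimizer searching the continuous box
[0, 4]^n: a position vector decodes to a word by flooring each
coordinate to a quaternary digit, and a penalty fitness scores the word
so that fitness zero is exactly admissibility (feasible under the NL and
GC constraints and at Hamming distance >= d from every word already in
the set).  Each search randomly relabels the digit alphabet per
dimension (decorrelating the swarm's spatial preferences from word
identity) and seeds the flock on random feasible words.  When a search
comes up empty, maximality is certified exactly against the enumerated
feasible lexicon; the outer loop then perturbs the set by removing a
few random words and keeps growing, tracking the best set ever seen,
with independent restarts rerandomizing the trajectory.

Two independent oracles support verification: an exact branch-and-bound
maximum-clique search over the feasible-word compatibility graph (small
n), and a randomized first-fit greedy baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import dna
from .dna import CodeSet, default_gc_weight, digits_to_word, word_to_digits
from .hho import HHOConfig, SearchDomain, run

__all__ = [
    "BuilderConfig", "decode_vector", "candidate_fitness", "grow_code_set",
    "exhaustive_best", "greedy_baseline", "enumerate_feasible",
    "feasible_digit_matrix",
]


@dataclass(frozen=True)
class BuilderConfig:
    """Search budget and code parameters for :func:`grow_code_set`.

    ``iterations`` is the per-inner-search iteration cap; inner searches
    stop early the moment an admissible word (fitness zero) is found, so
    short caps waste little and merely declare maximality sooner — a
    cheap declaration is harmless because the perturbation step reopens
    the set anyway.  ``max_consecutive_failures`` is the number of
    perturbation cycles without a new best size tolerated before a
    restart ends.
    """

    n: int
    d: int
    w: Optional[int] = None
    hawks: int = 30
    iterations: int = 60
    max_consecutive_failures: int = 150
    restarts: int = 8
    seed: int = 0
    ruin_max: int = 3          # perturbation removes 1..ruin_max words
    target_size: Optional[int] = None   # optional early-stop set size
    max_cycles: Optional[int] = None    # hard cap on cycles per restart
    swarm_attempts: int = 1    # NOL-HHO searches per word query
    exact_rescue: bool = True  # certify maximality by a lexicon scan

    def __post_init__(self):
        if not 1 <= self.d <= self.n:
            raise ValueError("require 1 <= d <= n")
        if self.w is None:
            object.__setattr__(self, "w", default_gc_weight(self.n))
        if not 0 <= self.w <= self.n:
            raise ValueError("require 0 <= w <= n")


def decode_vector(v: np.ndarray) -> str:
    """Floor a continuous vector in [0, 4]^n to a DNA word."""
    v = np.asarray(v, dtype=float)
    digits = np.clip(np.floor(v).astype(int), 0, 3)
    return digits_to_word(digits)


def _batch_decode(v: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(np.atleast_2d(v)).astype(np.int8), 0, 3)


def _batch_fitness(digits: np.ndarray, code_matrix: np.ndarray,
                   n: int, d: int, w: int) -> np.ndarray:
    """Vectorized penalty fitness over a batch of digit rows."""
    penalty = n + 1
    nl = (digits[:, 1:] == digits[:, :-1]).sum(axis=1)
    gc = np.abs(((digits == 1) | (digits == 2)).sum(axis=1) - w)
    fit = penalty * (nl + gc).astype(float)
    if code_matrix.shape[0]:
        mism = (digits[:, None, :] != code_matrix[None, :, :]).sum(axis=2)
        fit += np.maximum(0, d - mism.min(axis=1))
    return fit


def candidate_fitness(word: str, current: CodeSet) -> float:
    """Penalty score of one candidate word against the current set.

    fitness = (n+1) * (adjacent repeats) + (n+1) * |GC count - w|
              + max(0, d - min Hamming distance to the set),

    with the min distance of an empty set defined as n, so the first
    word only needs feasibility.  Fitness 0 iff the word is admissible.
    """
    digits = word_to_digits(word)[None, :]
    return float(_batch_fitness(digits, current.digit_matrix(),
                                current.n, current.d, current.w)[0])


# --- feasible-word enumeration (oracle support) -------------------------

def enumerate_feasible(n: int, w: int) -> list[str]:
    """All length-n words with no adjacent repeat and GC count w."""
    return [digits_to_word(row) for row in feasible_digit_matrix(n, w)]


def feasible_digit_matrix(n: int, w: int) -> np.ndarray:
    """Digit rows of the feasible words, in lexicographic digit order."""
    rows: list[list[int]] = []

    def extend(prefix: list[int], gc: int) -> None:
        if len(prefix) == n:
            if gc == w:
                rows.append(prefix.copy())
            return
        remaining = n - len(prefix)
        if gc > w or gc + remaining < w:
            return
        for digit in range(4):
            if prefix and digit == prefix[-1]:
                continue
            prefix.append(digit)
            extend(prefix, gc + (1 if digit in (1, 2) else 0))
            prefix.pop()

    extend([], 0)
    if not rows:
        return np.empty((0, n), dtype=np.int8)
    return np.array(rows, dtype=np.int8)


# --- the NOL-HHO driven builder -----------------------------------------

def _find_admissible(code_matrix: np.ndarray, config: BuilderConfig,
                     rng: np.random.Generator,
                     lexicon: Optional[np.ndarray] = None) -> Optional[str]:
    """One inner NOL-HHO search for a fitness-zero word; None on failure.

    Each search draws a fresh random relabeling of the digit alphabet in
    every dimension (a symmetry of the decoding, not of the constraints:
    the fitness is always computed on the relabeled word).  The swarm has
    systematic spatial preferences — e.g. regions near the rabbit's basin
    are revisited — and without relabeling those preferences pin repeated
    searches to the same few codewords, which starves the outer
    perturbation loop of diversity.  Relabeling makes the identity of the
    word found approximately uniform over the admissible set while the
    swarm dynamics themselves are untouched.

    When the feasible lexicon (all NL- and GC-feasible digit rows) is
    supplied, the flock starts on random lexicon words, jittered inside
    their continuous cells, instead of uniformly in the box: for longer
    words the feasible manifold is a thin slice of [0, 4]^n and a blind
    start spends the whole budget rediscovering it.
    """
    n, d, w = config.n, config.d, config.w
    relabel = np.argsort(rng.random((n, 4)), axis=1).astype(np.int8)
    cols = np.arange(n)

    def objective(x):
        digits = relabel[cols, _batch_decode(x)]
        return _batch_fitness(digits, code_matrix, n, d, w)

    x0 = None
    if lexicon is not None and len(lexicon):
        inverse = np.argsort(relabel, axis=1)
        picks = lexicon[rng.integers(len(lexicon), size=config.hawks)]
        x0 = (inverse[cols, picks] + rng.random(picks.shape))

    domain = SearchDomain(np.zeros(n), np.full(n, 4.0))
    hho_cfg = HHOConfig.nol(n_hawks=config.hawks,
                            n_iterations=config.iterations)
    result = run(objective, hho_cfg, domain=domain, rng=rng, f_target=0.0,
                 x0=x0)
    if result.best_fitness <= 0.0:
        raw = np.clip(np.floor(result.best_position).astype(int), 0, 3)
        return digits_to_word(relabel[cols, raw])
    return None


def grow_code_set(config: BuilderConfig) -> CodeSet:
    """Grow the largest A^GC,NL(n, d, w) set the budget allows.

    Within each restart, words found by the inner NOL-HHO searches are
    appended while admissible ones keep turning up.  When the searches
    come up empty, maximality is certified exactly by a vectorized scan
    of the feasible lexicon before the set is perturbed: a stochastic
    search can miss an existing extension, and perturbing a
    still-extendable set degrades the walk, so a missed extension found
    by the scan is added (chosen uniformly at random) instead.  On
    certified maximality, 1..ruin_max random words are dropped and
    growth resumes.  A restart ends after ``max_consecutive_failures``
    perturbation cycles without improving that restart's best size, or
    after ``max_cycles`` word queries.  The best set across all
    restarts is returned and always validates.
    """
    rng = np.random.default_rng(config.seed)
    best_words: list[str] = []
    lexicon = feasible_digit_matrix(config.n, config.w)
    n = config.n

    def dist_ok(row: np.ndarray) -> np.ndarray:
        return (lexicon != row[None, :]).sum(axis=1) >= config.d

    for _ in range(config.restarts):
        words: list[str] = []
        matrix = np.empty((0, n), dtype=np.int8)
        # admissibility mask over the lexicon, maintained incrementally
        mask = np.ones(len(lexicon), dtype=bool)
        restart_best = 0
        stale = 0
        cycles = 0
        # recent swarm outcomes; when the swarm stops hitting, the exact
        # scan carries the search and swarm attempts are throttled
        swarm_recent: list[bool] = []
        while (stale < config.max_consecutive_failures
               and (config.max_cycles is None
                    or cycles < config.max_cycles)):
            cycles += 1
            found = None
            throttled = (len(swarm_recent) == 25 and not any(swarm_recent)
                         and cycles % 4 != 0)
            if not throttled:
                for _ in range(max(1, config.swarm_attempts)):
                    found = _find_admissible(matrix, config, rng, lexicon)
                    if found is not None:
                        break
                swarm_recent.append(found is not None)
                if len(swarm_recent) > 25:
                    swarm_recent.pop(0)
            if found is None and config.exact_rescue:
                idx = np.flatnonzero(mask)
                if len(idx):
                    found = digits_to_word(lexicon[rng.choice(idx)])
            if found is not None:
                row = word_to_digits(found)
                words.append(found)
                matrix = np.vstack([matrix, row])
                mask &= dist_ok(row)
                if len(words) > restart_best:
                    restart_best = len(words)
                    stale = 0
                    if len(words) > len(best_words):
                        best_words = words.copy()
                        if (config.target_size is not None
                                and len(best_words) >= config.target_size):
                            return _finalize(best_words, config)
            else:
                # certified maximal (or, without rescue, the searches
                # gave up): perturb and continue
                stale += 1
                if words:
                    k = min(len(words), int(rng.integers(1, config.ruin_max + 1)))
                    for _ in range(k):
                        words.pop(int(rng.integers(len(words))))
                    matrix = (np.vstack([word_to_digits(wd) for wd in words])
                              if words else np.empty((0, n), dtype=np.int8))
                    mask = np.ones(len(lexicon), dtype=bool)
                    for row in matrix:
                        mask &= dist_ok(row)

    return _finalize(best_words, config)


def _finalize(words: list[str], config: BuilderConfig) -> CodeSet:
    out = CodeSet(config.n, config.d, config.w, words)
    report = dna.validate_code_set(out)
    if not report.ok:  # pragma: no cover - soundness guard
        raise AssertionError(f"builder emitted an invalid set: "
                             f"{report.first_violation}")
    return out


# --- exact oracle: maximum clique over the compatibility graph ----------

def exhaustive_best(n: int, d: int, w: Optional[int] = None,
                    max_n: int = 7) -> CodeSet:
    """Exact maximum A^GC,NL(n, d, w) by branch-and-bound clique search.

    Enumerates the feasible words, builds the graph joining pairs at
    Hamming distance >= d, and finds a maximum clique with a
    Tomita-style greedy-coloring bound.  Practical for n <= 6 (the
    feasible graphs stay small); larger n raises.
    """
    if w is None:
        w = default_gc_weight(n)
    if n > max_n:
        raise ValueError(f"exact search supported only for n <= {max_n}")
    words = feasible_digit_matrix(n, w)
    m = len(words)
    if m == 0:
        return CodeSet(n, d, w, [])
    dist = (words[:, None, :] != words[None, :, :]).sum(axis=2)
    adjmat = dist >= d
    np.fill_diagonal(adjmat, False)

    # order vertices by degree (descending) for tighter early bounds
    order = np.argsort(-adjmat.sum(axis=1), kind="stable")
    adjmat = adjmat[np.ix_(order, order)]
    adj = [int.from_bytes(np.packbits(adjmat[i], bitorder="little").tobytes(),
                          "little") for i in range(m)]

    best: list[int] = []

    def expand(clique: list[int], cand: int) -> None:
        # greedy coloring of cand: color number bounds the clique extension
        verts: list[int] = []
        colors: list[int] = []
        rem = cand
        color = 0
        while rem:
            color += 1
            avail = rem
            while avail:
                v = (avail & -avail).bit_length() - 1
                verts.append(v)
                colors.append(color)
                avail &= ~(adj[v] | (1 << v))
                rem &= ~(1 << v)
        for i in range(len(verts) - 1, -1, -1):
            if len(clique) + colors[i] <= len(best):
                return
            v = verts[i]
            clique.append(v)
            nxt = cand & adj[v]
            if nxt:
                expand(clique, nxt)
            elif len(clique) > len(best):
                best[:] = clique
            clique.pop()
            cand &= ~(1 << v)

    expand([], (1 << m) - 1)
    chosen = [digits_to_word(words[order[v]]) for v in sorted(best)]
    return CodeSet(n, d, w, chosen)


# --- randomized greedy oracle -------------------------------------------

def greedy_baseline(n: int, d: int, w: Optional[int] = None,
                    orderings: int = 200, seed: int = 0) -> CodeSet:
    """First-fit greedy over random orderings of the feasible words.

    A cheap lower-bound oracle: for each ordering, keep a word iff its
    distance to everything kept so far is >= d; return the best set.
    """
    if w is None:
        w = default_gc_weight(n)
    words = feasible_digit_matrix(n, w)
    rng = np.random.default_rng(seed)
    best_idx: list[int] = []
    for _ in range(max(1, orderings)):
        order = rng.permutation(len(words))
        kept: list[int] = []
        kept_mat = np.empty((0, n), dtype=np.int8)
        for i in order:
            if (not kept or
                    (words[i][None, :] != kept_mat).sum(axis=1).min() >= d):
                kept.append(int(i))
                kept_mat = np.vstack([kept_mat, words[i]])
        if len(kept) > len(best_idx):
            best_idx = kept
    return CodeSet(n, d, w, [digits_to_word(words[i]) for i in best_idx])
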