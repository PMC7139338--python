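"""Constraint algebra for DNA-storage codewords.

Words are fixed-length strings over {A, C, G, T}, written 5'->3' left to
right, with the quaternary digit codec A-0, G-1, C-2, T-3.  A code set
A^GC,NL(n, d, w) collects words that simultaneously satisfy

* the No-runlength (NL) constraint: no two adjacent bases are equal
  (forbids homopolymers, which inflate sequencing error rates);
* the GC-content constraint: exactly w of the n bases are G or C
  (stabilizes melting behavior), with w = floor(n/2) by default;
* the minimum-distance constraint: every pair of distinct words has
  Hamming distance >= d (limits nonspecific hybridization and provides
  substitution-error resilience).

The size M of such a set gives a lower bound on the maximum achievable
code, and the code rate R = log4(M)/n measures information per base.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BASES", "CodeSet", "ValidationReport",
    "word_to_digits", "digits_to_word", "has_no_runlength", "gc_content",
    "gc_count", "hamming", "validate_code_set", "code_rate",
    "write_fasta", "read_fasta", "write_text", "read_text",
]

BASES = "AGCT"  # index position encodes the digit: A-0, G-1, C-2, T-3
_BASE_TO_DIGIT = {b: i for i, b in enumerate(BASES)}


def word_to_digits(word: str) -> np.ndarray:
    """Map a word to its base-4 digit vector (A-0, G-1, C-2, T-3)."""
    try:
        return np.array([_BASE_TO_DIGIT[b] for b in word], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in {word!r}") from exc


def digits_to_word(digits: Sequence[int]) -> str:
    """Inverse of :func:`word_to_digits`."""
    digits = np.asarray(digits, dtype=int)
    if digits.size and (digits.min() < 0 or digits.max() > 3):
        raise ValueError("digits must lie in 0..3")
    return "".join(BASES[int(d)] for d in digits)


def has_no_runlength(word: str) -> bool:
    """True iff no two adjacent bases are equal (e.g. CTAACG fails)."""
    return all(a != b for a, b in zip(word, word[1:]))


def _first_run_position(word: str) -> Optional[int]:
    """0-based index of the second base of the first adjacent repeat."""
    for i in range(1, len(word)):
        if word[i] == word[i - 1]:
            return i
    return None


def gc_count(word: str) -> int:
    return sum(1 for b in word if b in "GC")


def gc_content(word: str) -> float:
    """(G count + C count) / length, in [0, 1]."""
    if not word:
        raise ValueError("empty word has no GC-content")
    return gc_count(word) / len(word)


def hamming(x: str, y: str) -> int:
    """Number of positions at which two equal-length words differ."""
    if len(x) != len(y):
        raise ValueError("hamming distance requires equal lengths")
    return sum(1 for a, b in zip(x, y) if a != b)


def default_gc_weight(n: int) -> int:
    """Default GC weight: floor(n/2) (exactly n/2 for even n)."""
    return n // 2


@dataclass
class CodeSet:
    """A set of codewords with its parameters (n, d, w)."""

    n: int
    d: int
    w: int
    words: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 1 <= self.d <= self.n:
            raise ValueError("require 1 <= d <= n")
        if not 0 <= self.w <= self.n:
            raise ValueError("require 0 <= w <= n")
        self.words = list(self.words)

    def __len__(self) -> int:
        return len(self.words)

    def digit_matrix(self) -> np.ndarray:
        if not self.words:
            return np.empty((0, self.n), dtype=np.int8)
        return np.vstack([word_to_digits(wd) for wd in self.words])

    @property
    def rate(self) -> float:
        return code_rate(len(self.words), self.n)


@dataclass
class ValidationReport:
    """Outcome of checking a candidate code set against its constraints."""

    ok: bool
    n_words: int
    min_pairwise_distance: int      # n+1 sentinel when fewer than 2 words
    gc_counts: list[int]
    nl_violations: list[tuple[int, int]]   # (word index, 0-based position)
    gc_violations: list[int]               # word indices with wrong weight
    length_violations: list[int]
    duplicate_words: list[str]
    first_violation: Optional[str] = None

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["nl_violations"] = [list(v) for v in self.nl_violations]
        return json.dumps(d, indent=2)


def validate_code_set(candidate: CodeSet) -> ValidationReport:
    """Check lengths, NL, GC weight, duplicates and pairwise distances.

    Failures are report entries, never exceptions; ``first_violation``
    describes the earliest problem found, scanning words in order.
    """
    n, d, w = candidate.n, candidate.d, candidate.w
    words = candidate.words
    length_violations = [i for i, wd in enumerate(words) if len(wd) != n]
    nl_violations = []
    for i, wd in enumerate(words):
        pos = _first_run_position(wd)
        if pos is not None:
            nl_violations.append((i, pos))
    gc_counts = [gc_count(wd) for wd in words]
    gc_violations = [i for i, c in enumerate(gc_counts) if c != w]
    seen, duplicates = set(), []
    for wd in words:
        if wd in seen:
            duplicates.append(wd)
        seen.add(wd)

    min_dist = n + 1  # sentinel: no pair to measure
    closest = None
    ok_words = [wd for wd in words if len(wd) == n]
    if len(ok_words) >= 2:
        mat = np.vstack([word_to_digits(wd) for wd in ok_words])
        dm = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
        iu = np.triu_indices(len(ok_words), k=1)
        k = int(np.argmin(dm[iu]))
        min_dist = int(dm[iu][k])
        closest = (int(iu[0][k]), int(iu[1][k]))

    first = None
    if length_violations:
        first = f"word {length_violations[0]} has length != {n}"
    elif nl_violations:
        i, pos = nl_violations[0]
        first = (f"word {i} ({words[i]!r}) violates No-runlength at "
                 f"position {pos}")
    elif gc_violations:
        i = gc_violations[0]
        first = f"word {i} ({words[i]!r}) has GC count {gc_counts[i]} != {w}"
    elif duplicates:
        first = f"duplicate word {duplicates[0]!r}"
    elif min_dist < d:
        first = (f"words {closest[0]} and {closest[1]} at Hamming distance "
                 f"{min_dist} < {d}")

    return ValidationReport(
        ok=first is None,
        n_words=len(words),
        min_pairwise_distance=min_dist,
        gc_counts=gc_counts,
        nl_violations=nl_violations,
        gc_violations=gc_violations,
        length_violations=length_violations,
        duplicate_words=duplicates,
        first_violation=first,
    )


def code_rate(set_size: int, n: int) -> float:
    """Information rate R = log4(M) / n of an M-word length-n code."""
    if set_size < 1 or n < 1:
        raise ValueError("require M >= 1 and n >= 1")
    return math.log(set_size, 4) / n


# --- I/O ----------------------------------------------------------------

def write_fasta(words: Iterable[str], path: Union[str, Path]) -> None:
    """One record per codeword, ids word_0, word_1, ..."""
    records = [SeqRecord(Seq(wd), id=f"word_{k}", description="")
               for k, wd in enumerate(words)]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Union[str, Path]) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def write_text(words: Iterable[str], path: Union[str, Path]) -> None:
    Path(path).write_text("".join(f"{wd}\n" for wd in words))


def read_text(path: Union[str, Path]) -> list[str]:
    return [ln.strip().upper() for ln in Path(path).read_text().splitlines()
            if ln.strip()]
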