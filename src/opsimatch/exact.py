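"""Exact pattern matching: failure-table linear scan (EPM) and the naive baseline.

Both searchers report every occurrence start (0-based, overlapping included,
ascending) together with :class:`SearchStats` counters.  Character comparisons
— not wall-clock time — are the cost proxy used throughout the package, so
algorithm costs are reproducible across machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sbarc import InvalidInputError, Pattern, compute_sbarc


@dataclass(frozen=True)
class Sequence:
    """A subject sequence, case-folded to uppercase."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ExactHit:
    """An exact occurrence: pattern begins at 0-based ``start``."""

    start: int


@dataclass
class SearchStats:
    """Instrumentation counters shared by all searchers.

    char_comparisons
        number of character-pair equality tests performed.
    window_shifts
        number of times the implied alignment window start advanced.
    seq_index_regressions
        number of times the sequence index moved backwards.  Zero for the
        linear-scan exact matcher by construction; the approximate matcher
        may rewind to the first mismatch of an alignment.
    """

    char_comparisons: int = 0
    window_shifts: int = 0
    seq_index_regressions: int = 0


def as_sequence(sequence: Sequence | str, identifier: str = "seq") -> Sequence:
    return sequence if isinstance(sequence, Sequence) else Sequence(identifier, sequence)


def as_pattern(pattern: Pattern | str) -> Pattern:
    return pattern if isinstance(pattern, Pattern) else Pattern(pattern)


def epm_search(
    sequence: Sequence | str, pattern: Pattern | str
) -> tuple[list[ExactHit], SearchStats]:
    """Find all exact occurrences with a single forward scan.

    On a mismatch at pattern index j > 0 the pattern index falls back to the
    shift value of index j-1, so characters known to match are never
    re-compared and the sequence index never decreases.  After a full match
    the pattern index continues from the table's last entry, which finds
    overlapping occurrences.  Total character comparisons are at most twice
    the sequence length.
    """
    pat = as_pattern(pattern)
    seq = as_sequence(sequence)
    stats = SearchStats()
    hits: list[ExactHit] = []
    s, p = seq.residues, pat.residues
    ls, lp = len(s), len(p)
    if lp > ls:
        return hits, stats
    table = compute_sbarc(pat).values
    i = j = 0
    window_start = 0  # implied alignment start i - j
    while i < ls:
        stats.char_comparisons += 1
        if s[i] == p[j]:
            i += 1
            j += 1
            if j == lp:
                hits.append(ExactHit(i - lp))
                j = table[lp - 1]
        elif j > 0:
            j = table[j - 1]
        else:
            i += 1
        if i - j > window_start:
            stats.window_shifts += 1
            window_start = i - j
    return hits, stats


def naive_search(
    sequence: Sequence | str, pattern: Pattern | str
) -> tuple[list[ExactHit], SearchStats]:
    """Check every window, shifting by one position after each.

    Examines ``ls - lp + 1`` windows on a full scan; each window comparison
    stops at the first mismatching character.  Worst-case comparisons are
    ``lp * (ls - lp + 1)`` (e.g. a run of A's searched for a shorter run).
    """
    pat = as_pattern(pattern)
    seq = as_sequence(sequence)
    stats = SearchStats()
    hits: list[ExactHit] = []
    s, p = seq.residues, pat.residues
    ls, lp = len(s), len(p)
    for start in range(ls - lp + 1):
        if start > 0:
            stats.window_shifts += 1
        matched = True
        for j in range(lp):
            stats.char_comparisons += 1
            if s[start + j] != p[j]:
                matched = False
                break
        if matched:
            hits.append(ExactHit(start))
    return hits, stats
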