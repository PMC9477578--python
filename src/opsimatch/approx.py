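"""Approximate (k-mismatch) pattern matching under the substitution-only model.

Two matchers are provided:

``hamming_window_search``
    the brute-force sliding-window matcher with early abandon.  It examines
    every window and therefore reports *every* occurrence within the mismatch
    budget; it serves both as a comparison baseline and as the completeness
    oracle for the optimized matcher.

``opsi_search``
    the optimized pattern-similarity matcher.  It scans like the exact
    failure-table matcher but tolerates up to ``è`` substitutions per
    alignment; on exhausting the budget (or after reporting an inexact hit)
    it rewinds the sequence index to the *first* mismatch of the current
    alignment and resumes with the failure-table shift taken there.  Every
    character before the first mismatch matched exactly, so the prefix-shift
    precondition of the failure table holds at that point — this is what
    makes rewinding to the first (not last) mismatch sound.

Reported hits are sound by construction and re-certified at report time by a
direct window comparison; whether the optimized matcher finds every in-budget
occurrence is measured against the oracle, not assumed (see the benchmark and
test suite, which report its recall).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exact import SearchStats, Sequence, as_pattern, as_sequence
from .sbarc import InvalidInputError, Pattern, compute_sbarc


@dataclass(frozen=True)
class SearchConfig:
    """Approximate-search parameters: ``max_mismatches`` is the per-occurrence
    substitution budget è (non-negative)."""

    max_mismatches: int

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise InvalidInputError("mismatch budget must be non-negative")


@dataclass(frozen=True)
class ApproxHit:
    """An approximate occurrence.

    ``start`` is the 0-based window start; ``mismatch_offsets`` are the
    ascending pattern-relative offsets at which window and pattern differ,
    with ``mismatch_count == len(mismatch_offsets)``.
    """

    start: int
    mismatch_count: int
    mismatch_offsets: tuple[int, ...]


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(a) != len(b):
        raise InvalidInputError(f"hamming distance needs equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _window_offsets(s: str, start: int, p: str) -> tuple[int, ...]:
    return tuple(j for j in range(len(p)) if s[start + j] != p[j])


def _config(config: SearchConfig | int) -> SearchConfig:
    return config if isinstance(config, SearchConfig) else SearchConfig(config)


def hamming_window_search(
    sequence: Sequence | str,
    pattern: Pattern | str,
    config: SearchConfig | int,
) -> tuple[list[ApproxHit], SearchStats]:
    """Report every window whose hamming distance to the pattern is within budget.

    Scans all ``ls - lp + 1`` windows; each window scan abandons as soon as the
    mismatch count exceeds the budget.  Complete by construction.
    """
    pat = as_pattern(pattern)
    seq = as_sequence(sequence)
    cfg = _config(config)
    stats = SearchStats()
    hits: list[ApproxHit] = []
    s, p = seq.residues, pat.residues
    ls, lp = len(s), len(p)
    budget = cfg.max_mismatches
    for start in range(ls - lp + 1):
        if start > 0:
            stats.window_shifts += 1
        offsets: list[int] = []
        for j in range(lp):
            stats.char_comparisons += 1
            if s[start + j] != p[j]:
                offsets.append(j)
                if len(offsets) > budget:
                    break
        else:
            hits.append(ApproxHit(start, len(offsets), tuple(offsets)))
    return hits, stats


def opsi_search(
    sequence: Sequence | str,
    pattern: Pattern | str,
    config: SearchConfig | int,
) -> tuple[list[ApproxHit], SearchStats]:
    """Failure-table scan tolerating up to ``è`` substitutions per alignment.

    Scanning proceeds left to right as in exact search.  A mismatch while the
    error count is below budget is forgiven: the coordinates of the alignment's
    first mismatch are recorded and the scan continues right.  When the pattern
    index reaches the pattern length the window start is reported with its
    mismatch offsets (recomputed by direct window comparison, so every reported
    hit is self-certified).  When the budget would be exceeded — or after
    reporting a hit that contained at least one mismatch — the scan rewinds to
    the recorded first mismatch and resumes with the failure-table shift taken
    at its pattern index; after an exact hit it continues forward KMP-style.
    With a zero budget this reduces exactly to the exact matcher.

    Hits are deduplicated and returned in ascending start order.  A degenerate
    budget ``è >= lp`` makes every window a hit and is served by a direct
    window enumeration.
    """
    pat = as_pattern(pattern)
    seq = as_sequence(sequence)
    cfg = _config(config)
    stats = SearchStats()
    s, p = seq.residues, pat.residues
    ls, lp = len(s), len(p)
    budget = cfg.max_mismatches
    if lp > ls:
        return [], stats

    if budget >= lp:  # every window qualifies
        hits = []
        for start in range(ls - lp + 1):
            if start > 0:
                stats.window_shifts += 1
            stats.char_comparisons += lp
            offsets = _window_offsets(s, start, p)
            hits.append(ApproxHit(start, len(offsets), offsets))
        return hits, stats

    table = compute_sbarc(pat).values
    found: dict[int, ApproxHit] = {}
    i = j = 0
    errors = 0
    first_mismatch: tuple[int, int] | None = None  # (seq index, pat index)
    max_window_start = 0

    def restart(at: tuple[int, int]) -> tuple[int, int]:
        """Resume from the alignment's first mismatch with the shift taken there."""
        fi, fj = at
        if fj > 0:
            return fi, table[fj - 1]
        return fi + 1, 0

    while i < ls:
        stats.char_comparisons += 1
        if s[i] == p[j]:
            step_ok = True
        elif errors < budget:
            if first_mismatch is None:
                first_mismatch = (i, j)
            errors += 1
            step_ok = True
        else:
            ni, nj = restart(first_mismatch if first_mismatch is not None else (i, j))
            if ni < i:
                stats.seq_index_regressions += 1
            i, j = ni, nj
            errors = 0
            first_mismatch = None
            if i - j > max_window_start:
                stats.window_shifts += 1
                max_window_start = i - j
            continue

        if step_ok:
            i += 1
            j += 1
            if j == lp:
                start = i - lp
                if start not in found:
                    if errors == 0:
                        found[start] = ApproxHit(start, 0, ())
                    else:
                        stats.char_comparisons += lp
                        offsets = _window_offsets(s, start, p)
                        if len(offsets) <= budget:
                            found[start] = ApproxHit(start, len(offsets), offsets)
                if errors == 0:
                    j = table[lp - 1]
                else:
                    ni, nj = restart(first_mismatch)  # type: ignore[arg-type]
                    if ni < i:
                        stats.seq_index_regressions += 1
                    i, j = ni, nj
                    errors = 0
                    first_mismatch = None
        if i - j > max_window_start:
            stats.window_shifts += 1
            max_window_start = i - j

    return [found[k] for k in sorted(found)], stats
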