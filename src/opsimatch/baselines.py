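"""Comparison baselines: pattern automaton and Boyer–Moore bad-character table.

The automaton gives an exact matcher with exactly one state transition per
sequence character; the bad-character table is the preprocessing half of
Boyer–Moore used in the preprocessing-cost comparison against the failure
table (only the bad-character rule is built — the good-suffix rule and the
full Boyer–Moore search are out of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exact import ExactHit, Sequence, as_pattern, as_sequence
from .sbarc import InvalidInputError, Pattern, compute_sbarc, resolve_alphabet


@dataclass(frozen=True)
class PatternDfa:
    """Deterministic automaton recognising occurrences of a pattern.

    States 0..lp; state k means "the last k characters consumed equal the
    first k pattern characters (and k is maximal)".  State lp accepts.
    Transitions are total over the declared alphabet; symbols outside it
    fall back to state 0 (they can never be part of a match).
    """

    pattern: str
    alphabet: frozenset[str]
    transitions: tuple[dict[str, int], ...]

    @property
    def state_count(self) -> int:
        return len(self.pattern) + 1

    @property
    def accept_state(self) -> int:
        return len(self.pattern)

    def step(self, state: int, symbol: str) -> int:
        return self.transitions[state].get(symbol, 0)


def build_dfa(pattern: Pattern | str, alphabet: str | frozenset[str] | set[str] = "auto") -> PatternDfa:
    """Build the automaton from the failure table in O(lp * |alphabet|).

    From state k on symbol c the next state is k+1 if c equals the k-th
    pattern character, else the state of the longest pattern prefix that is a
    suffix of the consumed text — obtained by copying the transition of the
    failure state.  The accept state keeps scanning via the failure state of
    the full pattern, so overlapping occurrences are found.
    """
    pat = as_pattern(pattern)
    p = pat.residues
    symbols = resolve_alphabet(alphabet, p)
    missing = set(p) - symbols
    if missing:
        raise InvalidInputError(f"pattern symbols {sorted(missing)} outside declared alphabet")
    lp = len(p)
    table = compute_sbarc(pat).values
    transitions: list[dict[str, int]] = []
    for k in range(lp + 1):
        fail = transitions[table[k - 1]] if k > 0 else None
        row = {}
        for c in symbols:
            if k < lp and c == p[k]:
                row[c] = k + 1
            elif k == 0:
                row[c] = 0
            else:
                row[c] = fail[c]  # type: ignore[index]
        transitions.append(row)
    return PatternDfa(p, symbols, tuple(transitions))


def dfa_search(sequence: Sequence | str, dfa: PatternDfa) -> list[ExactHit]:
    """Exact search by running the automaton: one transition per character."""
    seq = as_sequence(sequence)
    lp = len(dfa.pattern)
    hits: list[ExactHit] = []
    state = 0
    for i, c in enumerate(seq.residues):
        state = dfa.step(state, c)
        if state == dfa.accept_state:
            hits.append(ExactHit(i - lp + 1))
    return hits


@dataclass(frozen=True)
class BadCharTable:
    """Boyer–Moore bad-character preprocessing.

    ``last_index[c]`` is the rightmost 0-based index of symbol c in the
    pattern, -1 if absent.  ``operations`` counts the per-symbol table
    updates performed during construction (lp + |alphabet|); the table build
    makes no character-equality comparisons, so this operation count is the
    unit used when its preprocessing cost is compared with the failure
    table's comparison count.
    """

    last_index: dict[str, int]
    operations: int = 0


def bm_bad_char_table(
    pattern: Pattern | str, alphabet: str | frozenset[str] | set[str] = "auto"
) -> BadCharTable:
    """Single left-to-right pass recording each symbol's rightmost position."""
    pat = as_pattern(pattern)
    p = pat.residues
    symbols = resolve_alphabet(alphabet, p)
    last = {c: -1 for c in symbols}
    ops = len(symbols)
    for i, c in enumerate(p):
        last[c] = i
        ops += 1
    return BadCharTable(last, ops)
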