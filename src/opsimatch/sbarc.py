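"""Failure-table ("shift beyond for avoiding redundant comparison") construction.

The SBARC table of a pattern P stores, at index i, the length of the longest
proper prefix of ``P[0..i]`` that is also a suffix of ``P[0..i]`` — the classic
KMP failure function.  Shifting the pattern by this value after a mismatch
skips every character that is already known to match, so the searching
algorithms built on it never re-read a sequence character.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_NAMED_ALPHABETS = {"dna": DNA_ALPHABET, "protein": PROTEIN_ALPHABET}


class InvalidInputError(ValueError):
    """Raised on inputs that violate an operation's preconditions."""


def resolve_alphabet(alphabet: str | frozenset[str] | set[str], residues: str = "") -> frozenset[str]:
    """Map an alphabet name ('dna' | 'protein' | 'auto') or explicit symbol set
    to a frozenset of uppercase symbols.  'auto' infers from the residues."""
    if isinstance(alphabet, (set, frozenset)):
        return frozenset(c.upper() for c in alphabet)
    name = alphabet.lower()
    if name == "auto":
        return frozenset(residues.upper())
    try:
        return _NAMED_ALPHABETS[name]
    except KeyError:
        raise InvalidInputError(f"unknown alphabet {alphabet!r}; expected dna, protein or auto") from None


@dataclass(frozen=True)
class Pattern:
    """A query string over a declared alphabet.

    Residues are case-folded to uppercase on construction (FASTA uses lower
    case for soft-masking; the match semantics here are case-insensitive).
    Symbols outside the named alphabets are legal under ``alphabet='auto'``;
    they simply never match anything but themselves.
    """

    residues: str
    alphabet: frozenset[str] = field(default=frozenset())

    def __init__(self, residues: str, alphabet: str | frozenset[str] | set[str] = "auto"):
        if not residues:
            raise InvalidInputError("pattern must contain at least one residue")
        folded = residues.upper()
        symbols = resolve_alphabet(alphabet, folded)
        missing = set(folded) - symbols
        if missing:
            raise InvalidInputError(
                f"pattern symbols {sorted(missing)} outside declared alphabet"
            )
        object.__setattr__(self, "residues", folded)
        object.__setattr__(self, "alphabet", symbols)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class SbarcTable:
    """Per-index shift values for a pattern.

    ``values[i]`` is the length of the longest proper prefix of the first
    i+1 pattern characters that is also their suffix.  Invariants:
    ``values[0] == 0`` and ``0 <= values[i] <= i`` with
    ``values[i] <= values[i-1] + 1``.
    """

    values: tuple[int, ...]
    comparisons: int = 0

    def __post_init__(self) -> None:
        v = self.values
        if not v or v[0] != 0:
            raise InvalidInputError("shift table must start with 0")
        for i, x in enumerate(v):
            if not 0 <= x <= i or (i and x > v[i - 1] + 1):
                raise InvalidInputError(f"shift value {x} at index {i} violates table invariants")

    def __getitem__(self, i: int) -> int:
        return self.values[i]

    def __len__(self) -> int:
        return len(self.values)


def _as_pattern(pattern: Pattern | str) -> Pattern:
    return pattern if isinstance(pattern, Pattern) else Pattern(pattern)


def compute_sbarc(pattern: Pattern | str) -> SbarcTable:
    """Build the failure table in a single left-to-right pass.

    The two-pointer construction performs at most ``2 * len(pattern)``
    character comparisons: each comparison either advances the scan index or
    strictly shrinks the tracked prefix length, and both are bounded by the
    pattern length.  The count is recorded on the returned table.
    """
    pat = _as_pattern(pattern).residues
    n = len(pat)
    values = [0] * n
    comparisons = 0
    k = 0  # length of the current longest proper prefix-suffix
    i = 1
    while i < n:
        comparisons += 1
        if pat[i] == pat[k]:
            k += 1
            values[i] = k
            i += 1
        elif k > 0:
            k = values[k - 1]
        else:
            values[i] = 0
            i += 1
    return SbarcTable(tuple(values), comparisons)


def lps_oracle(pattern: Pattern | str) -> SbarcTable:
    """Brute-force longest-proper-prefix-that-is-a-suffix reference.

    For each index i, tries every proper prefix length k from i down to 0 and
    keeps the largest k with ``pat[:k] == pat[i-k+1:i+1]``.  Cubic time; used
    only as an independent test oracle for :func:`compute_sbarc`.
    """
    pat = _as_pattern(pattern).residues
    values = []
    for i in range(len(pat)):
        for k in range(i, -1, -1):
            if pat[:k] == pat[i - k + 1 : i + 1]:
                values.append(k)
                break
    return SbarcTable(tuple(values))
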