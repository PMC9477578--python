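"""Synthetic test material: uniform random sequences and planted occurrences.

The generator emulates the kind of material the matchers are meant for:
i.i.d. uniform sequences over the DNA or protein alphabet, optionally with a
pattern copied in at known positions carrying exactly k substitutions
(substitution-only mutation — no indels, matching the error model of the
approximate matcher).  Everything is driven by an explicit integer seed and
is bit-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .exact import Sequence
from .sbarc import InvalidInputError, resolve_alphabet


def random_sequence(
    length: int,
    alphabet: str | frozenset[str] | set[str] = "dna",
    seed: int = 0,
    identifier: str | None = None,
) -> Sequence:
    """Uniform i.i.d. sequence of the given length; identical arguments give
    identical output."""
    if length < 0:
        raise InvalidInputError("sequence length must be non-negative")
    symbols = sorted(resolve_alphabet(alphabet))
    if length and not symbols:
        raise InvalidInputError("cannot draw residues from an empty alphabet")
    rng = random.Random(seed)
    residues = "".join(rng.choices(symbols, k=length))
    name = identifier if identifier is not None else f"synth_{length}_{seed}"
    return Sequence(name, residues)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a background sequence with planted pattern occurrences.

    ``plants`` lists (pattern, start, k_mismatches) triples; planted windows
    must lie inside the sequence and be pairwise non-overlapping, and each
    receives exactly ``k_mismatches`` substitutions at distinct offsets.
    """

    length: int
    alphabet: str = "dna"
    seed: int = 0
    plants: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.length < 0:
            raise InvalidInputError("sequence length must be non-negative")
        spans = []
        for pattern, start, k in self.plants:
            lp = len(pattern)
            if lp < 1:
                raise InvalidInputError("planted pattern must be non-empty")
            if not 0 <= start <= self.length - lp:
                raise InvalidInputError(f"plant at {start} (length {lp}) outside sequence of length {self.length}")
            if not 0 <= k <= lp:
                raise InvalidInputError(f"mismatch count {k} outside [0, {lp}]")
            spans.append((start, start + lp))
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise InvalidInputError(f"planted windows [{a0},{a1}) and [{b0},{b1}) overlap")


def plant_occurrences(spec: SyntheticSpec) -> tuple[Sequence, list[tuple[int, int]]]:
    """Generate the background and copy each plant in with its substitutions.

    Each plant writes the pattern into its window, then substitutes exactly
    ``k`` seeded-random distinct offsets, always changing the symbol — so the
    window's hamming distance to the pattern is exactly k by construction.
    Returns the sequence and the ground truth as (start, k) pairs sorted by
    start.
    """
    symbols = sorted(resolve_alphabet(spec.alphabet))
    background = random_sequence(spec.length, spec.alphabet, spec.seed)
    residues = list(background.residues)
    rng = random.Random(spec.seed + 1)
    truth = []
    for pattern, start, k in spec.plants:
        pat = pattern.upper()
        residues[start : start + len(pat)] = pat
        for offset in rng.sample(range(len(pat)), k):
            original = pat[offset]
            choices = [c for c in symbols if c != original]
            if not choices:
                raise InvalidInputError("alphabet too small to substitute a symbol")
            residues[start + offset] = rng.choice(choices)
        truth.append((start, k))
    truth.sort()
    return Sequence(background.identifier, "".join(residues)), truth
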