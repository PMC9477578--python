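"""Pattern automaton and bad-character table baselines."""

import pytest

from opsimatch import (
    InvalidInputError,
    bm_bad_char_table,
    build_dfa,
    dfa_search,
    epm_search,
)

from conftest import random_instance


def test_dfa_structure_and_accept():
    dfa = build_dfa("AAC", {"A", "C"})
    assert dfa.state_count == 4 and dfa.accept_state == 3
    assert dfa.step(2, "C") == 3  # final transition into accept
    assert dfa.step(0, "C") == 0  # non-initial symbol keeps state 0
    # transitions are total over the declared alphabet
    assert all(set(row) == {"A", "C"} for row in dfa.transitions)


def test_dfa_search_examples():
    dfa = build_dfa("AAC")
    assert [h.start for h in dfa_search("AAAC", dfa)] == [1]
    assert [h.start for h in dfa_search("CCCC", dfa)] == []
    assert [h.start for h in dfa_search("AAC", dfa)] == [0]
    # overlapping occurrences via the accept-state fallback
    dfa2 = build_dfa("AA")
    assert [h.start for h in dfa_search("AAAA", dfa2)] == [0, 1, 2]


def test_dfa_out_of_alphabet_symbols_reset():
    dfa = build_dfa("AC", {"A", "C"})
    assert [h.start for h in dfa_search("ANAC", dfa)] == [2]


def test_dfa_pattern_outside_alphabet_rejected():
    with pytest.raises(InvalidInputError):
        build_dfa("ACGT", {"A", "C"})


def test_dfa_matches_linear_scan_on_random_instances(rng):
    for _ in range(200):
        seq, pat = random_instance(rng, 500, 20)
        dfa = build_dfa(pat, "dna")
        assert [h.start for h in dfa_search(seq, dfa)] == [
            h.start for h in epm_search(seq, pat)[0]
        ]


@pytest.mark.parametrize(
    ("pattern", "expected"),
    [
        ("ACG", {"A": 0, "C": 1, "G": 2, "T": -1}),
        ("ACGACG", {"A": 3, "C": 4, "G": 5, "T": -1}),
        ("AAAA", {"A": 3, "C": -1, "G": -1, "T": -1}),
    ],
)
def test_bad_char_table(pattern, expected):
    table = bm_bad_char_table(pattern, "dna")
    assert table.last_index == expected
    # idempotent and sequence-independent by construction
    assert bm_bad_char_table(pattern, "dna").last_index == expected
    assert table.operations == len(pattern) + 4


def test_bad_char_empty_pattern():
    with pytest.raises(InvalidInputError):
        bm_bad_char_table("", "dna")


def test_preprocessing_costs_within_constant_factor(rng):
    """Failure-table comparisons and bad-character operations are both linear
    in pattern length and stay within a small constant factor of each other
    across long patterns."""
    from opsimatch import compute_sbarc, random_sequence

    for lp in (5000, 20000, 50000):
        pat = random_sequence(lp, "dna", seed=lp).residues
        sbarc_cost = compute_sbarc(pat).comparisons
        bc_cost = bm_bad_char_table(pat, "dna").operations
        ratio = sbarc_cost / bc_cost
        assert 1 / 4 <= ratio <= 4
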