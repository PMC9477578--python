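"""Approximate matchers: hamming primitives, soundness, oracle relations."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opsimatch import (
    InvalidInputError,
    epm_search,
    hamming_distance,
    hamming_window_search,
    opsi_search,
)

from conftest import random_instance

log = logging.getLogger(__name__)


@pytest.mark.parametrize(
    ("a", "b", "d"),
    [("ACGT", "ACGT", 0), ("AAAA", "TTTT", 4), ("ACGT", "ACGA", 1)],
)
def test_hamming_distance(a, b, d):
    assert hamming_distance(a, b) == d


def test_hamming_distance_length_mismatch():
    with pytest.raises(InvalidInputError):
        hamming_distance("AC", "ACG")


def test_window_search_enumerates_all_windows():
    hits, stats = hamming_window_search("AAAA", "AT", 1)
    assert [(h.start, h.mismatch_count, h.mismatch_offsets) for h in hits] == [
        (0, 1, (1,)),
        (1, 1, (1,)),
        (2, 1, (1,)),
    ]
    assert stats.window_shifts == 2


def test_window_search_identity_and_zero_budget(rng):
    hits, _ = hamming_window_search("ACGT", "ACGT", 4)
    assert [(h.start, h.mismatch_count) for h in hits] == [(0, 0)]
    for _ in range(50):
        seq, pat = random_instance(rng, 300, 10)
        wh, _ = hamming_window_search(seq, pat, 0)
        eh, _ = epm_search(seq, pat)
        assert [h.start for h in wh] == [h.start for h in eh]


def test_opsi_zero_budget_reduces_to_exact():
    hits, _ = opsi_search("ACGACGACG", "ACGACG", 0)
    assert [(h.start, h.mismatch_count) for h in hits] == [(0, 0), (3, 0)]


def test_opsi_degenerate_budget_reports_every_window():
    hits, _ = opsi_search("AAAA", "AT", 2)
    assert [h.start for h in hits] == [0, 1, 2]
    assert all(h.mismatch_count == hamming_distance("AAAA"[h.start : h.start + 2], "AT") for h in hits)


def test_opsi_invalid_inputs():
    with pytest.raises(InvalidInputError):
        opsi_search("ACGT", "", 1)
    with pytest.raises(InvalidInputError):
        opsi_search("ACGT", "AC", -1)


def test_opsi_soundness_subset_and_recall(rng):
    """On random instances every reported hit is hamming-certified within
    budget, exact hits are never missed, and the zero-budget run equals the
    exact matcher; recall against the exhaustive oracle is logged."""
    oracle_total = found_total = 0
    for _ in range(200):
        seq, pat = random_instance(rng, 600, 25)
        eta = rng.randint(0, 5)
        oh, _ = hamming_window_search(seq, pat, eta)
        ph, _ = opsi_search(seq, pat, eta)
        starts = [h.start for h in ph]
        assert starts == sorted(set(starts))  # ascending, deduplicated
        oracle = {h.start: h for h in oh}
        for h in ph:
            assert h.mismatch_count == len(h.mismatch_offsets) <= eta
            window = seq[h.start : h.start + len(pat)]
            assert hamming_distance(window, pat) == h.mismatch_count
            assert h.start in oracle  # never reports a window the oracle rejects
        opsi_map = {h.start: h.mismatch_count for h in ph}
        for h in epm_search(seq, pat)[0]:
            assert opsi_map.get(h.start) == 0
        oracle_total += len(oh)
        found_total += sum(1 for s in oracle if s in opsi_map)
    recall = found_total / oracle_total if oracle_total else 1.0
    log.info("optimized-matcher recall vs exhaustive oracle: %.4f (%d/%d)",
             recall, found_total, oracle_total)
    assert recall > 0.5  # gross-failure guard; completeness itself is reported, not asserted


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=120),
    st.text(alphabet="ACGT", min_size=1, max_size=10),
    st.integers(min_value=0, max_value=4),
)
def test_property_soundness(seq, pat, eta):
    hits, _ = opsi_search(seq, pat, eta)
    for h in hits:
        assert hamming_distance(seq[h.start : h.start + len(pat)], pat) == h.mismatch_count <= eta
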