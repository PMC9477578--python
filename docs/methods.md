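# Methods

## Model and scope

All matching is substitution-only: an occurrence of pattern `P` (length
`l_p`) in sequence `S` (length `l_s`) at start `i` is the window
`S[i..i+l_p)`, scored by its Hamming distance to `P`. Insertions and
deletions are out of scope by design — the shift-table machinery relies on
positional alignment, which indels break. Coordinates are 0-based half-open
throughout (BED convention); the CLI's `--one-based` flag shifts *display*
only. All residues are case-folded to uppercase before comparison, because
FASTA uses lower case for soft-masking, not for distinct symbols. Ambiguity
codes such as `N` are ordinary symbols that match only themselves: the
matcher makes no IUPAC expansion, so an `N`-rich region simply scores as
mismatches.

## The shift table

`compute_sbarc(P)` returns, for each index `i`, the length of the longest
proper prefix of `P[0..i]` that is also its suffix — the KMP failure
function. The two-pointer construction makes at most `2·l_p` character
comparisons (each comparison either advances the scan or strictly shrinks
the tracked prefix), and the count is recorded on the returned table so the
preprocessing-cost comparison against Boyer–Moore is measurable rather than
anecdotal. A cubic-time brute-force oracle (`lps_oracle`) exists purely for
testing: the suite checks agreement exhaustively for all binary patterns up
to length 12 and on random DNA patterns up to length 200.

## Exact search

`epm_search` is the classic failure-table scan: the sequence index never
moves backwards; on a mismatch at pattern index `j > 0` the pattern index
falls back to `SV[j−1]`; after a full match it continues from `SV[l_p−1]`,
which yields overlapping occurrences. Comparison count is bounded by
`2·l_s`. The instrumentation defines a *window shift* as any increase of the
implied alignment start `i − j`, which makes shift counts comparable across
the naive, automaton and approximate matchers.

## Approximate search

`opsi_search` extends the scan with a per-alignment error budget `è`:

- A mismatch while fewer than `è` errors are outstanding is *forgiven*: the
  coordinates of the alignment's **first** mismatch are recorded (once) and
  the scan continues right as if the characters had matched.
- When the pattern index reaches `l_p`, the window start is reported.
- When the budget would be exceeded, or after reporting a hit that contained
  at least one mismatch, the scan *rewinds*: the sequence index returns to
  the recorded first mismatch `i_f` and the pattern index becomes
  `SV[j_f−1]` (where `j_f` is the first mismatch's pattern index). The
  rewind anchors at the first mismatch because every character before it
  matched exactly, so the prefix-shift precondition of the failure table
  holds there; anchoring at a later mismatch would not be sound. After an
  exact hit the scan continues forward KMP-style from `SV[l_p−1]`.
- Edge case `j_f = 0` (`SV[−1]` undefined): the pattern index resets to 0
  and the sequence index advances one position — the same branch KMP takes
  at `j = 0`. With `è = 0` the whole procedure reduces exactly to
  `epm_search`, which the suite asserts.
- Degenerate budget `è ≥ l_p`: every window trivially qualifies, so the
  implementation enumerates windows directly instead of running the restart
  machinery.

Each rewind strictly increases the implied window start (`i_f − SV[j_f−1] >
i_f − j_f`), which guarantees termination and bounds the worst case at
`O(l_s·è)` comparisons. Hits are deduplicated and reported in ascending
start order; mismatch offsets are recomputed by a direct window comparison
at report time, so every reported hit is self-certifying (soundness is a
hard test invariant).

**Completeness is measured, not claimed.** The scan can pass over an
in-budget window when a forgiven mismatch steers the alignment past it, so
recall against the exhaustive sliding-window oracle is computed and logged
by the test suite (typically ≈ 98–99% on uniform random DNA at `è ≤ 5`)
rather than asserted at 100%. Three properties *are* asserted as hard:
soundness of every reported hit, equality with exact search at `è = 0`, and
the exact-subset property — no exact occurrence is ever missed at any
budget.

## Baselines

- `naive_search`: every window, early abandon at the first mismatch;
  examines `l_s − l_p + 1` windows; worst case `l_p·(l_s − l_p + 1)`
  comparisons.
- `build_dfa` / `dfa_search`: the `l_p + 1`-state pattern automaton built
  from the failure table in `O(l_p·|Σ|)`; exactly one transition per
  sequence character; out-of-alphabet symbols fall to state 0 since they can
  never be part of a match. Validated by three-way agreement with the linear
  scan and the naive scan.
- `bm_bad_char_table`: the bad-character half of Boyer–Moore preprocessing
  (rightmost index per symbol). Only this half is built — it is all the
  preprocessing comparison needs; the good-suffix rule and the full
  Boyer–Moore search are non-goals. The build makes no character-equality
  comparisons, so its cost counter records per-symbol table updates
  (`l_p + |Σ|`), the common unit for the preprocessing-cost comparison.
- `hamming_window_search`: every window, early abandon once mismatches
  exceed `è`. Complete by construction; doubles as the correctness oracle
  and the comparison baseline.

## Synthetic data

`random_sequence` draws i.i.d. uniform symbols over `{A,C,G,T}` or the 20
standard amino-acid one-letter codes, from a named `random.Random(seed)` —
bit-reproducible by construction. `plant_occurrences` copies a pattern into
pairwise non-overlapping windows and applies exactly `k` substitutions at
distinct seeded offsets, each guaranteed to change the symbol, so the
planted window's Hamming distance to the pattern is exactly `k` by
construction and the returned ground truth is exact.

What this emulates — and does not: uniform random backgrounds have no
repeats, skewed composition, low-complexity runs or homopolymers, all of
which real genomes have and all of which make shift tables *more* useful
(more self-similarity) while also raising the chance of coincidental
background hits. Passing tests on this material demonstrate algorithmic
correctness and the claimed comparison-count behaviour, not performance on
any particular genome.

## Benchmarks

Character comparisons, not wall-clock time, are the asserted cost metric:
comparison counts are exactly reproducible for a fixed seed on any machine,
whereas timings are not. Wall-clock seconds are recorded in the output table
for information only. Default grids:

- **budget sweep**: `l_s = 6000`, `l_p = 200`, `è ∈ {0,10,…,50}`;
- **length sweep**: `è = 10`, `l_p = 200`, `l_s` geometric
  `1000…64000` (the sweep values are artifact defaults, chosen to cover
  a 64-fold range in 7 points);
- **preprocessing sweep**: pattern lengths `5000…50000` step 5000,
  failure-table comparisons vs bad-character operations.

Each cell is the mean of 5 replicates on freshly seeded inputs; all
algorithms in a cell see identical input. The summary statistic is the
average-pairwise-slope improvement: average the slopes between consecutive
points of each series, then report
`100·(mean_slow − mean_fast)/mean_slow`. The suite asserts the *direction*
(the optimized matcher's slope undercuts the sliding-window matcher's on the
length sweep, for both alphabets) and the *shape* (comparison counts linear
in `l_s` and in `è`, least-squares `R² ≥ 0.9`); the magnitude of the
improvement is reported in the test log, since it depends on the cost proxy
and alphabet (early abandon makes the window scan cheap on large alphabets,
shrinking the margin).

## Numerical and design choices

- Tie-breaks: hits are sorted by (record order, start); a window is reported
  at most once even if revisited after a rewind.
- `pairwise_slope_improvement` requires identical x-grids with ≥ 2 points
  and a non-zero slow-series mean slope; degenerate inputs raise rather than
  return NaN.
- Derived per-run seeds are folded into `[0, 2^31)` so any stdlib or numpy
  consumer accepts them.
- Whether the error counter should survive a rewind that lands inside a
  previously matched prefix is underdetermined; this implementation clears
  all error state at every rewind (the prefix it resumes under matched
  exactly, so a fresh budget is consistent with the per-alignment
  semantics). Recorded as an assumption; the soundness certification makes
  any consequence visible as reduced recall, never as a false hit.

## Known limitations

- No indel tolerance; an occurrence shifted by a single indel scores as
  mostly mismatched.
- The approximate matcher trades completeness for speed; use
  `hamming_window_search` (CLI `approx --oracle`) when exhaustiveness
  matters more than cost.
- Multi-record FASTA inputs are searched per record; hits never span
  records, and no reverse-complement search is performed.
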