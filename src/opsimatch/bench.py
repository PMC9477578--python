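"""Hardware-independent benchmarking of the matchers.

The asserted cost metric is the character-comparison count, which is exactly
reproducible given a seed; wall-clock seconds are recorded for information
only.  The summary statistic is the average-pairwise-slope improvement: for
two cost-versus-size series on the same grid, average the slopes between
consecutive points of each series and report the percentage by which the
faster algorithm's average slope undercuts the slower one's.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import pandas as pd

from .approx import hamming_window_search, opsi_search
from .baselines import bm_bad_char_table
from .exact import epm_search, naive_search
from .sbarc import InvalidInputError, compute_sbarc
from .synth import random_sequence


@dataclass(frozen=True)
class BenchSeries:
    """(x, cost) points for one algorithm; x strictly increasing, cost the
    mean over replicate runs."""

    label: str
    points: tuple[tuple[float, float], ...]
    repeats: int = 1

    def __post_init__(self) -> None:
        xs = [x for x, _ in self.points]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise InvalidInputError("series x values must be strictly increasing")
        if any(c < 0 for _, c in self.points):
            raise InvalidInputError("costs must be non-negative")


def pairwise_slope_improvement(fast: BenchSeries, slow: BenchSeries) -> float:
    """Percentage improvement of ``fast`` over ``slow`` in average slope.

    For each series the slopes between consecutive points are averaged;
    the result is ``100 * (mean_slow - mean_fast) / mean_slow``.  The grids
    must match exactly and contain at least two points.
    """
    fx = [x for x, _ in fast.points]
    sx = [x for x, _ in slow.points]
    if fx != sx:
        raise InvalidInputError("series must share an identical x grid")
    if len(fx) < 2:
        raise InvalidInputError("need at least two points to form a slope")

    def mean_slope(series: BenchSeries) -> float:
        slopes = [
            (c1 - c0) / (x1 - x0)
            for (x0, c0), (x1, c1) in zip(series.points, series.points[1:])
        ]
        return sum(slopes) / len(slopes)

    ms, mf = mean_slope(slow), mean_slope(fast)
    if ms == 0:
        raise InvalidInputError("slow series has zero average slope; improvement undefined")
    return 100.0 * (ms - mf) / ms


# -- grid configuration -------------------------------------------------------

_SEARCH_ALGORITHMS = {
    "epm": lambda seq, pat, eta: epm_search(seq, pat)[1].char_comparisons,
    "naive": lambda seq, pat, eta: naive_search(seq, pat)[1].char_comparisons,
    "opsi": lambda seq, pat, eta: opsi_search(seq, pat, eta)[1].char_comparisons,
    "hamming": lambda seq, pat, eta: hamming_window_search(seq, pat, eta)[1].char_comparisons,
}
_PREPROC_ALGORITHMS = {
    "sbarc_preproc": lambda pat: compute_sbarc(pat).comparisons,
    "badchar_preproc": lambda pat: bm_bad_char_table(pat).operations,
}


@dataclass(frozen=True)
class BenchGrid:
    """One benchmark sweep: which algorithms, which variable, which values.

    ``sweep`` is one of 'eta', 'length' or 'pattern_length'; the other two
    quantities are held at their fixed values.  Replicates draw fresh seeded
    inputs; all algorithms at a given (value, replicate) see identical input.
    """

    name: str
    algorithms: tuple[str, ...]
    sweep: str
    values: tuple[int, ...]
    length: int = 6000
    pattern_length: int = 200
    eta: int = 10
    alphabet: str = "dna"
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweep not in {"eta", "length", "pattern_length"}:
            raise InvalidInputError(f"unknown sweep variable {self.sweep!r}")
        known = set(_SEARCH_ALGORITHMS) | set(_PREPROC_ALGORITHMS)
        unknown = set(self.algorithms) - known
        if unknown:
            raise InvalidInputError(f"unknown algorithm(s) {sorted(unknown)}; known: {sorted(known)}")
        if len(set(self.values)) != len(self.values) or list(self.values) != sorted(self.values):
            raise InvalidInputError("sweep values must be strictly increasing")


def mismatch_budget_grid(seed: int = 0, alphabet: str = "dna") -> BenchGrid:
    """Budget sweep: 6000 bp sequence, 200 bp pattern, è from 0 to 50 by 10."""
    return BenchGrid(
        name="eta",
        algorithms=("opsi", "hamming"),
        sweep="eta",
        values=(0, 10, 20, 30, 40, 50),
        length=6000,
        pattern_length=200,
        seed=seed,
        alphabet=alphabet,
    )


def sequence_length_grid(seed: int = 0, alphabet: str = "dna") -> BenchGrid:
    """Length sweep at è=10, 200-residue pattern, geometric 1000..64000."""
    return BenchGrid(
        name="length",
        algorithms=("epm", "opsi", "hamming"),
        sweep="length",
        values=(1000, 2000, 4000, 8000, 16000, 32000, 64000),
        eta=10,
        pattern_length=200,
        seed=seed,
        alphabet=alphabet,
    )


def preprocessing_grid(seed: int = 0, alphabet: str = "dna") -> BenchGrid:
    """Preprocessing-cost sweep over pattern lengths 5000..50000."""
    return BenchGrid(
        name="preproc",
        algorithms=("sbarc_preproc", "badchar_preproc"),
        sweep="pattern_length",
        values=tuple(range(5000, 50001, 5000)),
        seed=seed,
        alphabet=alphabet,
    )


DEFAULT_GRIDS = {
    "eta": mismatch_budget_grid,
    "length": sequence_length_grid,
    "preproc": preprocessing_grid,
}


def _derived_seed(base: int, value_index: int, repeat: int, salt: int) -> int:
    return (base * 1_000_003 + value_index * 10_007 + repeat * 101 + salt) % (2**31 - 1)


def run_benchmark(grid: BenchGrid) -> pd.DataFrame:
    """Run the grid and return the mean cost table.

    One row per (algorithm, swept value): columns ``algorithm``, ``x``,
    ``char_comparisons`` (mean over replicates, the asserted metric) and
    ``seconds`` (mean wall-clock, informational).  Bit-reproducible in the
    comparison counts for a fixed grid seed.
    """
    rows = []
    for vi, value in enumerate(grid.values):
        length = value if grid.sweep == "length" else grid.length
        pattern_length = value if grid.sweep == "pattern_length" else grid.pattern_length
        eta = value if grid.sweep == "eta" else grid.eta
        for repeat in range(grid.repeats):
            seq = random_sequence(length, grid.alphabet, _derived_seed(grid.seed, vi, repeat, 1))
            pat = random_sequence(pattern_length, grid.alphabet, _derived_seed(grid.seed, vi, repeat, 2)).residues
            for name in grid.algorithms:
                t0 = time.perf_counter()
                if name in _PREPROC_ALGORITHMS:
                    cost = _PREPROC_ALGORITHMS[name](pat)
                else:
                    cost = _SEARCH_ALGORITHMS[name](seq, pat, eta)
                elapsed = time.perf_counter() - t0
                rows.append(
                    {"algorithm": name, "x": value, "repeat": repeat,
                     "char_comparisons": cost, "seconds": elapsed}
                )
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["algorithm", "x"], as_index=False)[["char_comparisons", "seconds"]]
        .mean()
        .sort_values(["algorithm", "x"], ignore_index=True)
    )
    out["repeats"] = grid.repeats
    return out


def series_from_table(table: pd.DataFrame, algorithm: str) -> BenchSeries:
    """Extract one algorithm's (x, char_comparisons) series from a benchmark table."""
    sub = table[table["algorithm"] == algorithm].sort_values("x")
    if sub.empty:
        raise InvalidInputError(f"no rows for algorithm {algorithm!r}")
    points = tuple(zip(sub["x"].tolist(), sub["char_comparisons"].tolist()))
    repeats = int(sub["repeats"].iloc[0]) if "repeats" in sub else 1
    return BenchSeries(algorithm, points, repeats)
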