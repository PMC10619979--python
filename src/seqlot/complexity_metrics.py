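"""Alternative sequence-complexity metrics.

Five competitor measures used alongside the minimal-description-length
complexity in the behavioral model comparison: transition-pair entropy,
Lempel-Ziv (LZ76) phrase count, number of subsymmetries, run/chunk
complexity, and change complexity.  All operate on item strings over
``{A, B}`` and are invariant to a global A/B relabeling.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict

from .mdl_search import CostSchedule, SearchLimits, lot_complexity, run_lengths

__all__ = [
    "UndefinedMetricError",
    "transition_entropy",
    "lempel_ziv",
    "subsymmetries",
    "chunk_complexity",
    "change_complexity",
    "metric_vector",
    "METRIC_NAMES",
]

METRIC_NAMES = ("lot", "entropy", "lempel_ziv", "subsymmetries", "chunk", "change")


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given sequence length."""


def _check(seq: str, min_len: int, name: str) -> None:
    if any(ch not in "AB" for ch in seq):
        raise ValueError("sequence must be a string over {A, B}")
    if len(seq) < min_len:
        raise UndefinedMetricError(f"{name} requires length >= {min_len}")


def transition_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the empirical distribution of the N-1
    ordered adjacent pairs over {AA, AB, BA, BB}."""
    _check(seq, 2, "transition_entropy")
    counts = Counter(zip(seq, seq[1:]))
    total = len(seq) - 1
    entropy = -sum(
        (c / total) * math.log2(c / total) for c in counts.values() if c > 0
    )
    return entropy + 0.0  # avoid negative zero for single-category inputs


def lempel_ziv(seq: str) -> int:
    """LZ76 complexity: number of phrases in the exhaustive-history
    parsing, the final (possibly non-novel) phrase included."""
    _check(seq, 1, "lempel_ziv")
    n = len(seq)
    phrases = 0
    i = 0
    while i < n:
        # longest prefix of seq[i:] occurring in seq with a start < i
        length = 1
        while i + length < n and seq[: i + length].find(seq[i : i + length + 1]) != -1:
            length += 1
        phrases += 1
        i += length
    return phrases


def subsymmetries(seq: str, min_length: int = 2) -> int:
    """Number of contiguous palindromic substrings of length >= ``min_length``
    (length-1 substrings are trivially symmetric and excluded by default)."""
    _check(seq, 2, "subsymmetries")
    n = len(seq)
    count = 0
    # expand around each center
    for center in range(2 * n - 1):
        lo, hi = center // 2, (center + 1) // 2
        while lo >= 0 and hi < n and seq[lo] == seq[hi]:
            if hi - lo + 1 >= min_length:
                count += 1
            lo -= 1
            hi += 1
    return count


def chunk_complexity(seq: str, weight=None) -> float:
    """Runs weighted by their length: sum over maximal runs of
    ``weight(run length)``; the default weight ``1 + digits(l)`` mirrors
    the MDL charge for an encoded repetition count."""
    _check(seq, 1, "chunk_complexity")
    if weight is None:
        weight = lambda l: 1.0 + len(str(l))
    return float(sum(weight(l) for l in run_lengths(seq)))


def change_complexity(seq: str) -> float:
    """Average amount of change over all contiguous windows: the mean, over
    windows of length >= 2, of the fraction of adjacent item pairs within
    the window that differ."""
    _check(seq, 2, "change_complexity")
    n = len(seq)
    diffs = [1 if a != b else 0 for a, b in zip(seq, seq[1:])]
    prefix = [0]
    for d in diffs:
        prefix.append(prefix[-1] + d)
    total = 0.0
    n_windows = 0
    for length in range(2, n + 1):
        for start in range(0, n - length + 1):
            changes = prefix[start + length - 1] - prefix[start]
            total += changes / (length - 1)
            n_windows += 1
    return total / n_windows


def metric_vector(
    seq: str,
    schedule: CostSchedule = CostSchedule(),
    limits: SearchLimits = SearchLimits(),
) -> Dict[str, float]:
    """All six complexity values for one sequence, keyed by metric name."""
    return {
        "lot": lot_complexity(seq, schedule, limits).complexity,
        "entropy": transition_entropy(seq),
        "lempel_ziv": float(lempel_ziv(seq)),
        "subsymmetries": float(subsymmetries(seq)),
        "chunk": chunk_complexity(seq),
        "change": change_complexity(seq),
    }
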