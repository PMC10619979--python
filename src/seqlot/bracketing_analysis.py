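"""Segmentation (bracketing) productions versus model predictions.

Participants mark how they group a sequence by drawing opening/closing
brackets between items; counting brackets at each of the N+1 inter-item
intervals yields a production vector (length 17 for 16 items).  The
group-averaged vector is correlated with (a) the bracket profile implied
by the sequence's minimal program and (b) the pooled transition-surprise
profile, which places boundaries at rare transitions instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import lot_language as lot
from .experiment_design import SequenceRecord
from .transition_observer import (
    DegenerateSurpriseError,
    asymptotic_transition_surprise,
)

__all__ = [
    "aggregate_brackets",
    "CorrelationResult",
    "lot_correlation",
    "surprise_correlation",
    "correlation_table",
]


def aggregate_brackets(productions: Sequence[Sequence[float]]) -> np.ndarray:
    """Element-wise mean of per-subject bracket-count vectors (all the
    same length)."""
    arrays = [np.asarray(p, dtype=float) for p in productions]
    if not arrays:
        raise ValueError("no productions")
    lengths = {a.shape for a in arrays}
    if len(lengths) != 1 or arrays[0].ndim != 1:
        raise ValueError("productions must be 1-D vectors of equal length")
    return np.mean(arrays, axis=0)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    degenerate: bool
    template: Optional[str] = None  # which equivalent encoding was used

    @property
    def defined(self) -> bool:
        return not self.degenerate


def _pearson(observed: np.ndarray, predicted: np.ndarray) -> CorrelationResult:
    if np.allclose(observed, observed[0]) or np.allclose(predicted, predicted[0]):
        return CorrelationResult(np.nan, np.nan, degenerate=True)
    r, p = stats.pearsonr(observed, predicted)
    return CorrelationResult(float(r), float(p), degenerate=False)


def _itemwise_template(n_items: int) -> np.ndarray:
    """The '[A][A][A]...' style production: every item individually
    bracketed (plus the whole-sequence group)."""
    counts = np.full(n_items + 1, 2.0)
    return counts


def lot_correlation(
    observed: Sequence[float], record: SequenceRecord
) -> CorrelationResult:
    """Pearson correlation between a (group-mean) production vector and
    the bracket profile of the sequence's minimal program.

    For the pure repetition and alternation sequences the single-group and
    item-wise encodings are equivalent descriptions; each non-degenerate
    equivalent is tried and the better-correlating one reported, with the
    chosen template named in the result.
    """
    observed = np.asarray(observed, dtype=float)
    n = len(record.items)
    if observed.shape != (n + 1,):
        raise ValueError(f"expected a vector of length {n + 1}")
    templates: Dict[str, np.ndarray] = {
        "minimal": np.asarray(
            lot.bracket_prediction(record.lot_expr, n), dtype=float
        )
    }
    if record.name in ("Repeat", "Alternate"):
        templates["itemwise"] = _itemwise_template(n)
    best: Optional[CorrelationResult] = None
    for name, template in templates.items():
        res = _pearson(observed, template)
        if res.degenerate:
            continue
        if best is None or res.r > best.r:
            best = CorrelationResult(res.r, res.p_value, False, template=name)
    if best is None:
        return CorrelationResult(np.nan, np.nan, degenerate=True)
    return best


def surprise_correlation(
    observed: Sequence[float], record: SequenceRecord
) -> CorrelationResult:
    """Correlation of interior bracket counts (intervals 1..N-1) with the
    pooled transition-surprise profile of the N-1 transitions; degenerate
    for sequences whose transitions are all equally predictable."""
    observed = np.asarray(observed, dtype=float)
    n = len(record.items)
    if observed.shape != (n + 1,):
        raise ValueError(f"expected a vector of length {n + 1}")
    try:
        surprise = asymptotic_transition_surprise(record.items)
    except DegenerateSurpriseError:
        return CorrelationResult(np.nan, np.nan, degenerate=True)
    interior = observed[1:n]
    res = _pearson(interior, surprise)
    return CorrelationResult(res.r, res.p_value, res.degenerate, template="surprise")


def correlation_table(
    productions: pd.DataFrame, roster: Sequence[SequenceRecord]
) -> pd.DataFrame:
    """Per-sequence summary of both correlations from a tidy production
    table (columns subject, sequence, interval, count)."""
    rows: List[dict] = []
    by_name = {r.name: r for r in roster}
    for sequence, group in productions.groupby("sequence"):
        record = by_name[sequence]
        wide = group.pivot_table(
            index="subject", columns="interval", values="count"
        ).to_numpy()
        mean_vec = wide.mean(axis=0)
        lot_res = lot_correlation(mean_vec, record)
        sur_res = surprise_correlation(mean_vec, record)
        rows.append(
            {
                "sequence": sequence,
                "lot_r": lot_res.r,
                "lot_p": lot_res.p_value,
                "lot_template": lot_res.template,
                "surprise_r": sur_res.r,
                "surprise_p": sur_res.p_value,
                "surprise_degenerate": sur_res.degenerate,
            }
        )
    return pd.DataFrame(rows)
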