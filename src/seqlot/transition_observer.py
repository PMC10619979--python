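"""Ideal Bayesian observer of first-order transition probabilities.

The observer tracks leaky counts of the four transitions AA, AB, BA, BB.
Each incoming item first decays all counts by ``exp(-1/omega)`` (an
exponential memory over ``omega`` items, default 100), then increments the
count of the observed transition.  Predictions are posterior means under
independent Beta(alpha, beta) priors on each transition row; surprise is
the negative log2 predicted probability of the item actually observed.

Besides the per-item streaming observer, the module derives the regressors
used downstream: repetition/alternation indicators and surprise at the
current and next item for sensor-level regressions, per-block average
deviant surprise for the behavioral models, and the no-decay pooled
("asymptotic") per-transition surprise used by the bracketing analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np

__all__ = [
    "ObserverConfig",
    "ObserverState",
    "SurpriseTrace",
    "fresh_state",
    "observe",
    "predict",
    "surprise_trace",
    "meg_regressors",
    "deviant_block_surprise",
    "asymptotic_transition_surprise",
    "DegenerateSurpriseError",
]

_ITEMS = ("A", "B")


class DegenerateSurpriseError(ValueError):
    """All transitions of a sequence are equally predictable: the surprise
    profile is constant and correlations with it are undefined."""


@dataclass(frozen=True)
class ObserverConfig:
    """``decay_window`` is the exponential memory constant in items
    (``None`` disables decay, i.e. a perfect integrator); ``alpha``/``beta``
    are the prior pseudo-counts of each transition row."""

    decay_window: Optional[float] = 100.0
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.decay_window is not None and self.decay_window <= 0:
            raise ValueError("decay_window must be positive (or None)")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("prior pseudo-counts must be positive")

    @property
    def decay_factor(self) -> float:
        if self.decay_window is None:
            return 1.0
        return math.exp(-1.0 / self.decay_window)


@dataclass(frozen=True)
class ObserverState:
    """Leaky transition counts plus the last item seen."""

    counts: dict = field(
        default_factory=lambda: {(x, y): 0.0 for x in _ITEMS for y in _ITEMS}
    )
    last_item: Optional[str] = None
    n_observed: int = 0


def fresh_state() -> ObserverState:
    return ObserverState()


def observe(state: ObserverState, config: ObserverConfig, item: str) -> ObserverState:
    """Decay all counts, then credit the transition (last item -> item)."""
    if item not in _ITEMS:
        raise ValueError(f"item must be 'A' or 'B', got {item!r}")
    rho = config.decay_factor
    counts = {k: v * rho for k, v in state.counts.items()}
    if state.last_item is not None:
        counts[(state.last_item, item)] += 1.0
    return ObserverState(counts=counts, last_item=item, n_observed=state.n_observed + 1)


def predict(state: ObserverState, config: ObserverConfig, next_item: str) -> float:
    """Posterior-mean probability of ``next_item`` given the current state;
    1/2 when no item has been seen yet (no transition context)."""
    if next_item not in _ITEMS:
        raise ValueError(f"item must be 'A' or 'B', got {next_item!r}")
    x = state.last_item
    if x is None:
        return 0.5
    row = state.counts[(x, "A")] + state.counts[(x, "B")]
    return (state.counts[(x, next_item)] + config.alpha) / (
        row + config.alpha + config.beta
    )


@dataclass(frozen=True)
class SurpriseTrace:
    probability: np.ndarray  # predicted probability of each observed item
    surprise: np.ndarray  # -log2(probability), bits
    repetition: np.ndarray  # 1 if item repeats its predecessor; NaN at pos 1
    final_state: ObserverState


def surprise_trace(
    items: Iterable[str], config: ObserverConfig = ObserverConfig(),
    state: Optional[ObserverState] = None,
) -> SurpriseTrace:
    """Sequentially observe ``items``; at each position record the
    predict-before-observe probability of the item that then occurs.

    An initial ``state`` allows traces to continue across trials of a
    block, as when surprise is accumulated within an experimental block.
    """
    if state is None:
        state = fresh_state()
    probs: List[float] = []
    reps: List[float] = []
    for item in items:
        probs.append(predict(state, config, item))
        reps.append(
            float(item == state.last_item) if state.last_item is not None else np.nan
        )
        state = observe(state, config, item)
    probability = np.asarray(probs, dtype=float)
    return SurpriseTrace(
        probability=probability,
        surprise=-np.log2(probability),
        repetition=np.asarray(reps, dtype=float),
        final_state=state,
    )


def meg_regressors(
    items: Sequence[str], config: ObserverConfig = ObserverConfig(),
    state: Optional[ObserverState] = None,
):
    """Per-position design columns for sensor-level regressions: the
    repetition indicator and the observer surprise, each for the item at
    the current position and for the next item (one stimulus-onset
    asynchrony later).  Edges without a defined value carry NaN.

    Returns a dict of four equal-length float arrays:
    ``repetition``, ``surprise``, ``repetition_next``, ``surprise_next``.
    """
    trace = surprise_trace(items, config, state=state)
    n = len(trace.surprise)
    rep_next = np.full(n, np.nan)
    sur_next = np.full(n, np.nan)
    if n > 1:
        rep_next[:-1] = trace.repetition[1:]
        sur_next[:-1] = trace.surprise[1:]
    return {
        "repetition": trace.repetition,
        "surprise": trace.surprise,
        "repetition_next": rep_next,
        "surprise_next": sur_next,
    }


def deviant_block_surprise(
    deviant_surprises: Sequence[float],
    detected: Optional[Sequence[bool]] = None,
    detected_only: bool = False,
) -> float:
    """Average observer surprise of a block's deviant items; with
    ``detected_only``, only correctly detected deviants contribute (the
    response-time model's convention).  NaN when nothing qualifies."""
    values = np.asarray(deviant_surprises, dtype=float)
    if detected_only:
        if detected is None:
            raise ValueError("detected flags required when detected_only=True")
        mask = np.asarray(detected, dtype=bool)
        values = values[mask]
    if values.size == 0:
        return float("nan")
    return float(np.mean(values))


def asymptotic_transition_surprise(seq: str) -> np.ndarray:
    """Surprise of each of the N-1 transitions under transition
    probabilities estimated by pooling the sequence's own transition counts
    (no decay, no prior): an observer that has fully learned the sequence.

    Raises :class:`DegenerateSurpriseError` when the profile is constant
    (e.g. pure repetition or pure alternation sequences, where every
    transition is fully predictable).
    """
    if len(seq) < 2 or any(ch not in "AB" for ch in seq):
        raise ValueError("need a sequence of length >= 2 over {A, B}")
    counts = {(x, y): 0 for x in _ITEMS for y in _ITEMS}
    for x, y in zip(seq, seq[1:]):
        counts[(x, y)] += 1
    surprises = []
    for x, y in zip(seq, seq[1:]):
        row = counts[(x, "A")] + counts[(x, "B")]
        p = counts[(x, y)] / row
        surprises.append(-math.log2(p))
    out = np.asarray(surprises, dtype=float)
    if np.allclose(out, out[0]):
        raise DegenerateSurpriseError(
            "all transitions equally predictable; surprise profile is constant"
        )
    return out
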