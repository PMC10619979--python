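"""Sequence roster and trial-stream generation.

The experiments present 16-item binary tone sequences in mini-sessions: a
habituation phase (10 unviolated trials) followed by a test phase in which
some trials contain a single *deviant* — one tone replaced by the other —
at one of four sequence-specific positions between 9 and 15.  The deviant
detection (fMRI-style) design uses 18 test trials, one third deviant, with
button responses; the passive-listening (MEG-style) design uses 36 test
trials, two thirds deviant, and no responses.  Tones last 50 ms at a fixed
250 ms onset asynchrony, so a trial spans 4000 ms, with 500 ms between
trials.  Every sequence is presented in two versions related by swapping
the two tones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import lot_language as lot
from .complexity_metrics import metric_vector
from .mdl_search import CostSchedule, MdlResult, SearchLimits, lot_complexity

__all__ = [
    "SEQUENCE_LENGTH",
    "BUILTIN_SEQUENCES",
    "SYNTHETIC_SEQUENCES",
    "MEG_EXCLUDED",
    "ROSTER_ORDER",
    "SequenceRecord",
    "DesignSpec",
    "FMRI_DESIGN",
    "MEG_DESIGN",
    "RosterError",
    "build_record",
    "default_roster",
    "bundled_roster",
    "make_mini_session",
]

SEQUENCE_LENGTH = 16

#: The five sequences whose item strings the experimental literature spells
#: out in text: repetition, alternation, pairs, quadruplets, and the nested
#: pairs-then-alternations pattern.
BUILTIN_SEQUENCES: Dict[str, str] = {
    "Repeat": "A" * 16,
    "Alternate": "AB" * 8,
    "Pairs": "AABB" * 4,
    "Quadruplets": "AAAABBBB" * 2,
    "Pairs&Alt.1": "AABBABABAABBABAB",
}

#: Synthetic stand-ins for the five roster sequences whose item strings are
#: published only in figure form.  Chosen at design time to respect each
#: name's motif (shrinking runs; alternation/pair nesting; runs of three and
#: two; a mirror-symmetric layout; a balanced, maximally incompressible
#: control) and to realize the documented complexity hierarchy: complexity
#: is non-decreasing along ROSTER_ORDER and strictly maximal for Complex,
#: which was selected as the highest-MDL length-16 string with runs <= 3 and
#: near-balanced transition counts.
SYNTHETIC_SEQUENCES: Dict[str, str] = {
    "Shrinking": "AAAABBAABBABABAB",
    "Pairs&Alt.2": "AABBABABABABAABB",
    "ThreeTwo": "AAABBBAABBAAABBB",
    "CenterMirror": "AABABBABBABBABAA",
    "Complex": "AAABAAABBABAAABA",
}

ROSTER_ORDER: Tuple[str, ...] = (
    "Repeat",
    "Alternate",
    "Pairs",
    "Quadruplets",
    "Pairs&Alt.1",
    "Shrinking",
    "Pairs&Alt.2",
    "ThreeTwo",
    "CenterMirror",
    "Complex",
)

#: Sequences presented only in the deviant-detection experiment.
MEG_EXCLUDED: Tuple[str, ...] = ("Pairs&Alt.2", "ThreeTwo", "CenterMirror")


class RosterError(ValueError):
    """Missing or malformed roster configuration."""


@dataclass(frozen=True)
class SequenceRecord:
    name: str
    items: str
    lot_result: MdlResult
    deviant_positions: Tuple[int, ...]
    metrics: Dict[str, float]

    @property
    def complexity(self) -> float:
        return self.lot_result.complexity

    @property
    def lot_expr(self):
        return self.lot_result.argmin_expr


@dataclass(frozen=True)
class DesignSpec:
    """Counts and timing of one mini-session."""

    modality: str  # "fmri" or "meg"
    n_habituation: int = 10
    n_test: int = 18
    deviant_fraction: float = 1.0 / 3.0
    soa_ms: float = 250.0
    tone_ms: float = 50.0
    iti_ms: float = 500.0
    response_window_ms: Tuple[float, float] = (200.0, 2500.0)
    habituation_blocks: Tuple[int, ...] = (5, 5)
    test_blocks: Tuple[int, ...] = (6, 6, 6)
    rest_s: float = 6.0
    rest_jitter_s: float = 1.5

    @property
    def n_deviant(self) -> int:
        return round(self.deviant_fraction * self.n_test)

    @property
    def trial_ms(self) -> float:
        return SEQUENCE_LENGTH * self.soa_ms

    @property
    def n_trials(self) -> int:
        return self.n_habituation + self.n_test


FMRI_DESIGN = DesignSpec(modality="fmri")
MEG_DESIGN = DesignSpec(
    modality="meg",
    n_test=36,
    deviant_fraction=2.0 / 3.0,
    habituation_blocks=(10,),
    test_blocks=(36,),
)


def _default_deviant_positions(name: str) -> Tuple[int, ...]:
    """Four reproducible deviant positions in 9..15, derived from a stable
    hash of the sequence name (used when the roster config gives none)."""
    digest = hashlib.sha256(name.encode("utf8")).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:4], "little"))
    return tuple(sorted(rng.choice(np.arange(9, 16), size=4, replace=False).tolist()))


def build_record(
    name: str,
    items: str,
    deviant_positions: Optional[Sequence[int]] = None,
    schedule: CostSchedule = CostSchedule(),
    limits: SearchLimits = SearchLimits(),
) -> SequenceRecord:
    if len(items) != SEQUENCE_LENGTH or any(ch not in "AB" for ch in items):
        raise RosterError(
            f"sequence {name!r}: items must be a length-16 string over {{A, B}}"
        )
    if deviant_positions is None:
        deviant_positions = _default_deviant_positions(name)
    positions = tuple(sorted(int(p) for p in deviant_positions))
    if len(positions) != 4 or any(not 9 <= p <= 15 for p in positions):
        raise RosterError(
            f"sequence {name!r}: need exactly 4 deviant positions in 9..15"
        )
    return SequenceRecord(
        name=name,
        items=items,
        lot_result=lot_complexity(items, schedule, limits),
        deviant_positions=positions,
        metrics=metric_vector(items, schedule, limits),
    )


def default_roster(
    config: Optional[Dict[str, dict]] = None,
    modality: str = "fmri",
    schedule: CostSchedule = CostSchedule(),
    limits: SearchLimits = SearchLimits(),
) -> List[SequenceRecord]:
    """The experiment's 10-sequence roster (7 for the passive-listening
    modality).  The five text-attested sequences are built in; the
    remaining five must be supplied in ``config`` as
    ``{name: {"items": str, "deviant_positions": [4 ints]}}`` — see
    :func:`bundled_roster` for a ready-made synthetic completion.
    """
    config = dict(config or {})
    names = [n for n in ROSTER_ORDER if modality != "meg" or n not in MEG_EXCLUDED]
    missing = [
        n for n in names if n not in BUILTIN_SEQUENCES and n not in config
    ]
    if missing:
        raise RosterError(
            "roster config must supply item strings for: " + ", ".join(missing)
        )
    records = []
    for name in names:
        entry = config.get(name, {})
        items = entry.get("items", BUILTIN_SEQUENCES.get(name))
        positions = entry.get("deviant_positions")
        records.append(build_record(name, items, positions, schedule, limits))
    return records


def bundled_roster(
    modality: str = "fmri",
    schedule: CostSchedule = CostSchedule(),
    limits: SearchLimits = SearchLimits(),
) -> List[SequenceRecord]:
    """Full roster completed with the bundled synthetic stand-in sequences."""
    config = {name: {"items": items} for name, items in SYNTHETIC_SEQUENCES.items()}
    return default_roster(config, modality, schedule, limits)


def make_mini_session(
    record: SequenceRecord,
    version: str,
    spec: DesignSpec,
    seed: int,
) -> pd.DataFrame:
    """One mini-session trial stream as a tidy table (one row per item).

    Habituation trials come first; deviant test trials are placed in random
    order within the test phase, their positions drawn uniformly from the
    record's four deviant positions.  Version "B" swaps the two tones.
    Columns: trial, block, phase, trial_type, position (1-based), item,
    onset_ms (relative to session start), is_deviant, deviant_position.
    """
    if version not in ("A", "B"):
        raise ValueError("version must be 'A' or 'B'")
    if sum(spec.habituation_blocks) != spec.n_habituation:
        raise ValueError("habituation blocks do not sum to n_habituation")
    if sum(spec.test_blocks) != spec.n_test:
        raise ValueError("test blocks do not sum to n_test")
    rng = np.random.default_rng(seed)
    items = record.items if version == "A" else lot.flip_sequence(record.items)

    # trial roles
    n_dev = spec.n_deviant
    roles = ["deviant"] * n_dev + ["standard"] * (spec.n_test - n_dev)
    rng.shuffle(roles)
    dev_positions = rng.choice(record.deviant_positions, size=n_dev, replace=True)

    block_of_trial: List[int] = []
    for b, size in enumerate(list(spec.habituation_blocks) + list(spec.test_blocks)):
        block_of_trial.extend([b] * size)

    rows = []
    onset = 0.0
    dev_iter = iter(dev_positions)
    for t in range(spec.n_trials):
        if t < spec.n_habituation:
            phase, ttype, dev_pos = "habituation", "habituation", None
        else:
            ttype = roles[t - spec.n_habituation]
            phase = "test"
            dev_pos = int(next(dev_iter)) if ttype == "deviant" else None
        trial_items = list(items)
        if dev_pos is not None:
            trial_items[dev_pos - 1] = lot.flip_item(trial_items[dev_pos - 1])
        for pos, item in enumerate(trial_items, start=1):
            rows.append(
                {
                    "trial": t + 1,
                    "block": block_of_trial[t] + 1,
                    "phase": phase,
                    "trial_type": ttype,
                    "position": pos,
                    "item": item,
                    "onset_ms": onset + (pos - 1) * spec.soa_ms,
                    "is_deviant": dev_pos == pos,
                    "deviant_position": dev_pos,
                }
            )
        onset += spec.trial_ms + spec.iti_ms
    frame = pd.DataFrame(rows)
    frame.attrs["sequence"] = record.name
    frame.attrs["version"] = version
    frame.attrs["modality"] = spec.modality
    return frame
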