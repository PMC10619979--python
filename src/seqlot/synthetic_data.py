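"""Synthetic datasets with the statistical structure the analyses assume.

Three generators emulate the study designs so that every downstream
analysis stage can be exercised and validated without any recordings:

* :func:`simulate_behavior` — deviant-detection trials whose latent
  sensitivity and response times are linear in sequence complexity, the
  published group-level estimates serving as the generating parameters;
* :func:`simulate_bracketing` — per-subject segmentation (bracket count)
  vectors derived noisily from each sequence's predicted grouping;
* :func:`simulate_evoked` — multi-sensor epochs in which the evoked
  amplitude scales positively with complexity during habituation and the
  deviant mismatch response scales negatively with complexity.

All generators are pure functions of (parameters, seed); seeds are split
through ``numpy.random.SeedSequence`` so stages are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats

from . import lot_language as lot
from .experiment_design import (
    FMRI_DESIGN,
    DesignSpec,
    SequenceRecord,
    make_mini_session,
)
from .transition_observer import ObserverConfig, surprise_trace

__all__ = [
    "BehaviorSimParams",
    "BracketSimParams",
    "EvokedSimParams",
    "EvokedEpochs",
    "simulate_behavior",
    "simulate_bracketing",
    "simulate_evoked",
    "alternate_pairs_template",
]


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorSimParams:
    """Ground-truth parameters of the behavioral generator.

    Latent sensitivity follows d' = ``dprime_intercept + dprime_slope * C``
    plus a subject intercept, on the scale of the log-linear d' estimator
    with a subject-pooled false-alarm rate (the scale on which the group
    coefficients were fitted).  Responding uses a fixed criterion, so
    false alarms are rare and shared across sequences; per-cell hit
    probabilities are obtained by numerically inverting the expectation of
    the estimator, which makes the estimator unbiased for the latent
    linear model by construction.  Correct detections get a response time
    ``rt_intercept + rt_slope * C`` plus subject and trial noise,
    truncated to the response window (the noise defaults keep the
    truncation rarely binding).  Optional surprise slopes add an effect of
    the observer's deviant surprise, for testing whether model comparison
    can identify generators that also track transition probabilities.
    """

    n_subjects: int = 23
    dprime_intercept: float = 3.39
    dprime_slope: float = -0.092
    rt_intercept_ms: float = 475.4
    rt_slope_ms: float = 17.4
    dprime_subject_sd: float = 0.4
    rt_subject_sd_ms: float = 80.0
    rt_residual_sd_ms: float = 120.0
    criterion: float = 1.645  # fixed response criterion; FA rate = Phi(-c)
    false_alarm_rate: Optional[float] = None  # overrides Phi(-criterion)
    dprime_surprise_slope: float = 0.0
    rt_surprise_slope_ms: float = 0.0
    observer: ObserverConfig = field(default_factory=ObserverConfig)


def _loglinear_probit_expectation(p: float, n: int) -> float:
    """E[Phi^-1((X + 0.5) / (n + 1))] for X ~ Binomial(n, p): the mean of
    the log-linear-adjusted probit of an observed proportion."""
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p)
    return float(np.sum(pmf * stats.norm.ppf((k + 0.5) / (n + 1))))


def _invert_hit_link(target: float, n: int) -> float:
    """Hit probability whose log-linear probit expectation equals
    ``target`` (clipped to the range attainable with n trials)."""
    lo_p, hi_p = 1e-9, 1.0 - 1e-9
    lo, hi = (
        _loglinear_probit_expectation(lo_p, n),
        _loglinear_probit_expectation(hi_p, n),
    )
    if target <= lo:
        return lo_p
    if target >= hi:
        return hi_p
    from scipy.optimize import brentq

    return float(
        brentq(
            lambda p: _loglinear_probit_expectation(p, n) - target, lo_p, hi_p,
            xtol=1e-10,
        )
    )


def _block_deviant_surprise(
    stream: pd.DataFrame, observer: ObserverConfig
) -> pd.Series:
    """Observer surprise of each deviant item, accumulated over the whole
    mini-session item stream (indexed like the deviant rows of ``stream``)."""
    trace = surprise_trace(stream["item"].tolist(), observer)
    mask = stream["is_deviant"].to_numpy()
    return pd.Series(trace.surprise[mask], index=stream.index[mask])


def simulate_behavior(
    params: BehaviorSimParams,
    roster: Sequence[SequenceRecord],
    spec: DesignSpec = FMRI_DESIGN,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial-level deviant-detection table.

    One row per test trial and (subject, sequence, version): columns
    ``subject, sequence, complexity, version, trial, trial_type,
    deviant_position, surprise, latent_dprime, response, rt_ms,
    press_time_ms``.  ``response`` marks a button press (hit on deviant
    trials, false alarm on standards); press times are absolute within the
    mini-session so the scoring stage can be run end-to-end.
    """
    if not roster:
        raise ValueError("empty roster")
    root = np.random.SeedSequence(seed)
    subj_ss, trial_ss = root.spawn(2)
    rng_subj = np.random.default_rng(subj_ss)
    u = rng_subj.normal(0.0, params.dprime_subject_sd, params.n_subjects)
    v = rng_subj.normal(0.0, params.rt_subject_sd_ms, params.n_subjects)
    rng = np.random.default_rng(trial_ss)
    lo, hi = spec.response_window_ms

    # Deviant placement inside mini-sessions is itself seeded data; reuse
    # one stream per (sequence, version) across subjects for the surprise
    # regressor would tie subjects together, so streams are per subject.
    p_fa = (
        params.false_alarm_rate
        if params.false_alarm_rate is not None
        else float(stats.norm.cdf(-params.criterion))
    )
    n_signal = 2 * spec.n_deviant  # both versions feed one d' cell
    n_noise = 2 * (spec.n_test - spec.n_deviant) * len(roster)  # subject pool
    fa_probit = _loglinear_probit_expectation(p_fa, n_noise)

    rows: List[dict] = []
    for s in range(params.n_subjects):
        for record in roster:
            # streams (and their deviant surprises) for both versions first,
            # since sensitivity is a property of the (subject, sequence) cell
            streams = {}
            surprises = {}
            for version in ("A", "B"):
                stream_seed = int(rng.integers(0, 2**31 - 1))
                stream = make_mini_session(record, version, spec, stream_seed)
                dev_surprise = _block_deviant_surprise(stream, params.observer)
                streams[version] = stream
                surprises[version] = dict(
                    zip(stream.loc[dev_surprise.index, "trial"], dev_surprise)
                )
            block_mean_surprise = float(
                np.mean([v for d in surprises.values() for v in d.values()])
            )
            latent_d = (
                params.dprime_intercept
                + params.dprime_slope * record.complexity
                + params.dprime_surprise_slope * block_mean_surprise
                + u[s]
            )
            p_hit = _invert_hit_link(latent_d + fa_probit, n_signal)

            for version in ("A", "B"):
                stream = streams[version]
                trial_info = (
                    stream.drop_duplicates("trial").set_index("trial").sort_index()
                )
                trial_surprise = surprises[version]

                for trial, info in trial_info.iterrows():
                    if info["phase"] != "test":
                        continue
                    trial_onset = float(info["onset_ms"])
                    is_dev = info["trial_type"] == "deviant"
                    surprise = trial_surprise.get(trial, np.nan)
                    response = False
                    rt = np.nan
                    press = np.nan
                    if is_dev:
                        response = bool(rng.random() < p_hit)
                        if response:
                            mean_rt = (
                                params.rt_intercept_ms
                                + params.rt_slope_ms * record.complexity
                                + params.rt_surprise_slope_ms * surprise
                                + v[s]
                            )
                            a = (lo - mean_rt) / params.rt_residual_sd_ms
                            b = (hi - mean_rt) / params.rt_residual_sd_ms
                            rt = float(
                                stats.truncnorm.rvs(
                                    a, b, loc=mean_rt,
                                    scale=params.rt_residual_sd_ms,
                                    random_state=rng,
                                )
                            )
                            dev_onset = trial_onset + (
                                int(info["deviant_position"]) - 1
                            ) * spec.soa_ms
                            press = dev_onset + rt
                    else:
                        response = bool(rng.random() < p_fa)
                        if response:
                            # late in the trial, outside any deviant window
                            press = trial_onset + 3900.0
                    rows.append(
                        {
                            "subject": s,
                            "sequence": record.name,
                            "complexity": record.complexity,
                            "version": version,
                            "trial": int(trial),
                            "trial_type": info["trial_type"],
                            "deviant_position": info["deviant_position"],
                            "surprise": surprise,
                            "block_mean_surprise": block_mean_surprise,
                            "latent_dprime": latent_d,
                            "response": response,
                            "rt_ms": rt,
                            "press_time_ms": press,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bracketing
# ---------------------------------------------------------------------------


def alternate_pairs_template(n_items: int = 16) -> np.ndarray:
    """Bracket profile of the 'groups of two' parse of the alternation
    sequence (e.g. eight AB pairs for 16 items)."""
    expr = lot.Repeat(lot.Concat((lot.Primitive(lot.STAY), lot.Primitive(lot.CHANGE))), n_items // 2)
    return np.asarray(lot.bracket_prediction(expr, n_items), dtype=float)


@dataclass(frozen=True)
class BracketSimParams:
    """``emit_probability`` is the chance each predicted bracket is actually
    drawn; ``noise_rate`` adds spurious brackets (Poisson per interval);
    ``alternate_pairs_fraction`` is the share of subjects who segment the
    alternation sequence into two-item groups instead of one 16-item group.
    """

    n_subjects: int = 42
    emit_probability: float = 0.9
    noise_rate: float = 0.1
    alternate_pairs_fraction: float = 0.5


def simulate_bracketing(
    params: BracketSimParams,
    roster: Sequence[SequenceRecord],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject bracket-count vectors, tidy: one row per (subject,
    sequence, interval 0..N)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows: List[dict] = []
    for record in roster:
        n = len(record.items)
        template = np.asarray(
            lot.bracket_prediction(record.lot_expr, n), dtype=float
        )
        pairs = alternate_pairs_template(n)
        for s in range(params.n_subjects):
            base = template
            if record.name == "Alternate" and rng.random() < params.alternate_pairs_fraction:
                base = pairs
            counts = rng.binomial(
                base.astype(int), params.emit_probability
            ) + rng.poisson(params.noise_rate, size=n + 1)
            for interval, c in enumerate(counts):
                rows.append(
                    {
                        "subject": s,
                        "sequence": record.name,
                        "interval": interval,
                        "count": int(c),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evoked sensor-level epochs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvokedSimParams:
    """Amplitudes are in arbitrary sensor units; gains are per MDL unit.

    The habituation/standard response carries a complexity-scaled
    component in the 100-210 ms window (``habituation_gain`` > 0); deviant
    epochs additionally carry a mismatch component with amplitude
    ``mismatch_base + mismatch_gain * C`` (gain < 0: weaker violation
    responses for harder sequences) in the 130-250 ms window.
    """

    n_subjects: int = 19
    n_sensors: int = 30
    sfreq_hz: float = 250.0
    epoch_window_ms: Tuple[float, float] = (-50.0, 350.0)
    deviant_window_ms: Tuple[float, float] = (-50.0, 600.0)
    auditory_amplitude: float = 2.0
    habituation_gain: float = 0.06
    mismatch_base: float = 2.4
    mismatch_gain: float = -0.08
    noise_sd: float = 1.0
    n_habituation: int = 10
    n_standards: int = 12
    n_deviants: int = 24


@dataclass
class EvokedEpochs:
    """Sensor-level epochs: ``data`` is (trials, sensors, times) per
    subject stacked as (subjects, trials, sensors, times); ``metadata``
    has one row per trial (sequence, complexity, trial_type, run,
    version, deviant_position); ``adjacency`` is the sensor neighborhood
    graph used by spatiotemporal clustering."""

    data: np.ndarray
    times_ms: np.ndarray
    sfreq_hz: float
    metadata: pd.DataFrame
    adjacency: sparse.spmatrix

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


def _bump(times: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Smooth raised-cosine activation over [start, stop] ms."""
    out = np.zeros_like(times)
    inside = (times >= start) & (times <= stop)
    phase = (times[inside] - start) / (stop - start)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return out


def _ring_adjacency(n_sensors: int) -> sparse.csr_matrix:
    """Explicit sensor neighborhood for the synthetic helmet: a ring in
    which each sensor touches its two neighbors."""
    rows, cols = [], []
    for i in range(n_sensors):
        for j in ((i - 1) % n_sensors, (i + 1) % n_sensors):
            rows.append(i)
            cols.append(j)
    data = np.ones(len(rows), dtype=bool)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n_sensors, n_sensors))


def simulate_evoked(
    params: EvokedSimParams,
    roster: Sequence[SequenceRecord],
    seed: int = 0,
    deviant_epochs: bool = False,
) -> EvokedEpochs:
    """Item-locked epochs for habituation/standard trials, or (with
    ``deviant_epochs``) deviant-locked epochs over the longer window.

    Each epoch is the sum of a fixed auditory template, a complexity-scaled
    habituation component, a mismatch component on deviants, and white
    sensor noise, then baselined to the pre-onset mean.  Trials are split
    into two runs per version so the decoder's run-wise cross-validation
    has the structure it expects.
    """
    root = np.random.SeedSequence(seed)
    topo_ss, noise_ss = root.spawn(2)
    rng_topo = np.random.default_rng(topo_ss)
    rng = np.random.default_rng(noise_ss)

    window = params.deviant_window_ms if deviant_epochs else params.epoch_window_ms
    dt = 1000.0 / params.sfreq_hz
    times = np.arange(window[0], window[1] + 0.5 * dt, dt)

    topo_aud = rng_topo.normal(size=params.n_sensors)
    topo_aud /= np.linalg.norm(topo_aud)
    topo_hab = rng_topo.normal(size=params.n_sensors)
    topo_hab /= np.linalg.norm(topo_hab)
    topo_mmn = rng_topo.normal(size=params.n_sensors)
    topo_mmn /= np.linalg.norm(topo_mmn)

    shape_aud = _bump(times, 50.0, 150.0)
    shape_hab = _bump(times, 100.0, 210.0)
    shape_mmn = _bump(times, 130.0, 250.0)

    meta_rows: List[dict] = []
    run = 0
    for record in roster:
        for version in ("A", "B"):
            n_hab = params.n_habituation
            n_std = params.n_standards
            n_dev = params.n_deviants
            if deviant_epochs:
                kinds = ["standard"] * n_std + ["deviant"] * n_dev
            else:
                kinds = ["habituation"] * n_hab + ["standard"] * n_std + [
                    "deviant"
                ] * n_dev
            for kind in kinds:
                meta_rows.append(
                    {
                        "sequence": record.name,
                        "complexity": record.complexity,
                        "trial_type": kind,
                        "version": version,
                        "run": run,
                        "deviant_position": np.nan,
                    }
                )
            run += 1
    metadata = pd.DataFrame(meta_rows)
    n_trials = len(metadata)

    base = np.zeros((n_trials, params.n_sensors, times.size))
    complexity = metadata["complexity"].to_numpy()[:, None, None]
    is_dev = (metadata["trial_type"] == "deviant").to_numpy()[:, None, None]
    base += params.auditory_amplitude * np.outer(topo_aud, shape_aud)
    base += (
        params.habituation_gain
        * complexity
        * np.outer(topo_hab, shape_hab)[None, :, :]
    )
    base += (
        is_dev
        * (params.mismatch_base + params.mismatch_gain * complexity)
        * np.outer(topo_mmn, shape_mmn)[None, :, :]
    )

    data = np.empty((params.n_subjects, n_trials, params.n_sensors, times.size))
    for s in range(params.n_subjects):
        data[s] = base + rng.normal(0.0, params.noise_sd, size=base.shape)

    # baseline: zero mean over the pre-onset interval
    pre = times < 0
    data -= data[..., pre].mean(axis=-1, keepdims=True)

    return EvokedEpochs(
        data=data,
        times_ms=times,
        sfreq_hz=params.sfreq_hz,
        metadata=metadata,
        adjacency=_ring_adjacency(params.n_sensors),
    )
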