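"""Scoring, signal-detection summaries and the mixed-model comparison.

The deviant-detection task yields, per subject and sequence, hit and
false-alarm counts and response times for correct detections.
Sensitivity (d') uses the log-linear adjustment of extreme proportions
before the normal-quantile transform.  Group-level effects of sequence
complexity are assessed by ordinary least squares on sequence means and
by linear mixed models with a participant random intercept, fitted by
maximum likelihood so that AIC and likelihood-ratio comparisons are
meaningful.  The model grid crosses the six complexity metrics with the
presence/absence of a transition-surprise regressor (12 models per
outcome) and ranks them by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .complexity_metrics import METRIC_NAMES
from .experiment_design import DesignSpec, FMRI_DESIGN, SequenceRecord

__all__ = [
    "dprime",
    "score_responses",
    "summarize_behavior",
    "attach_metrics",
    "group_regression",
    "ModelFitResult",
    "fit_metric_models",
    "model_grid",
]


def dprime(
    hits: int, n_signal: int, false_alarms: int, n_noise: int,
    adjust: str = "loglinear",
) -> float:
    """Sensitivity index Phi^-1(hit rate) - Phi^-1(false-alarm rate).

    The log-linear adjustment adds 0.5 to each count and 1 to each trial
    total, keeping the quantiles finite for perfect or empty cells.
    """
    if min(hits, n_signal, false_alarms, n_noise) < 0:
        raise ValueError("counts must be nonnegative")
    if n_signal == 0:
        return float("nan")
    if adjust == "loglinear":
        hr = (hits + 0.5) / (n_signal + 1)
        far = (false_alarms + 0.5) / (n_noise + 1)
    elif adjust == "none":
        hr = hits / n_signal
        far = false_alarms / n_noise
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def score_responses(
    stream: pd.DataFrame,
    press_times_ms: Sequence[float],
    spec: DesignSpec = FMRI_DESIGN,
) -> pd.DataFrame:
    """Score button presses against a mini-session item stream.

    A press inside the response window after a deviant onset is a hit for
    that deviant (first press wins); any other press is a false alarm.
    Deviants without an in-window press are misses.  Returns one row per
    event with ``event`` in {hit, miss, false_alarm} and ``rt_ms`` for
    hits.
    """
    lo, hi = spec.response_window_ms
    deviants = stream[stream["is_deviant"]].sort_values("onset_ms")
    dev_onsets = deviants["onset_ms"].to_numpy()
    dev_trials = deviants["trial"].to_numpy()
    claimed = np.zeros(len(dev_onsets), dtype=bool)

    events: List[dict] = []
    for press in sorted(float(p) for p in press_times_ms):
        rel = press - dev_onsets
        in_window = (rel >= lo) & (rel <= hi) & ~claimed
        if in_window.any():
            idx = int(np.flatnonzero(in_window)[-1])  # most recent deviant
            claimed[idx] = True
            events.append(
                {
                    "event": "hit",
                    "trial": int(dev_trials[idx]),
                    "rt_ms": float(rel[idx]),
                    "press_time_ms": press,
                }
            )
        else:
            events.append(
                {
                    "event": "false_alarm",
                    "trial": np.nan,
                    "rt_ms": np.nan,
                    "press_time_ms": press,
                }
            )
    for i, trial in enumerate(dev_trials):
        if not claimed[i]:
            events.append(
                {
                    "event": "miss",
                    "trial": int(trial),
                    "rt_ms": np.nan,
                    "press_time_ms": np.nan,
                }
            )
    return pd.DataFrame(events)


def summarize_behavior(
    trials: pd.DataFrame, fa_pooling: str = "subject"
) -> pd.DataFrame:
    """Per (subject, sequence) signal-detection summary from a trial table
    as produced by the behavioral generator: hit/miss/false-alarm counts,
    log-linear d', and mean correct-detection response time.  Carries the
    complexity and block-mean surprise columns through.

    With the default ``fa_pooling="subject"``, d' relates each cell's hit
    rate to the subject's overall false-alarm rate across all standard
    trials; ``"cell"`` uses the cell's own standards instead.
    """
    if fa_pooling not in ("subject", "cell"):
        raise ValueError("fa_pooling must be 'subject' or 'cell'")
    std_all = trials[trials["trial_type"] == "standard"]
    subject_fas = std_all.groupby("subject")["response"].agg(["sum", "count"])
    rows = []
    for (subject, sequence), cell in trials.groupby(["subject", "sequence"]):
        dev = cell[cell["trial_type"] == "deviant"]
        std = cell[cell["trial_type"] == "standard"]
        hits = int(dev["response"].sum())
        fas = int(std["response"].sum())
        if fa_pooling == "subject":
            fa_n = int(subject_fas.loc[subject, "sum"])
            fa_total = int(subject_fas.loc[subject, "count"])
        else:
            fa_n, fa_total = fas, len(std)
        rows.append(
            {
                "subject": subject,
                "sequence": sequence,
                "complexity": cell["complexity"].iloc[0],
                "block_mean_surprise": cell["block_mean_surprise"].mean(),
                "n_deviant": len(dev),
                "n_standard": len(std),
                "hits": hits,
                "misses": len(dev) - hits,
                "false_alarms": fas,
                "dprime": dprime(hits, len(dev), fa_n, fa_total),
                "mean_rt_ms": dev.loc[dev["response"], "rt_ms"].mean(),
                "detected_surprise": dev.loc[dev["response"], "surprise"].mean(),
            }
        )
    return pd.DataFrame(rows)


def attach_metrics(
    summary: pd.DataFrame, roster: Sequence[SequenceRecord]
) -> pd.DataFrame:
    """Join the per-sequence complexity-metric columns (lot, entropy, ...)
    onto a per-(subject, sequence) summary table."""
    metric_table = pd.DataFrame(
        [{"sequence": r.name, **r.metrics} for r in roster]
    )
    return summary.merge(metric_table, on="sequence", how="left")


def group_regression(
    values: Sequence[float], complexity: Sequence[float]
) -> Dict[str, float]:
    """OLS of per-sequence group means on complexity: slope, intercept,
    R^2, F(1, n-2) and its p-value."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(complexity, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 sequences")
    if np.allclose(x, x[0]):
        raise ValueError("constant predictor: slope undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "f_stat": float(fit.fvalue),
        "p_value": float(fit.f_pvalue),
        "df_resid": float(fit.df_resid),
    }


@dataclass(frozen=True)
class ModelFitResult:
    outcome: str
    metric: str
    with_surprise: bool
    quadratic: bool
    estimates: Dict[str, float]
    standard_errors: Dict[str, float]
    aic: float
    log_likelihood: float
    n_params: int
    conditional_r2: float
    converged: bool
    delta_aic: float = np.nan

    def lrt_against(self, reduced: "ModelFitResult") -> Dict[str, float]:
        """Likelihood-ratio test of this (full) model against a nested
        reduced one (both fitted by maximum likelihood)."""
        chi2 = 2.0 * (self.log_likelihood - reduced.log_likelihood)
        df = self.n_params - reduced.n_params
        return {
            "chi2": float(chi2),
            "df": int(df),
            "p_value": float(stats.chi2.sf(max(chi2, 0.0), df)),
        }


def _fit_mixed(
    table: pd.DataFrame, outcome: str, predictors: List[str],
    columns: List[str],
) -> Tuple[object, bool]:
    data = table.dropna(subset=[outcome] + columns).copy()
    formula = f"{outcome} ~ " + " + ".join(predictors) if predictors else f"{outcome} ~ 1"
    model = smf.mixedlm(formula, data, groups=data["subject"])
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=False, method="lbfgs")
            converged = bool(fit.converged)
        except Exception:
            fit = model.fit(reml=False)
            converged = bool(fit.converged)
    return fit, converged


def _conditional_r2(fit) -> float:
    """Nakagawa-Schielzeth conditional R^2: (fixed + random variance) /
    total variance, for a random-intercept model."""
    X = fit.model.exog
    var_f = float(np.var(X @ fit.fe_params))
    var_r = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    var_e = float(fit.scale)
    return (var_f + var_r) / (var_f + var_r + var_e)


def fit_metric_models(
    table: pd.DataFrame,
    metric: str,
    outcome: str = "dprime",
    with_surprise: bool = False,
    quadratic: bool = False,
    surprise_column: Optional[str] = None,
) -> ModelFitResult:
    """Fit one linear mixed model: outcome ~ metric (+ metric^2)
    (+ surprise), random intercept per participant, maximum likelihood.

    ``table`` is the per-(subject, sequence) summary with one column per
    metric (named as in the complexity-metric vector), the outcome
    column, and the surprise regressor (``block_mean_surprise`` for
    sensitivity, ``detected_surprise`` for response times, unless
    overridden).
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}")
    if surprise_column is None:
        surprise_column = (
            "detected_surprise" if outcome == "mean_rt_ms" else "block_mean_surprise"
        )
    predictors = [metric]
    columns = [metric, "subject"]
    if quadratic:
        predictors.append(f"I({metric} ** 2)")
    if with_surprise:
        predictors.append(surprise_column)
        columns.append(surprise_column)
    fit, converged = _fit_mixed(table, outcome, predictors, columns)
    k = len(fit.fe_params) + 2  # + random-intercept variance + residual
    aic = -2.0 * fit.llf + 2.0 * k
    names = list(fit.fe_params.index)
    return ModelFitResult(
        outcome=outcome,
        metric=metric,
        with_surprise=with_surprise,
        quadratic=quadratic,
        estimates={n: float(fit.fe_params[n]) for n in names},
        standard_errors={n: float(fit.bse_fe[n]) for n in names},
        aic=float(aic),
        log_likelihood=float(fit.llf),
        n_params=k,
        conditional_r2=_conditional_r2(fit),
        converged=converged,
    )


def model_grid(
    table: pd.DataFrame, outcome: str = "dprime"
) -> List[ModelFitResult]:
    """The 6-metric x {with, without surprise} grid (12 mixed models),
    ranked by AIC; the best converged model has delta_aic 0."""
    fits: List[ModelFitResult] = []
    for metric in METRIC_NAMES:
        for with_surprise in (False, True):
            fits.append(
                fit_metric_models(
                    table, metric, outcome=outcome, with_surprise=with_surprise
                )
            )
    converged = [f for f in fits if f.converged]
    if not converged:
        warnings.warn("no model converged; delta AIC undefined")
        return fits
    best = min(f.aic for f in converged)
    ranked = sorted(fits, key=lambda f: (not f.converged, f.aic))
    return [
        ModelFitResult(
            **{
                **f.__dict__,
                "delta_aic": (f.aic - best) if f.converged else np.nan,
            }
        )
        for f in ranked
    ]
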