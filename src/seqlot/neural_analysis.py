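"""Sensor-level statistics: GFP, complexity regressions, cluster-based
permutation tests, and the time-resolved deviancy decoder.

The statistical core is nonparametric: point-wise statistics (one-sample
t or correlation) are thresholded, contiguous suprathreshold points are
merged into clusters under a supplied adjacency (time axis, sensor graph
x time, or a time-time lattice), each cluster is scored by the sum of its
member statistics, and the family-wise null is obtained by sign-flipping
subjects.  Decoding uses an L2-regularized linear classifier per time
point with channels z-scored across trials, two-fold cross-validation
that keeps the two sequence versions in separate folds, and standards
matched to deviant ordinal positions; generalization across time
evaluates every training time on every testing time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .synthetic_data import EvokedEpochs

__all__ = [
    "gfp",
    "gfp_complexity_correlation",
    "regress_complexity",
    "ClusterResult",
    "cluster_permutation",
    "temporal_cluster_permutation",
    "deviancy_decoder",
    "DecoderOutput",
    "gat",
]


def gfp(evoked: np.ndarray) -> np.ndarray:
    """Global field power: root-mean-square across sensors (axis -2) of an
    evoked (sensors x time) array; batched dimensions pass through."""
    evoked = np.asarray(evoked, dtype=float)
    if evoked.ndim < 2:
        raise ValueError("need at least (sensors, times)")
    return np.sqrt(np.mean(evoked**2, axis=-2))


# ---------------------------------------------------------------------------
# Cluster-based permutation machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterResult:
    members: Tuple[Tuple[int, int], ...]  # (space, time) index pairs
    statistic: float  # sum of member statistics
    p_value: float

    def covers(self, mask: np.ndarray) -> float:
        """Fraction of ``mask`` (space x time boolean) inside the cluster."""
        inside = np.zeros_like(mask, dtype=bool)
        for s, t in self.members:
            inside[s, t] = True
        return float((inside & mask).sum() / max(mask.sum(), 1))


def _label_clusters(
    mask: np.ndarray, adjacency: Optional[sparse.spmatrix]
) -> List[np.ndarray]:
    """Connected components of a suprathreshold (space x time) mask.
    Points are adjacent along time, and across space where ``adjacency``
    says so (None: purely temporal clustering per space row)."""
    n_space, n_time = mask.shape
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        return []
    pos = {p: i for i, p in enumerate(idx)}
    rows: List[int] = []
    cols: List[int] = []
    adj = adjacency.tocoo() if adjacency is not None else None
    neighbors_of: Dict[int, List[int]] = {}
    if adj is not None:
        for a, b in zip(adj.row, adj.col):
            neighbors_of.setdefault(int(a), []).append(int(b))
    for p in idx:
        s, t = divmod(int(p), n_time)
        if t + 1 < n_time and mask[s, t + 1]:
            q = p + 1
            rows.append(pos[p])
            cols.append(pos[q])
        for s2 in neighbors_of.get(s, ()):
            if mask[s2, t]:
                q = s2 * n_time + t
                rows.append(pos[p])
                cols.append(pos[q])
    graph = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(idx.size, idx.size)
    )
    n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def _cluster_masses(
    t_map: np.ndarray,
    threshold: float,
    adjacency: Optional[sparse.spmatrix],
    tails: int,
) -> List[Tuple[np.ndarray, float]]:
    out: List[Tuple[np.ndarray, float]] = []
    signs = (1, -1) if tails == 2 else (1,)
    for sign in signs:
        mask = sign * t_map > threshold
        for members in _label_clusters(mask, adjacency):
            mass = float(t_map.ravel()[members].sum())
            out.append((members, mass))
    return out


def cluster_permutation(
    stat_maps: np.ndarray,
    adjacency: Optional[sparse.spmatrix] = None,
    threshold: Optional[float] = None,
    n_permutations: int = 1000,
    tails: int = 2,
    seed: int = 0,
) -> List[ClusterResult]:
    """One-sample cluster-based permutation test.

    ``stat_maps``: per-subject maps (subjects x space x time); for purely
    temporal tests pass space of size 1.  Point-wise one-sample t values
    above the cluster-forming ``threshold`` (default: two-tailed t
    critical at p < 0.05 for n-1 df) are clustered under ``adjacency``;
    cluster mass is the sum of member t values.  The null distribution of
    the maximal |mass| is built from subject sign flips, and each observed
    cluster gets p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    data = np.asarray(stat_maps, dtype=float)
    if data.ndim != 3:
        raise ValueError("stat_maps must be (subjects, space, time)")
    n_subjects = data.shape[0]
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_permutations < 100:
        import warnings

        warnings.warn("fewer than 100 permutations: p-values are coarse")
    if threshold is None:
        threshold = float(stats.t.ppf(1 - 0.025, df=n_subjects - 1))

    def t_map(x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n_subjects))
        return np.nan_to_num(t)

    observed = _cluster_masses(t_map(data), threshold, adjacency, tails)
    if not observed:
        return []

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        flips = rng.choice((-1.0, 1.0), size=n_subjects)
        perm = t_map(data * flips[:, None, None])
        masses = _cluster_masses(perm, threshold, adjacency, tails)
        null_max[i] = max((abs(m) for _, m in masses), default=0.0)

    n_time = data.shape[2]
    results = []
    for members, mass in observed:
        p = (1.0 + float(np.sum(null_max >= abs(mass)))) / (1.0 + n_permutations)
        coords = tuple(divmod(int(m), n_time) for m in members)
        results.append(ClusterResult(members=coords, statistic=mass, p_value=p))
    return sorted(results, key=lambda c: c.p_value)


def temporal_cluster_permutation(
    series: np.ndarray, **kwargs
) -> List[ClusterResult]:
    """Cluster test on per-subject time series (subjects x time)."""
    series = np.asarray(series, dtype=float)
    return cluster_permutation(series[:, None, :], adjacency=None, **kwargs)


def lattice_adjacency(n_rows: int) -> sparse.csr_matrix:
    """4-neighborhood rows for a (rows x time) lattice along the row axis
    (time adjacency is implicit in the clustering)."""
    rows, cols = [], []
    for i in range(n_rows):
        for j in (i - 1, i + 1):
            if 0 <= j < n_rows:
                rows.append(i)
                cols.append(j)
    return sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n_rows, n_rows)
    )


# ---------------------------------------------------------------------------
# GFP / regression analyses
# ---------------------------------------------------------------------------


def _sequence_evoked(
    epochs: EvokedEpochs, trial_types: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-subject per-sequence evoked averages (subjects, sequences,
    sensors, times) and the matching complexity values."""
    meta = epochs.metadata
    sequences = meta["sequence"].unique()
    complexities = []
    evoked = []
    for seq in sequences:
        sel = (meta["sequence"] == seq) & meta["trial_type"].isin(trial_types)
        evoked.append(epochs.data[:, sel.to_numpy()].mean(axis=1))
        complexities.append(float(meta.loc[sel, "complexity"].iloc[0]))
    return np.stack(evoked, axis=1), np.asarray(complexities)


def gfp_complexity_correlation(
    epochs: EvokedEpochs,
    trial_types: Sequence[str] = ("habituation",),
    n_permutations: int = 1000,
    seed: int = 0,
):
    """Per-subject, per-time Pearson correlation between sequence-mean GFP
    and sequence complexity, with temporal cluster significance via
    subject sign flips.  Returns (per-subject r array (subjects x times),
    cluster list)."""
    evoked, complexity = _sequence_evoked(epochs, trial_types)
    if len(complexity) < 3:
        raise ValueError("need at least 3 sequences")
    power = gfp(evoked)  # subjects x sequences x times
    cx = complexity - complexity.mean()
    cx_norm = np.sqrt((cx**2).sum())
    centered = power - power.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1)) * cx_norm
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("sqt,q->st", centered, cx) / denom
    r = np.nan_to_num(r)
    clusters = temporal_cluster_permutation(
        r, n_permutations=n_permutations, seed=seed
    )
    return r, clusters


def regress_complexity(
    epochs: EvokedEpochs,
    trial_types: Sequence[str] = ("habituation",),
    controls: Optional[np.ndarray] = None,
    residualize: bool = False,
    folds: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Per-subject sensor x time regression slope of the signal on
    complexity, averaged over cross-validation folds.

    ``controls`` (trials x k) adds nuisance regressors; with
    ``residualize`` the controls are fitted first and complexity is
    regressed on their residuals (the partial effect).  Returns
    (subjects, sensors, times) coefficient maps.
    """
    meta = epochs.metadata
    sel = meta["trial_type"].isin(trial_types).to_numpy()
    data = epochs.data[:, sel]
    x = meta.loc[sel, "complexity"].to_numpy(dtype=float)
    n_subjects, n_trials, n_sensors, n_times = data.shape
    rng = np.random.default_rng(seed)
    fold_ids = rng.permutation(np.arange(n_trials) % folds)
    ctrl = None
    if controls is not None:
        ctrl = np.asarray(controls, dtype=float)[sel]

    coefs = np.zeros((n_subjects, n_sensors, n_times))
    for fold in range(folds):
        mask = fold_ids == fold
        xf = x[mask]
        yf = data[:, mask]  # subjects x trials_f x sensors x times
        if ctrl is not None:
            C = np.column_stack([np.ones(mask.sum()), ctrl[mask]])
            if residualize:
                # residualize both signal and complexity on the controls
                proj = C @ np.linalg.pinv(C)
                xf = xf - proj @ xf
                yf = yf - np.einsum("ab,sbkt->sakt", proj, yf)
                X = np.column_stack([np.ones(mask.sum()), xf])
                col = 1
            else:
                X = np.column_stack([C, xf])
                col = X.shape[1] - 1
        else:
            X = np.column_stack([np.ones(mask.sum()), xf])
            col = 1
        pinv = np.linalg.pinv(X)
        beta = np.einsum("pb,sbkt->spkt", pinv, yf)
        coefs += beta[:, col]
    return coefs / folds


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


@dataclass
class DecoderOutput:
    times_ms: np.ndarray
    projections: np.ndarray  # (subjects, trials, times) decision values
    trials: pd.DataFrame  # metadata of the decoded trials (label, sequence, ...)
    performance: pd.DataFrame  # per (subject, sequence, time)
    mean_performance: np.ndarray  # subjects x times


def _zscore_train_apply(train: np.ndarray, *others: np.ndarray):
    """Z-score channels across trials (per sensor/time) using training
    statistics."""
    mu = train.mean(axis=0, keepdims=True)
    sd = train.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return tuple((arr - mu) / sd for arr in (train,) + others)


def _match_standards(
    meta: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Keep all deviants and an equal number of standards per (sequence,
    run); with the synthetic generator standards are exchangeable, so the
    match is a per-cell subsample."""
    keep = np.zeros(len(meta), dtype=bool)
    for (_, _), cell in meta.groupby(["sequence", "run"]):
        dev_idx = cell.index[cell["trial_type"] == "deviant"].to_numpy()
        std_idx = cell.index[cell["trial_type"] == "standard"].to_numpy()
        keep[dev_idx] = True
        if len(std_idx) > len(dev_idx):
            std_idx = rng.choice(std_idx, size=len(dev_idx), replace=False)
        keep[std_idx] = True
    return keep


def deviancy_decoder(
    epochs: EvokedEpochs,
    C: float = 1.0,
    train_window_ms: Optional[Tuple[float, float]] = None,
    metric: str = "projection",
    seed: int = 0,
) -> DecoderOutput:
    """Standard-versus-deviant decoding, per subject and time point.

    ``metric`` selects the per-sequence performance score: ``"projection"``
    (mean decision-value difference, the default) or ``"auc"`` (area under
    the ROC of the projections).

    Trials are restricted to test-phase standards matched in number to the
    deviants of each (sequence, run); runs are split into two folds such
    that the two versions of every sequence fall in different folds
    (training and testing are then swapped).  Channels are z-scored
    across training trials per time point; the classifier is logistic
    regression with L2 penalty.  Projections are signed decision-function
    values of left-out trials; per-sequence performance is
    mean(projection | deviant) - mean(projection | standard).

    With ``train_window_ms`` a single decoder per subject/fold is trained
    on the average over that window and applied to every time point
    (projection time courses from a fixed post-deviant training window).
    """
    meta = epochs.metadata.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    filtered = meta[meta["trial_type"].isin(["standard", "deviant"])]
    keep = _match_standards(filtered.reset_index(drop=True), rng)
    # keep is aligned to the filtered index; rebuild a full mask
    test_phase = meta["trial_type"].isin(["standard", "deviant"]).to_numpy()
    full_keep = np.zeros(len(meta), dtype=bool)
    full_keep[np.flatnonzero(test_phase)] = keep
    sub = meta[full_keep].reset_index(drop=True)
    data = epochs.data[:, full_keep]
    y = (sub["trial_type"] == "deviant").to_numpy().astype(int)

    # two folds: version A runs vs version B runs
    fold_of_trial = (sub["version"] == "B").to_numpy().astype(int)
    n_subjects, n_trials, n_sensors, n_times = data.shape
    times = epochs.times_ms

    proj = np.full((n_subjects, n_trials, n_times), np.nan)
    for s in range(n_subjects):
        for fold in (0, 1):
            train_mask = fold_of_trial == fold
            test_mask = ~train_mask
            if len(np.unique(y[train_mask])) < 2:
                raise ValueError("a class is absent in a training fold")
            if train_window_ms is not None:
                t_sel = (times >= train_window_ms[0]) & (times <= train_window_ms[1])
                Xtr = data[s][train_mask][:, :, t_sel].mean(axis=-1)
                Xtr_z, = _zscore_train_apply(Xtr)
                clf = LogisticRegression(C=C, max_iter=1000)
                clf.fit(Xtr_z, y[train_mask])
                for t in range(n_times):
                    Xte = data[s][test_mask][:, :, t]
                    _, Xte_z = _zscore_train_apply(Xtr, Xte)
                    proj[s, test_mask, t] = clf.decision_function(Xte_z)
            else:
                for t in range(n_times):
                    Xtr = data[s][train_mask][:, :, t]
                    Xte = data[s][test_mask][:, :, t]
                    Xtr_z, Xte_z = _zscore_train_apply(Xtr, Xte)
                    clf = LogisticRegression(C=C, max_iter=1000)
                    clf.fit(Xtr_z, y[train_mask])
                    proj[s, test_mask, t] = clf.decision_function(Xte_z)

    perf_rows = []
    for s in range(n_subjects):
        for seq, cell in sub.groupby("sequence"):
            idx = cell.index.to_numpy()
            dev = idx[y[idx] == 1]
            std = idx[y[idx] == 0]
            if metric == "auc":
                perf = np.array(
                    [roc_auc_score(y[idx], proj[s, idx, t]) for t in range(n_times)]
                )
            elif metric == "projection":
                perf = proj[s, dev].mean(axis=0) - proj[s, std].mean(axis=0)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            for t, time in enumerate(times):
                perf_rows.append(
                    {
                        "subject": s,
                        "sequence": seq,
                        "complexity": float(cell["complexity"].iloc[0]),
                        "time_ms": float(time),
                        "performance": float(perf[t]),
                    }
                )
    performance = pd.DataFrame(perf_rows)
    mean_perf = (
        performance.groupby(["subject", "time_ms"])["performance"]
        .mean()
        .unstack()
        .to_numpy()
    )
    return DecoderOutput(
        times_ms=times,
        projections=proj,
        trials=sub.assign(label=y),
        performance=performance,
        mean_performance=mean_perf,
    )


def gat(
    epochs: EvokedEpochs,
    C: float = 1.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Generalization-across-time: decoders trained at each time point are
    evaluated at every test time.  Returns (per-subject GAT matrices
    (subjects x train_times x test_times), times).  The diagonal equals
    the time-resolved performance of the same folds."""
    meta = epochs.metadata.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    filtered = meta[meta["trial_type"].isin(["standard", "deviant"])]
    keep = _match_standards(filtered.reset_index(drop=True), rng)
    test_phase = meta["trial_type"].isin(["standard", "deviant"]).to_numpy()
    full_keep = np.zeros(len(meta), dtype=bool)
    full_keep[np.flatnonzero(test_phase)] = keep
    sub = meta[full_keep].reset_index(drop=True)
    data = epochs.data[:, full_keep]
    y = (sub["trial_type"] == "deviant").to_numpy().astype(int)
    fold_of_trial = (sub["version"] == "B").to_numpy().astype(int)
    n_subjects, n_trials, n_sensors, n_times = data.shape

    matrices = np.zeros((n_subjects, n_times, n_times))
    for s in range(n_subjects):
        for fold in (0, 1):
            train_mask = fold_of_trial == fold
            test_mask = ~train_mask
            ytr, yte = y[train_mask], y[test_mask]
            for t_train in range(n_times):
                Xtr = data[s][train_mask][:, :, t_train]
                Xtr_z, = _zscore_train_apply(Xtr)
                clf = LogisticRegression(C=C, max_iter=1000)
                clf.fit(Xtr_z, ytr)
                mu = Xtr.mean(axis=0, keepdims=True)
                sd = Xtr.std(axis=0, keepdims=True)
                sd[sd == 0] = 1.0
                Xte_all = (data[s][test_mask] - mu[..., None]) / sd[..., None]
                dec = np.einsum(
                    "k,nkt->nt", clf.coef_[0], Xte_all
                ) + clf.intercept_[0]
                matrices[s, t_train] += 0.5 * (
                    dec[yte == 1].mean(axis=0) - dec[yte == 0].mean(axis=0)
                )
    return matrices, epochs.times_ms
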