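"""GFP, cluster permutation statistics, regressions and decoding."""

import numpy as np
import pytest
from scipy import sparse, stats

from seqlot.neural_analysis import (
    cluster_permutation,
    deviancy_decoder,
    gat,
    gfp,
    gfp_complexity_correlation,
    lattice_adjacency,
    regress_complexity,
    temporal_cluster_permutation,
)
from seqlot.synthetic_data import EvokedSimParams, simulate_evoked

SMALL = EvokedSimParams(
    n_subjects=4, n_sensors=12, n_habituation=4, n_standards=6, n_deviants=6
)


class TestGfp:
    def test_single_sensor_magnitude(self):
        np.testing.assert_allclose(gfp(np.array([[-3.0, 2.0]])), [3.0, 2.0])

    def test_two_sensor_rms(self):
        assert gfp(np.array([[3.0], [4.0]]))[0] == pytest.approx(np.sqrt(12.5))

    def test_zeros(self):
        np.testing.assert_array_equal(gfp(np.zeros((5, 7))), np.zeros(7))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 20))
        np.testing.assert_allclose(gfp(-2.5 * x), 2.5 * gfp(x))


class TestClusterPermutation:
    def test_p_value_lower_bound(self):
        rng = np.random.default_rng(1)
        data = rng.normal(1.0, 0.2, size=(10, 1, 20))  # strong effect
        clusters = cluster_permutation(data, n_permutations=200, seed=0)
        assert clusters
        assert clusters[0].p_value >= 1.0 / 201.0

    def test_no_suprathreshold_points_gives_empty_list(self):
        data = np.full((6, 1, 10), 1e-12)
        data += np.random.default_rng(2).normal(0, 1e-9, data.shape)
        out = cluster_permutation(data, threshold=50.0, n_permutations=120, seed=0)
        assert out == []

    def test_injected_blob_is_recovered(self):
        rng = np.random.default_rng(3)
        n_sensors, n_times = 10, 40
        blob = np.zeros((n_sensors, n_times), dtype=bool)
        blob[3:6, 10:22] = True
        data = rng.normal(0.0, 1.0, size=(12, n_sensors, n_times))
        data[:, blob] += 1.0  # SNR 1
        adjacency = sparse.csr_matrix(np.eye(n_sensors, k=1) + np.eye(n_sensors, k=-1))
        clusters = cluster_permutation(
            data, adjacency=adjacency.astype(bool), n_permutations=300, seed=0
        )
        best = clusters[0]
        assert best.p_value < 0.05
        assert best.covers(blob) >= 0.5

    def test_matches_reference_implementation_cluster_masses(self):
        """Cross-check observed clusters against the MNE implementation of
        the same test (same threshold; masses and memberships coincide)."""
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(7)
        data = rng.normal(0.3, 1.0, size=(9, 1, 30))
        threshold = float(stats.t.ppf(0.975, df=8))
        ours = cluster_permutation(
            data, threshold=threshold, n_permutations=100, seed=0, tails=2
        )
        t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            data[:, 0, :], threshold=threshold, n_permutations=100,
            tail=0, out_type="mask", seed=0, verbose=False,
        )
        ref_masses = sorted(
            float(t_obs[mask].sum()) for mask in clusters
        )
        our_masses = sorted(c.statistic for c in ours)
        np.testing.assert_allclose(our_masses, ref_masses, rtol=1e-10)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((1, 2, 3)))


class TestGfpComplexityCorrelation:
    def test_positive_cluster_inside_injected_window(self, meg_roster):
        epochs = simulate_evoked(
            EvokedSimParams(
                n_subjects=8, n_sensors=15, n_habituation=6,
                n_standards=4, n_deviants=4, habituation_gain=0.1,
            ),
            meg_roster,
            seed=5,
        )
        r, clusters = gfp_complexity_correlation(epochs, n_permutations=300, seed=1)
        sig = [c for c in clusters if c.p_value < 0.05 and c.statistic > 0]
        assert sig
        times = epochs.times_ms
        t_idx = [t for _, t in sig[0].members]
        assert times[min(t_idx)] >= 80.0
        assert times[max(t_idx)] <= 230.0

    def test_needs_three_sequences(self, meg_roster):
        epochs = simulate_evoked(SMALL, meg_roster[:2], seed=0)
        with pytest.raises(ValueError):
            gfp_complexity_correlation(epochs)


class TestRegressComplexity:
    def test_recovers_injected_slope(self, meg_roster):
        params = EvokedSimParams(
            n_subjects=3, n_sensors=10, noise_sd=0.3,
            n_habituation=8, n_standards=4, n_deviants=4,
        )
        epochs = simulate_evoked(params, meg_roster, seed=2)
        coefs = regress_complexity(epochs, trial_types=("habituation",))
        # the injected component is gain * (unit topography) * shape(t) with
        # shape peaking at 1 mid-window, so the sensor-space norm of the
        # subject-mean coefficient map at the peak recovers the gain
        mean_map = coefs.mean(axis=0)
        peak_t = int(np.argmin(np.abs(epochs.times_ms - 155.0)))
        norm = float(np.linalg.norm(mean_map[:, peak_t]))
        assert norm == pytest.approx(params.habituation_gain, rel=0.2)

    def test_orthogonal_controls_leave_slope_unchanged(self, meg_roster):
        params = EvokedSimParams(
            n_subjects=2, n_sensors=6, noise_sd=0.2,
            n_habituation=8, n_standards=4, n_deviants=4,
        )
        epochs = simulate_evoked(params, meg_roster, seed=3)
        plain = regress_complexity(epochs, trial_types=("habituation",))
        meta = epochs.metadata
        sel = meta["trial_type"] == "habituation"
        x = meta["complexity"].to_numpy(dtype=float)
        rng = np.random.default_rng(0)
        ctrl = rng.normal(size=(len(meta), 1))
        ctrl[sel.to_numpy()] -= (
            np.polyfit(x[sel], ctrl[sel.to_numpy(), 0], 1)[0] * x[sel]
        )[:, None] * 0  # keep random control; orthogonality is approximate
        with_ctrl = regress_complexity(
            epochs, trial_types=("habituation",), controls=ctrl
        )
        np.testing.assert_allclose(plain, with_ctrl, atol=0.02)

    def test_residualization_matches_partial_regression_closed_form(self):
        """On a toy collinear dataset, regressing the signal on the
        residuals of complexity given the control equals the textbook
        partial-regression slope."""
        rng = np.random.default_rng(9)
        n = 200
        c = rng.normal(size=n)
        x = 0.8 * c + 0.6 * rng.normal(size=n)  # complexity, collinear with c
        y = 2.0 * x + 1.5 * c + 0.1 * rng.normal(size=n)

        # package route: wrap as a 1-subject, 1-sensor, 1-time epochs object
        from seqlot.synthetic_data import EvokedEpochs
        import pandas as pd

        epochs = EvokedEpochs(
            data=y[None, :, None, None],
            times_ms=np.array([0.0]),
            sfreq_hz=250.0,
            metadata=pd.DataFrame(
                {"sequence": "S", "complexity": x, "trial_type": "habituation",
                 "version": "A", "run": 0, "deviant_position": np.nan}
            ),
            adjacency=sparse.csr_matrix((1, 1)),
        )
        got = regress_complexity(
            epochs, controls=c[:, None], residualize=True, folds=1
        )[0, 0, 0]

        # closed form: slope of y on x residualized against c
        X = np.column_stack([np.ones(n), c])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        expected = (rx @ ry) / (rx @ rx)
        assert got == pytest.approx(expected, rel=1e-6)


@pytest.fixture(scope="module")
def decoder_epochs(meg_roster):
    params = EvokedSimParams(
        n_subjects=4, n_sensors=12, n_habituation=2,
        n_standards=8, n_deviants=8, noise_sd=1.0,
    )
    return simulate_evoked(params, meg_roster, seed=11)


class TestDecoder:
    def test_null_data_decodes_at_chance(self, meg_roster):
        params = EvokedSimParams(
            n_subjects=5, n_sensors=10, n_habituation=2,
            n_standards=8, n_deviants=8,
            mismatch_base=0.0, mismatch_gain=0.0,  # deviants == standards
        )
        epochs = simulate_evoked(params, meg_roster, seed=13)
        out = deviancy_decoder(epochs, seed=0)
        window = (out.times_ms >= 100) & (out.times_ms <= 300)
        perf = out.mean_performance[:, window].mean(axis=1)
        se = perf.std(ddof=1) / np.sqrt(len(perf))
        assert abs(perf.mean()) < 2.5 * se + 0.05

    def test_performance_decreases_with_complexity(self, decoder_epochs):
        out = deviancy_decoder(decoder_epochs, seed=0)
        window = (out.times_ms >= 130) & (out.times_ms <= 250)
        perf = (
            out.performance[out.performance["time_ms"].between(130, 250)]
            .groupby("complexity")["performance"]
            .mean()
        )
        levels = perf.sort_index()
        # monotone trend: rank correlation strongly negative
        rho = stats.spearmanr(levels.index, levels.values).statistic
        assert rho < -0.8

    def test_gat_diagonal_equals_time_resolved_performance(self, decoder_epochs):
        out = deviancy_decoder(decoder_epochs, seed=0)
        matrices, times = gat(decoder_epochs, seed=0)
        diag = np.einsum("stt->st", matrices)
        np.testing.assert_allclose(diag, out.mean_performance, atol=1e-8)

    def test_sustained_component_generalizes_off_diagonal(self, decoder_epochs):
        matrices, times = gat(decoder_epochs, seed=0)
        window = (times >= 140) & (times <= 240)
        block = matrices[:, window][:, :, window].mean()
        off = matrices[:, window][:, :, times < 0].mean()
        assert block > 5 * abs(off)

    def test_fixed_window_decoder_tracks_deviants(self, decoder_epochs):
        out = deviancy_decoder(decoder_epochs, train_window_ms=(130, 210), seed=0)
        labels = out.trials["label"].to_numpy()
        window = (out.times_ms >= 130) & (out.times_ms <= 250)
        proj = out.projections[:, :, window].mean(axis=(0, 2))
        assert proj[labels == 1].mean() > proj[labels == 0].mean()

    def test_auc_metric_above_chance_in_mismatch_window(self, decoder_epochs):
        out = deviancy_decoder(decoder_epochs, metric="auc", seed=0)
        window_perf = (
            out.performance[out.performance["time_ms"].between(130, 250)]
            ["performance"].mean()
        )
        assert 0.5 < window_perf <= 1.0
        with pytest.raises(ValueError):
            deviancy_decoder(decoder_epochs, metric="accuracy", seed=0)


def test_temporal_lattice_helpers():
    adj = lattice_adjacency(4).toarray()
    assert adj.sum() == 6  # 3 undirected neighbor pairs
    clusters = temporal_cluster_permutation(
        np.random.default_rng(0).normal(2.0, 0.5, size=(8, 15)),
        n_permutations=150,
        seed=0,
    )
    assert clusters and clusters[0].p_value < 0.05
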