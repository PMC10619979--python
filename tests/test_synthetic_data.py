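"""Generators: determinism, limiting behavior, and construction checks."""

import numpy as np
import pandas as pd
import pytest

from seqlot.experiment_design import FMRI_DESIGN
from seqlot.lot_language import bracket_prediction
from seqlot.neural_analysis import gfp
from seqlot.synthetic_data import (
    BehaviorSimParams,
    BracketSimParams,
    EvokedSimParams,
    alternate_pairs_template,
    simulate_behavior,
    simulate_bracketing,
    simulate_evoked,
)

SMALL_EVOKED = EvokedSimParams(
    n_subjects=3, n_sensors=10, n_habituation=4, n_standards=4, n_deviants=4
)


class TestSimulateBehavior:
    def test_seed_determinism(self, roster):
        params = BehaviorSimParams(n_subjects=3)
        a = simulate_behavior(params, roster[:4], seed=5)
        b = simulate_behavior(params, roster[:4], seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_latent_sensitivity_is_linear_without_random_effects(self, roster):
        params = BehaviorSimParams(n_subjects=2, dprime_subject_sd=0.0)
        table = simulate_behavior(params, roster, seed=1)
        for record in roster:
            cell = table[table["sequence"] == record.name]
            expected = params.dprime_intercept + params.dprime_slope * record.complexity
            assert cell["latent_dprime"].unique() == pytest.approx([expected])

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            simulate_behavior(BehaviorSimParams(), [], seed=0)

    def test_trial_counts_follow_design(self, roster):
        table = simulate_behavior(
            BehaviorSimParams(n_subjects=2), roster[:3], FMRI_DESIGN, seed=0
        )
        counts = table.groupby(["subject", "sequence", "trial_type"]).size()
        assert set(counts.xs("deviant", level="trial_type")) == {12}
        assert set(counts.xs("standard", level="trial_type")) == {24}

    def test_rts_respect_response_window(self, roster):
        table = simulate_behavior(BehaviorSimParams(n_subjects=4), roster, seed=2)
        rts = table["rt_ms"].dropna()
        assert rts.between(200.0, 2500.0).all()


class TestSimulateBracketing:
    def test_full_fidelity_reproduces_prediction(self, roster):
        params = BracketSimParams(
            n_subjects=3, emit_probability=1.0, noise_rate=0.0,
            alternate_pairs_fraction=0.0,
        )
        table = simulate_bracketing(params, roster, seed=0)
        for record in roster:
            predicted = bracket_prediction(record.lot_expr, 16)
            for _, subj in table[table["sequence"] == record.name].groupby("subject"):
                observed = subj.sort_values("interval")["count"].tolist()
                assert observed == predicted

    def test_alternate_pair_strategy_decorrelates_from_single_group(self, roster_by_name):
        record = roster_by_name["Alternate"]
        single = np.asarray(bracket_prediction(record.lot_expr, 16), float)
        pairs = alternate_pairs_template(16)
        r = np.corrcoef(single, pairs)[0, 1]
        assert r < 0.5  # the two encodings make clearly different profiles

        params = BracketSimParams(
            n_subjects=20, emit_probability=1.0, noise_rate=0.0,
            alternate_pairs_fraction=1.0,
        )
        table = simulate_bracketing(params, [record], seed=1)
        mean_vec = (
            table.groupby("interval")["count"].mean().sort_index().to_numpy()
        )
        r_sim = np.corrcoef(mean_vec, single)[0, 1]
        assert r_sim < 0.5

    def test_seed_determinism(self, roster):
        params = BracketSimParams(n_subjects=4)
        a = simulate_bracketing(params, roster, seed=9)
        b = simulate_bracketing(params, roster, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateEvoked:
    def test_noise_free_habituation_gfp_increases_with_complexity(self, meg_roster):
        params = EvokedSimParams(
            n_subjects=1, n_sensors=8, noise_sd=0.0,
            n_habituation=2, n_standards=2, n_deviants=2,
        )
        epochs = simulate_evoked(params, meg_roster, seed=0)
        window = (epochs.times_ms >= 100) & (epochs.times_ms <= 210)
        meta = epochs.metadata
        values = []
        for record in meg_roster:
            sel = (
                (meta["sequence"] == record.name)
                & (meta["trial_type"] == "habituation")
            ).to_numpy()
            evoked = epochs.data[0, sel].mean(axis=0)
            values.append((record.complexity, gfp(evoked)[window].mean()))
        by_level = {}
        for c, v in values:
            by_level.setdefault(c, []).append(v)
        levels = sorted(by_level)
        power = [np.mean(by_level[c]) for c in levels]
        assert all(b > a for a, b in zip(power, power[1:]))

    def test_noise_free_mismatch_amplitude_decreases_with_complexity(self, meg_roster):
        params = EvokedSimParams(
            n_subjects=1, n_sensors=8, noise_sd=0.0,
            n_habituation=2, n_standards=2, n_deviants=2,
        )
        epochs = simulate_evoked(params, meg_roster, seed=0)
        window = (epochs.times_ms >= 130) & (epochs.times_ms <= 250)
        meta = epochs.metadata
        values = []
        for record in meg_roster:
            dev = ((meta["sequence"] == record.name) & (meta["trial_type"] == "deviant")).to_numpy()
            std = ((meta["sequence"] == record.name) & (meta["trial_type"] == "standard")).to_numpy()
            diff = epochs.data[0, dev].mean(axis=0) - epochs.data[0, std].mean(axis=0)
            values.append((record.complexity, gfp(diff)[window].mean()))
        by_level = {}
        for c, v in values:
            by_level.setdefault(c, []).append(v)
        levels = sorted(by_level)
        power = [np.mean(by_level[c]) for c in levels]
        assert all(b < a for a, b in zip(power, power[1:]))

    def test_noise_sd_matches_configuration(self, meg_roster):
        params = EvokedSimParams(
            n_subjects=1, n_sensors=25, noise_sd=1.5,
            n_habituation=0, n_standards=20, n_deviants=0,
        )
        epochs = simulate_evoked(params, meg_roster[:1], seed=3)
        flat = epochs.data[0, :, :, epochs.times_ms > 260]
        # after the evoked components die out only noise remains (the
        # baseline subtraction inflates variance by 1/n_baseline)
        n_base = int((epochs.times_ms < 0).sum())
        expected = params.noise_sd * np.sqrt(1 + 1 / n_base)
        assert flat.std() == pytest.approx(expected, rel=0.02)

    def test_seed_determinism_and_baseline(self, meg_roster):
        params = EvokedSimParams(
            n_subjects=2, n_sensors=6, n_habituation=2, n_standards=2, n_deviants=2
        )
        a = simulate_evoked(params, meg_roster[:2], seed=4)
        b = simulate_evoked(params, meg_roster[:2], seed=4)
        np.testing.assert_array_equal(a.data, b.data)
        pre = a.times_ms < 0
        np.testing.assert_allclose(
            a.data[..., pre].mean(axis=-1), 0.0, atol=1e-12
        )
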