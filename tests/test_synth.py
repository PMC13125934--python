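"""Synthetic cohort generators: determinism, design completeness, oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from empathkit.config import SimConfig, study1_config, study2_config
from empathkit.errors import ConfigurationError, GenerationError
from empathkit.synth import (
    ecg_template,
    lpp_hump,
    simulate_ecg_waveform,
    simulate_epochs_study1,
    simulate_ratings_study1,
    simulate_ratings_study2,
    simulate_rri,
    MONTAGE,
)


class TestConfig:
    def test_design_factories(self):
        assert study1_config().design == "study1"
        assert study2_config().design == "study2"

    @pytest.mark.parametrize(
        "kw",
        [
            {"design": "study3"},
            {"n_trials_per_cell": 0},
            {"mean_rr": 300.0},
            {"lf_amp": -1.0},
            {"mean_rr": 400.0, "lf_amp": 80.0, "hf_amp": 80.0},  # RR floor
            {"ecg_fs": 50.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            SimConfig(**kw)

    def test_named_rng_streams_are_independent_and_reproducible(self):
        cfg = study1_config(seed=5)
        a = cfg.rng("x").standard_normal(4)
        b = cfg.rng("x").standard_normal(4)
        c = cfg.rng("y").standard_normal(4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_json_round_trip(self, tmp_path):
        cfg = study2_config(seed=9, hf_amp=12.5)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert SimConfig.from_json(path) == cfg


class TestRatingsStudy1:
    def test_design_completeness_and_bounds(self, tiny_study1):
        df = simulate_ratings_study1(tiny_study1)
        cells = df.groupby(
            ["participant", "tdcs_type", "task", "stim_type", "scale"]
        ).size()
        assert (cells == tiny_study1.n_trials_per_cell).all()
        assert len(cells) == 6 * 2 * 2 * 2 * 2
        assert df["value"].between(0, 10).all()

    def test_determinism(self, tiny_study1):
        a = simulate_ratings_study1(tiny_study1)
        b = simulate_ratings_study1(tiny_study1)
        pd.testing.assert_frame_equal(a, b)

    def test_null_effect_centers_pain_contrast_at_zero(self):
        diffs = []
        for seed in range(20):
            cfg = study1_config(n_participants_per_group=4,
                                n_trials_per_cell=12,
                                rating_effect_pain=0.0,
                                rating_effect_rtpj=0.0, seed=seed)
            df = simulate_ratings_study1(cfg)
            other = df[df["scale"] == "other"]
            m = other.groupby("stim_type")["value"].mean()
            diffs.append(m["pain"] - m["nonpain"])
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 0.05

    def test_strong_effect_orders_condition_medians(self):
        """With a 3-SD latent shift, nearly every participant's painful
        median rating should dominate (Monte-Carlo over seeds)."""
        wins = total = 0
        for seed in range(30):
            cfg = study1_config(n_participants_per_group=2,
                                n_trials_per_cell=10,
                                rating_effect_pain=3.0, seed=seed)
            df = simulate_ratings_study1(cfg)
            other = df[df["scale"] == "other"]
            med = other.groupby(["participant", "stim_type"])["value"].median()
            for pid in other["participant"].unique():
                total += 1
                wins += med[pid, "pain"] >= med[pid, "nonpain"]
        assert wins / total >= 0.95

    def test_wrong_design_rejected(self, tiny_study2):
        with pytest.raises(ConfigurationError):
            simulate_ratings_study1(tiny_study2)


class TestRatingsStudy2:
    def test_design_and_bounds(self, tiny_study2):
        df = simulate_ratings_study2(tiny_study2)
        cells = df.groupby(
            ["participant", "valence", "time", "scale"]
        ).size()
        assert (cells == tiny_study2.n_trials_per_cell).all()
        assert len(cells) == 9 * 3 * 2 * 4
        assert df["value"].between(1, 9).all()

    def test_determinism(self, tiny_study2):
        pd.testing.assert_frame_equal(
            simulate_ratings_study2(tiny_study2),
            simulate_ratings_study2(tiny_study2),
        )

    def test_rtpj_cognitive_boost_recovered(self):
        """A +2-SD post boost on cognitive scales should beat sham on
        Δcontent in nearly all seeds."""
        wins = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = study2_config(n_participants_per_group=6,
                                n_trials_per_cell=2,
                                rating_effect_rtpj=2.0, seed=seed)
            df = simulate_ratings_study2(cfg)
            content = df[df["scale"] == "content"]
            m = content.groupby(["group", "time"])["value"].mean()
            d_rtpj = m["rtpj", "post"] - m["rtpj", "pre"]
            d_sham = m["sham", "post"] - m["sham", "pre"]
            wins += d_rtpj > d_sham
        assert wins / n_seeds >= 0.95


class TestEpochs:
    def test_montage_and_window(self, tiny_study1):
        epochs, truth = simulate_epochs_study1(tiny_study1)
        assert "CP1" in epochs.channel_names and "CP2" in epochs.channel_names
        assert epochs.t_start == -1.0
        assert epochs.times[-1] == pytest.approx(3.0 - 1 / epochs.fs)
        assert len(truth.true_labels) == epochs.n_epochs

    def test_noise_free_amplitude_matches_quadrature_oracle(self):
        """Mean 0.5-1.0 s voltage at CP1 equals amplitude x the window
        overlap of the hump, integrated independently."""
        cfg = study1_config(n_participants_per_group=1, n_trials_per_cell=1,
                            eeg_noise_sd=0.0, lpp_amp_pain=5.0, seed=0)
        epochs, _ = simulate_epochs_study1(cfg, cells=[("sham", "somatic")])
        lab = epochs.trial_labels
        i = lab.index[lab["stim_type"] == "pain"][0]
        cp1 = epochs.channel_index("CP1")
        times = epochs.times
        win = (times >= 0.5) & (times < 1.0)
        measured = epochs.data[i, cp1, win].mean()
        expected = 5.0 * quad(lpp_hump, 0.5, 1.0)[0] / 0.5
        assert measured == pytest.approx(expected, rel=0.01)

    def test_prestimulus_mean_is_zero(self, tiny_study1):
        epochs, _ = simulate_epochs_study1(tiny_study1)
        pre = epochs.times < 0
        assert np.allclose(epochs.data[:, :, pre].mean(axis=2), 0.0, atol=1e-9)

    def test_equal_amplitudes_give_null_delta(self):
        cfg = study1_config(n_participants_per_group=2, n_trials_per_cell=4,
                            lpp_amp_pain=5.0, lpp_amp_nonpain=5.0,
                            lpp_effect_rtpj=0.0, seed=1)
        epochs, truth = simulate_epochs_study1(cfg, cells=[("sham", "somatic")])
        amps = np.array(truth.true_condition_effects["trial_amplitudes"])
        assert np.all(amps == 5.0)

    def test_determinism(self, tiny_study1):
        a, _ = simulate_epochs_study1(tiny_study1)
        b, _ = simulate_epochs_study1(tiny_study1)
        assert np.array_equal(a.data, b.data)


class TestRri:
    def test_degenerate_series_is_constant(self):
        cfg = study2_config(lf_amp=0.0, hf_amp=0.0, rr_jitter_sd=0.0, seed=0)
        rri, _ = simulate_rri(cfg, 90)
        assert np.allclose(rri.rr_intervals, cfg.mean_rr)

    def test_hf_only_concentrates_power_downstream(self):
        from empathkit.hrv import hrv_frequency_domain

        cfg = study2_config(lf_amp=0.0, hf_amp=25.0, rr_jitter_sd=0.0, seed=0)
        rri, _ = simulate_rri(cfg, 300)
        fd = hrv_frequency_domain(rri)
        assert fd.hf_power > 10 * fd.lf_power

    def test_ldlpfc_post_cell_boosts_modulation(self):
        cfg = study2_config(seed=4, hrv_effect_ldlpfc=1.5)
        _, truth_pre = simulate_rri(cfg, 90, cell={"group": "ldlpfc", "time": "pre"})
        _, truth_post = simulate_rri(cfg, 90, cell={"group": "ldlpfc", "time": "post"})
        assert truth_post.true_condition_effects["lf_amp"] == pytest.approx(
            1.5 * truth_pre.true_condition_effects["lf_amp"]
        )

    def test_non_physiological_rr_raises(self):
        cfg = study2_config(seed=0)
        object.__setattr__(cfg, "mean_rr", 240.0)  # bypass config validation
        with pytest.raises(GenerationError):
            simulate_rri(cfg, 60)

    def test_determinism(self, tiny_study2):
        a, _ = simulate_rri(tiny_study2, 90, cell={"group": "sham", "time": "pre"})
        b, _ = simulate_rri(tiny_study2, 90, cell={"group": "sham", "time": "pre"})
        assert np.array_equal(a.peak_times, b.peak_times)


class TestEcgWaveform:
    def test_noise_free_maxima_at_true_r_times(self, tiny_study2):
        rri, gt = simulate_rri(tiny_study2, 90, cell={"group": "sham", "time": "pre"})
        trace, _ = simulate_ecg_waveform(rri, tiny_study2, noise_sd=0.0,
                                         wander_amp=0.0)
        fs = trace.fs
        for t_true in gt.true_r_peak_times[1:-1] / 1000.0:
            center = int(round(t_true * fs))
            seg = trace.samples[center - 20 : center + 21]
            assert abs(np.argmax(seg) - 20) <= 1  # within one sample

    def test_template_peaks_at_r(self):
        t = np.linspace(-0.4, 0.4, 2001)
        assert abs(t[np.argmax(ecg_template(t))]) < 1e-3

    def test_determinism(self, tiny_study2):
        rri, _ = simulate_rri(tiny_study2, 90, cell={"group": "sham", "time": "pre"})
        a, _ = simulate_ecg_waveform(rri, tiny_study2)
        b, _ = simulate_ecg_waveform(rri, tiny_study2)
        assert np.array_equal(a.samples, b.samples)
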