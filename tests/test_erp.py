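"""ERP preprocessing chain and LPP extraction."""

import numpy as np
import pandas as pd
import pytest

from empathkit.containers import EpochSet
from empathkit.erp import (
    bandpass,
    baseline_correct,
    condition_average,
    delta_lpp,
    delta_lpp_table,
    epoch,
    extract_lpp,
    lpp_table,
    reject_artifacts,
    rereference_average,
    LppFeatures,
)
from empathkit.errors import ValidationError

FS = 250.0


def make_epochs(data, labels=None, t_start=-1.0, channels=None):
    data = np.asarray(data, dtype=float)
    if channels is None:
        channels = [f"ch{i}" for i in range(data.shape[1])]
    if labels is None:
        labels = pd.DataFrame({"cond": ["a"] * data.shape[0]})
    return EpochSet(data=data, fs=FS, t_start=t_start,
                    channel_names=channels, trial_labels=labels)


class TestBandpass:
    @staticmethod
    def _tone_gain(freq):
        """Measured gain of a pure tone through the filter (demodulated over
        the middle half, which excludes the slow 0.1 Hz edge transients)."""
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(x[None, :], FS)[0]
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        return 2.0 * abs(np.mean(y[mid] * np.exp(-2j * np.pi * freq * t[mid])))

    def test_passband_tone_preserved(self):
        assert self._tone_gain(5.0) == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_attenuated_per_analytic_response(self):
        """45 Hz through the 0.1-30 Hz zero-phase filter: attenuation >= 90%
        and consistent with |H(45)|^2 from the filter's own transfer
        function (the forward-backward pass squares the response)."""
        from scipy import signal as sps

        sos = sps.butter(4, [0.1, 30.0], btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[45.0], fs=FS)
        analytic = float(np.abs(h[0]) ** 2)
        measured = self._tone_gain(45.0)
        assert measured < 0.10
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_dc_rejected(self):
        y = bandpass(np.full((1, 5000), 3.0), FS)
        assert np.abs(y).max() < 0.05

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            bandpass(np.zeros((1, 1000)), FS, low=0.1, high=200.0)


class TestEpoching:
    def test_slicing_identity_on_ramp(self):
        t = np.arange(0, 20, 1 / FS)
        ramp = t.copy()
        eps, dropped = epoch(ramp[None, :], FS, [10.0], window=(-1.0, 3.0))
        assert dropped == 0
        assert np.allclose(eps.data[0, 0], t[(t >= 9.0) & (t < 13.0)])

    def test_identical_onsets_give_identical_epochs(self, rng):
        x = rng.standard_normal((2, 5000))
        eps, _ = epoch(x, FS, [8.0, 8.0])
        assert np.array_equal(eps.data[0], eps.data[1])

    def test_out_of_bounds_onset_flagged(self):
        x = np.zeros((1, int(20 * FS)))
        eps, dropped = epoch(x, FS, [10.0, 19.5])
        assert dropped == 1 and eps.n_epochs == 1


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        eps = make_epochs(np.full((1, 2, 1000), 7.0))
        out = baseline_correct(eps)
        assert np.allclose(out.data, 0.0)

    def test_plateau_arithmetic(self):
        n = 1000
        data = np.zeros((1, 1, n))
        times = -1.0 + np.arange(n) / FS
        data[0, 0, times < 0] = 2.0
        data[0, 0, times >= 0] = 5.0
        out = baseline_correct(make_epochs(data))
        assert np.allclose(out.data[0, 0, times >= 0], 3.0)

    def test_idempotent(self, rng):
        eps = make_epochs(rng.standard_normal((3, 2, 1000)))
        once = baseline_correct(eps)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data)


class TestArtifactRejection:
    def test_clean_set_untouched(self, rng):
        eps = make_epochs(10.0 * rng.standard_normal((5, 2, 200)))
        out = reject_artifacts(eps, threshold=1e9)
        assert not out.reject_mask.any()

    def test_injected_spike_masks_exactly_that_epoch(self, rng):
        data = 5.0 * rng.standard_normal((6, 2, 200))
        data[3, 1, 50] += 500.0
        out = reject_artifacts(make_epochs(data), threshold=100.0)
        # oracle: direct peak-to-peak scan
        expected = (data.max(axis=2) - data.min(axis=2) > 100.0).any(axis=1)
        assert np.array_equal(out.reject_mask, expected)
        assert out.reject_mask[3] and out.reject_mask.sum() == 1


class TestRereference:
    def test_antisymmetric_pair_unchanged(self, rng):
        a = rng.standard_normal((2, 1, 300))
        data = np.concatenate([a, -a], axis=1)  # channel mean already zero
        out = rereference_average(make_epochs(data))
        assert np.allclose(out.data, data)

    def test_identical_channels_become_zero(self):
        data = np.tile(np.arange(100.0), (2, 3, 1))
        out = rereference_average(make_epochs(data))
        assert np.allclose(out.data, 0.0)

    def test_single_channel_rejected(self):
        with pytest.raises(ValidationError):
            rereference_average(make_epochs(np.zeros((1, 1, 100))))

    def test_commutes_with_baseline(self, rng):
        """Both operations are linear projections, so the order is free."""
        eps = make_epochs(rng.standard_normal((4, 3, 1000)))
        ab = rereference_average(baseline_correct(eps))
        ba = baseline_correct(rereference_average(eps))
        assert np.allclose(ab.data, ba.data, atol=1e-12)


class TestConditionAverage:
    def test_opposite_epochs_cancel(self, rng):
        x = rng.standard_normal((1, 2, 100))
        data = np.concatenate([x, -x], axis=0)
        eps = make_epochs(data, labels=pd.DataFrame({"cond": ["a", "a"]}))
        means = condition_average(eps, by=["cond"])
        assert np.allclose(means[("a",)], 0.0)

    def test_masked_epochs_excluded(self, rng):
        data = rng.standard_normal((3, 2, 100))
        eps = make_epochs(data, labels=pd.DataFrame({"cond": ["a"] * 3}))
        eps.reject_mask[1] = True
        means = condition_average(eps, by=["cond"])
        manual = data[[0, 2]].mean(axis=0)  # oracle: mean over unmasked subset
        assert np.allclose(means[("a",)], manual)

    def test_empty_condition_flagged(self, rng):
        data = rng.standard_normal((2, 2, 100))
        eps = make_epochs(data, labels=pd.DataFrame({"cond": ["a", "b"]}))
        eps.reject_mask[0] = True
        means = condition_average(eps, by=["cond"])
        assert means[("a",)] is None


class TestLppExtraction:
    def test_constant_waveform(self):
        wf = np.full((2, 1000), 4.0)
        feats = extract_lpp(wf, FS, -1.0, ["CP1", "CP2"])
        assert feats.early_lpp == pytest.approx(4.0)
        assert feats.late_lpp == pytest.approx(4.0)

    def test_boxcar_window_algebra(self):
        n = 1000
        times = -1.0 + np.arange(n) / FS
        wf = np.zeros((2, n))
        wf[:, (times >= 0.5) & (times < 1.0)] = 6.0
        feats = extract_lpp(wf, FS, -1.0, ["CP1", "CP2"])
        assert feats.early_lpp == pytest.approx(6.0)
        assert feats.late_lpp == pytest.approx(0.0)

    def test_missing_channel_named_in_error(self):
        with pytest.raises(ValidationError, match="CP2"):
            extract_lpp(np.zeros((1, 1000)), FS, -1.0, ["CP1"])


class TestDeltaLpp:
    def test_subtraction_and_antisymmetry(self):
        pain = LppFeatures(5.0, 4.0, labels={"participant": "p0"})
        nonpain = LppFeatures(2.0, 4.0, labels={"participant": "p0"})
        d = delta_lpp(pain, nonpain)
        assert (d.early_delta, d.late_delta) == (3.0, 0.0)
        flipped = delta_lpp(nonpain, pain)
        assert flipped.early_delta == -d.early_delta

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            delta_lpp(LppFeatures(1, 1, labels={"participant": "p0"}),
                      LppFeatures(1, 1, labels={"participant": "p1"}))


class TestPipelineLinearity:
    def test_noise_free_lpp_matches_generator_oracle(self):
        """End-to-end: baseline + table extraction on noise-free epochs
        reproduce amplitude x analytic window overlap to < 1%."""
        from scipy.integrate import quad

        from empathkit.config import study1_config
        from empathkit.synth import lpp_hump, simulate_epochs_study1

        cfg = study1_config(n_participants_per_group=1, n_trials_per_cell=2,
                            eeg_noise_sd=0.0, lpp_amp_pain=8.0,
                            lpp_amp_nonpain=5.0, lpp_effect_rtpj=0.0, seed=0)
        epochs, _ = simulate_epochs_study1(cfg, cells=[("sham", "somatic")])
        epochs = baseline_correct(epochs)
        table = lpp_table(epochs)
        w_early = quad(lpp_hump, 0.5, 1.0)[0] / 0.5
        pain = table[table["stim_type"] == "pain"]["early_lpp"]
        assert np.allclose(pain, 8.0 * w_early, rtol=0.01)
        dlpp = delta_lpp_table(table)
        assert np.allclose(dlpp["early_delta"], 3.0 * w_early, rtol=0.01)
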