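# empathkit

A multimodal empathy-physiology analysis pipeline, built as a tested,
reusable implementation of the measurement chain used in two-study tDCS
(transcranial direct current stimulation) empathy experiments:

1. **Rating-based signal detection.** Ordinal unpleasantness ratings for
   painful vs nonpainful pictures are treated as implicit decision
   criteria: for every criterion *c* on the 0–10 scale, hit rate
   P(rating ≥ c | painful) is plotted against false-alarm rate
   P(rating ≥ c | nonpainful), and the trapezoidal area under the curve
   (AUC) gives a response-bias-free discriminability index, identical to
   the rank statistic P(X > Y) + ½ P(X = Y).
2. **ERP late positive potential (LPP).** Stimulus-locked EEG epochs
   (−1.0 … 3.0 s) are band-pass filtered (0.1–30 Hz, zero-phase),
   baseline-corrected, threshold-rejected (±100 µV peak-to-peak),
   common-average re-referenced and condition-averaged; the LPP is the mean
   voltage at CP1/CP2 in the early (0.5–1.0 s) and late (1.0–3.0 s)
   windows, with ΔLPP = painful − nonpainful as the neural responsiveness
   index.
3. **ECG → heart-rate variability (HRV).** Ensemble empirical mode
   decomposition (EEMD) denoising, extreme-point R-peak detection with an
   adaptive amplitude threshold and 250 ms refractory period, rolling-median
   RR-interval correction, and ten HRV indices: HR, SDNN, RMSSD, pNN50
   (time domain); LF (0.04–0.15 Hz), HF (0.15–0.40 Hz) band powers and
   LF/HF from a Welch periodogram of the resampled tachogram; sample
   entropy and Poincaré SD1/SD2/SD1-SD2 (nonlinear).
4. **Multimodal decoding.** Rating means + LPP amplitudes (binary
   painful/nonpainful) or rating means + HRV indices (3-class valence) are
   decoded under leave-one-out cross-validation with five classifier
   families (LR, KNN, RF, SVM, NB), reporting accuracy, one-vs-rest ROC
   curves and Cohen's κ = (p_o − p_e)/(1 − p_e).

Because the underlying human data are not available, the package ships a
first-class **synthetic cohort generator** that emulates both study designs
with known ground truth (latent-normal ordinal ratings, 1/f-noise epochs
with a half-cosine LPP hump, sinusoidally modulated RR series rendered to a
P-QRS-T ECG template), so every stage can be validated by parameter
recovery rather than by comparison to irreproducible human results.  It is
aimed at psychophysiology researchers who want a transparent, testable
version of this analysis chain.

## Worked example

```python
from empathkit.config import study2_config
from empathkit.synth import simulate_rri, simulate_ecg_waveform
from empathkit.hrv import detect_r_peaks, correct_rri, hrv_profile

cfg = study2_config(seed=3)
rri, truth = simulate_rri(cfg, duration_s=300)
trace, _ = simulate_ecg_waveform(rri, cfg, noise_sd=0.05)
det = correct_rri(detect_r_peaks(trace))
prof = hrv_profile(det)
print(f"HR {prof.hr:.1f} bpm, SDNN {prof.sdnn:.1f} ms, "
      f"RMSSD {prof.rmssd:.1f} ms, LF/HF {prof.lf_hf:.2f}")
```

prints

```
HR 75.0 bpm, SDNN 30.8 ms, RMSSD 30.9 ms, LF/HF 1.10
```

i.e. the detector recovered the generated beat series (mean RR 800 ms →
75 bpm) and the variability indices reflect the configured 30 ms/25 ms
LF/HF modulation depths plus 15 ms beat-to-beat jitter (the jitter adds
broadband power, pulling the measured LF/HF below the noiseless ratio
(30/25)² = 1.44; with low jitter the estimate lands on the analytic value).

The numbered drivers under `analysis/` run the full narrative:
`01_simulate_cohorts.py` (synthetic cohorts), `02_sdt_auc.py` (criterion
sweep and per-cell AUC), `03_erp_lpp.py` (LPP/ΔLPP extraction),
`04_ecg_hrv.py` (ECG chain and HRV change scores), `05_decode.py`
(leave-one-out decoding and its chance calibration), `06_recovery.py`
(direction-of-effect recovery over seeds).  Each writes tidy tables under
`results/`.  A thin CLI mirrors the stages
(`empathkit simulate|sdt-auc|erp-lpp|hrv|decode|pipeline`).

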