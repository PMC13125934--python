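# Methods

This note documents the models, conventions and design choices behind
`empathkit`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cohort model

The generator emulates the statistical structure of two experimental
designs with known ground truth; it makes no claim to biophysical realism.

**Designs.** Study 1: 2 stimulation targets (lDLPFC, rTPJ;
between-subjects) × 2 stimulation types (real, sham; within) × 2 tasks
(somatic, affective) × 2 picture types (painful, nonpainful), default 38
participants per group and 30 trials per cell, two 0–10 ratings per trial
("other" = protagonist's pain, "self" = own unpleasantness).  Study 2: 3
groups (lDLPFC, rTPJ, sham; between) × 3 clip valences × 2 time points
(pre/post), default 40 per group and 4 two-minute clips per cell, four 1–9
ratings per clip (content understanding, emotion understanding, empathic
concern, emotional contagion).  The 1–9 bound follows the task
description; it is configurable because a 0–10 variant also circulates for
this paradigm.

**Ratings.** A latent-normal model: participant intercept (SD 0.5) +
condition shift + unit-SD trial noise, discretised by rounding onto the
integer scale (equal-width one-SD bins) and clipping.  Effect parameters
are therefore latent shifts in SD units: `rating_effect_pain` (default
1.5) separates painful from nonpainful pictures; `rating_effect_rtpj`
(default 0.5) adds to other-ratings of painful pictures under real rTPJ
stimulation (study 1) and to the two cognitive scales post-stimulation in
the rTPJ group (study 2); `rating_effect_valence` (default 1.0) shifts
emotional vs neutral clips with a scale-specific profile (negative clips
load on concern/contagion, both emotional valences on the cognitive
scales).  Defaults were chosen once to give realistic discriminability
(cell AUCs ≈ 0.8) and are not tuned to any downstream check.

**EEG epochs.** −1.0 … 3.0 s at 250 Hz (desk-scale; all window logic is in
seconds, so the rate is free) on an 8-channel montage peaking at CP1/CP2,
with CPz standing in for the online reference site.  Each epoch is
1/f-amplitude-shaped Gaussian noise (SD 10 µV per channel, the prestimulus
mean removed at generation) plus a half-cosine-ramped plateau (rise
0.4–0.6 s, fall 2.8–3.0 s) of amplitude `lpp_amp_pain` (8 µV) or
`lpp_amp_nonpain` (5 µV), plus `lpp_effect_rtpj` (1.5 µV) on painful
trials in real-rTPJ cells, spatially weighted per channel.  The hump
function is exported (`synth.lpp_hump`) so tests can integrate the exact
shape the generator uses.

**RR series and ECG.** RR(t) = mean RR (800 ms) + 30 ms·sin(2π·0.10·t) +
25 ms·sin(2π·0.25·t) + N(0, 15 ms), accumulated beat-to-beat; deterministic
sinusoids give a closed-form spectral ground truth (band-power ratio
a_LF²/a_HF²).  Post-stimulation lDLPFC cells multiply depths and jitter by
`hrv_effect_ldlpfc` (1.3).  Any generated RR ≤ 250 ms raises a generation
error, and the configuration validator enforces
mean_rr − boost·(a_LF + a_HF + 3·jitter) > 250 ms up front.  The
continuous ECG places a fixed P-QRS-T sum-of-Gaussians template (R
amplitude 1 mV) at each beat time, plus white noise and a < 0.5 Hz
baseline-wander sinusoid; template peak times are the ground-truth R
times.

**What the generator does not model** (and hence what passing tests do not
show about real data): ocular/muscle artifacts and volume conduction
beyond fixed spatial weights, 1/f slope fitting, ectopic-beat pathologies,
respiration–RSA coupling, rater idiosyncrasies beyond a single intercept.
Recovery results demonstrate that the pipeline measures what the generator
plants — not that real effects of this size exist.

**Reproducibility.** One global seed fans out to named child streams
(CRC-32 of the stream name combined with the seed in a `SeedSequence`), so
identical configs are bit-identical and individual modalities can be
regenerated independently.

## Signal detection

The criterion set is every value of the declared scale (plus a
pseudo-criterion above it), not only observed ratings, so curves are
comparable across cells; AUC is unchanged either way by the rank
equivalence, which the suite property-tests exactly (trapezoid over the
(fa, hit)-sorted curve ≡ Mann–Whitney with ½ credit for ties).  Cells
missing a condition or with < 2 trials per condition are flagged
`insufficient`, never silently dropped.

## ERP pipeline

Zero-phase 4th-order Butterworth (forward–backward) for the 0.1–30 Hz
band; windows are half-open [start, end) in seconds; channel average is
taken before time average (irrelevant for means, fixed for determinism).
Manual artifact screening is replaced by a ±100 µV peak-to-peak threshold
so the pipeline is automatic; ICA is deliberately out of scope because the
generator contains no ocular components, and the post-ICA second baseline
therefore collapses into the single baseline.  Note that common-average
re-referencing attenuates the centroparietal LPP by the montage-mean
spatial weight (≈ ×0.31 on the 8-channel montage): absolute amplitudes
shrink but all painful-vs-nonpainful and real-vs-sham contrasts scale
together, so ΔLPP comparisons are unaffected in direction.  Missing cells
are flagged and excluded from downstream summaries rather than imputed.

## EEMD and denoising

Standard sifting (cubic-spline envelopes through maxima/minima with
mirrored end extrema; Cauchy-type SD stop at 0.2, max 10 sifts, max 10
IMFs); a monotone signal returns residue only.  EEMD averages IMFs
rank-wise across members perturbed with white noise of SD 0.2 × signal SD
(ensemble default 100); the residue is the ensemble mean of member
residues, so the reconstruction equals the input plus the mean added
noise — exact with zero noise, and improving as 1/√ensemble, which the
suite measures directly.  Denoising keeps IMFs whose spectral centroid
lies in [0.5, 45] Hz, treating faster leading IMFs as broadband noise and
the slow tail plus residue as baseline wander; if everything would be
dropped the original trace is returned with a warning.

## R-peak detection and RR correction

Local maxima above `threshold_fraction` (0.5) × a rolling amplitude level
(99.9th percentile per 2-s block, interpolated per sample — i.e. the local
R-wave height; a lower quantile admits T waves), with a 250 ms refractory
period resolved in favour of the larger candidate.  Intervals deviating
more than 30% from an 11-beat rolling median are cubically interpolated
from their neighbours and flagged; more than 20% flagged rejects the
series as unusable rather than guessing.

## HRV conventions

Population variance (divide by n) throughout.  Successive RR differences
are treated as a zero-mean process, so SD1 is computed from the
*uncentred* mean square of the differences: SD1 = √(msd/2) = RMSSD/√2
exactly, an identity asserted on every profile; SD2² = 2·Var(rr) − msd/2,
clamped at zero with a warning if rounding drives it negative.  Frequency
indices come from cubic resampling of the tachogram to 4 Hz, mean/linear
detrending, and Welch averaging (Hann, 120-s segments, 50% overlap), with
band powers integrated over [0.04, 0.15) and [0.15, 0.40) Hz; LF/HF is
reported missing (not infinite) when HF is zero.  Sample entropy uses
m = 2, r = 0.2·SD(rr), Chebyshev distance, self-matches excluded, with
n − m templates at both lengths; B = 0 yields a missing value with a
recorded reason, and a constant series yields exactly 0 (A = B).  The
analytic LF/HF ratio a_LF²/a_HF² describes only the deterministic
modulation, so the spectral-calibration check runs at low jitter (5 ms);
at the default 15 ms jitter the broadband term legitimately shifts the
measured ratio.  HRV is computed per 2-minute trial and averaged within
each participant × condition × time cell (a pooled run over concatenated
trials is possible by passing a longer series).

## Decoding

Feature rows are participant × condition aggregates: mean self/other
rating + early/late LPP (binary task), or the four rating means + the ten
HRV indices (valence task).  Features enter on their original scale — no
standardisation — which is a deliberate, documented caveat for the
distance-based families (KNN, SVM).  Hyperparameters: LR with mild ridge
(C = 1) and lbfgs capped at 300 iterations (the unscaled features make
full convergence slow and immaterial); KNN k = 5 Euclidean; RF 300 trees
(seeded; 16 trees inside repeated seed sweeps, where chance and direction
behaviour are tree-count-insensitive); RBF SVM scored by a monotone
transform of its decision values (sigmoid/softmax); Gaussian NB.

**Chance calibration.** Under leave-one-out with exactly balanced classes,
every training fold is short one sample of the held-out class; classifiers
that follow the training prior are then systematically biased *against*
the held-out class and score below 1/K on informationless data (a
well-known LOOCV artifact — a pure majority-vote rule scores 0%).  All
families therefore run with balanced class priors (`class_weight=
"balanced"`; uniform priors for NB), which restores calibration at the
50% / 33.3% chance lines without affecting separable problems.  KNN has no
prior to balance; its residual bias is small.  Cross-validation is
leave-one-row-out by default, with a leave-one-participant-out option
because the default ignores within-participant row correlation.  Multiclass
ROC is one-vs-rest with macro averaging; Cohen's κ is computed from the
pooled held-out confusion matrix, with κ defined as 0 (with a warning)
when the expected agreement is 1.

## Pipeline and inference scope

`run_study1`/`run_study2` compose the stages in a fixed order, log stage
counts (epochs rejected, intervals corrected, rows dropped), and write a
manifest (config hash, seed, library versions, counts); a run re-executed
from its config and seed is bit-identical.  Factorial ANOVA and post-hoc
inference are intentionally not reimplemented: the pipeline emits tidy
tables for any standard statistics environment, and its own validation
uses direct Monte-Carlo comparisons over seeds (means ± SE of real-vs-sham
or group differences) rather than F-tests.

## Problem sizes of the standing checks

The chance-calibration sweeps use 80 rows (binary; 40 participants × 2
conditions, 6 trials per cell) and 45 rows (3-class; 15 participants × 3
valences, one 2-minute clip per cell) over 100 repetitions with fresh
labels permuted each repetition; direction-of-effect recovery uses 100
seeds at 10 (study 1) / 8 (study 2) participants per group.  These sizes
were chosen as the smallest at which the Monte-Carlo standard errors make
the sign checks meaningful (recovered effects ≥ 2 SE, nulls within 3 SE);
the quantities checked are chance levels and seed-averaged signs, which do
not depend on cohort scale.

## Known limitations

* The generator's effect sizes are stand-ins; absolute decoding accuracies
  are not comparable to any human dataset.
* EEMD at full ensemble size on long 1 kHz traces is expensive; the
  pipeline defaults to the RR-series route and offers the full ECG chain
  (rendering, optional EEMD denoising, re-detection) as an option.
* Threshold artifact rejection cannot stand in for ICA on real EEG with
  ocular components.
* Sample entropy is reported only for ≥ 50 intervals; shorter series get a
  missing value with a reason, not a number.
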