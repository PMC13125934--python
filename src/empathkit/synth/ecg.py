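"""Synthetic RR-interval series and continuous ECG with known ground truth.

The tachogram is deterministic sinusoidal modulation (0.10 Hz "LF", 0.25 Hz
"HF") around a mean RR plus Gaussian beat-to-beat jitter, which gives a
closed-form spectral ground truth (band-power ratio lf_amp²/hf_amp²).  The
continuous trace places a fixed P-QRS-T sum-of-Gaussians template at each
beat time, plus white noise and slow baseline wander.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimConfig
from ..containers import EcgTrace, GroundTruth, RriSeries
from ..errors import ConfigurationError, GenerationError

LF_HZ = 0.10
HF_HZ = 0.25

#: P-QRS-T template: (time offset s, amplitude mV, Gaussian width s)
ECG_WAVES = (
    (-0.200, 0.15, 0.025),   # P
    (-0.030, -0.10, 0.010),  # Q
    (0.000, 1.00, 0.010),    # R
    (0.030, -0.15, 0.010),   # S
    (0.250, 0.30, 0.060),    # T
)

R_AMPLITUDE = ECG_WAVES[2][1]


def ecg_template(t: np.ndarray) -> np.ndarray:
    """Evaluate the beat template at times ``t`` (s, relative to the R peak)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for offset, amp, width in ECG_WAVES:
        out += amp * np.exp(-0.5 * ((t - offset) / width) ** 2)
    return out


def simulate_rri(
    cfg: SimConfig,
    duration_s: float,
    cell: dict | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RriSeries, GroundTruth]:
    """Generate beat times whose successive intervals follow the modulated RR law.

    ``cell`` carries design labels; when it marks a post-stimulation lDLPFC
    cell (``{"group": "ldlpfc", "time": "post"}``) the modulation depths and
    jitter are multiplied by ``cfg.hrv_effect_ldlpfc``.
    """
    if duration_s < 60:
        raise ConfigurationError("duration_s must be >= 60 s")
    cell = cell or {}
    boost = 1.0
    if cell.get("group") == "ldlpfc" and cell.get("time") == "post":
        boost = cfg.hrv_effect_ldlpfc
    lf, hf, jitter = boost * cfg.lf_amp, boost * cfg.hf_amp, boost * cfg.rr_jitter_sd
    if rng is None:
        rng = cfg.rng(f"rri_{sorted(cell.items())}")

    peak_times = [0.0]
    t = 0.0
    while t < duration_s:
        rr = (
            cfg.mean_rr
            + lf * np.sin(2 * np.pi * LF_HZ * t)
            + hf * np.sin(2 * np.pi * HF_HZ * t)
            + jitter * rng.standard_normal()
        )
        if rr <= 250.0:
            raise GenerationError(f"non-physiological RR of {rr:.1f} ms generated")
        t += rr / 1000.0
        peak_times.append(t)

    times_ms = np.asarray(peak_times) * 1000.0
    series = RriSeries(peak_times=times_ms)
    truth = GroundTruth(
        true_r_peak_times=times_ms,
        true_condition_effects={
            "mean_rr": cfg.mean_rr,
            "lf_amp": lf,
            "hf_amp": hf,
            "jitter_sd": jitter,
            "boost": boost,
            "cell": dict(cell),
        },
    )
    return series, truth


def simulate_ecg_waveform(
    rri: RriSeries,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
    wander_amp: float | None = None,
) -> tuple[EcgTrace, GroundTruth]:
    """Render a continuous ECG trace from beat times.

    ``noise_sd`` / ``wander_amp`` override the config values (mV); set both
    to 0 for a noise-free trace whose maxima coincide with the true R times.
    """
    if cfg.ecg_fs < 100:
        raise ConfigurationError("ecg_fs too low to resolve the QRS (< 100 Hz)")
    if rri.n_beats < 2:
        raise ConfigurationError("need at least two beats")
    beat_s = rri.peak_times / 1000.0
    if np.any(np.diff(beat_s) <= 0):
        raise ConfigurationError("beat times must be strictly increasing")
    noise_sd = cfg.ecg_noise_sd if noise_sd is None else noise_sd
    wander_amp = cfg.ecg_wander_amp if wander_amp is None else wander_amp
    if rng is None:
        rng = cfg.rng("ecg_waveform")

    fs = cfg.ecg_fs
    n_samples = int(np.ceil((beat_s[-1] + 0.5) * fs)) + 1
    trace = np.zeros(n_samples)
    # place the template sparsely: +-0.45 s covers all five waves
    half = int(round(0.45 * fs))
    for tb in beat_s:
        center = int(round(tb * fs))
        lo, hi = max(center - half, 0), min(center + half + 1, n_samples)
        t_rel = np.arange(lo, hi) / fs - tb
        trace[lo:hi] += ecg_template(t_rel)

    t_axis = np.arange(n_samples) / fs
    trace += wander_amp * np.sin(2 * np.pi * cfg.ecg_wander_hz * t_axis)
    if noise_sd > 0:
        trace += noise_sd * rng.standard_normal(n_samples)

    truth = GroundTruth(
        true_r_peak_times=rri.peak_times.copy(),
        true_condition_effects={"noise_sd": noise_sd, "wander_amp": wander_amp},
    )
    return EcgTrace(samples=trace, fs=fs), truth
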