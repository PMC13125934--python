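"""Synthetic stimulus-locked EEG epochs with a condition-dependent LPP.

Each epoch spans -1.0 .. 3.0 s around picture onset and is the sum of
1/f-shaped background noise and a smooth positive hump (half-cosine-ramped
plateau) whose amplitude encodes the condition, spatially weighted to peak
at the centroparietal channels CP1/CP2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import STIM_TYPES, STUDY1, TASKS, TDCS_TARGETS, TDCS_TYPES, SimConfig
from ..containers import EpochSet, GroundTruth
from ..errors import ConfigurationError

#: Minimal centroparietal montage; CPz stands in for the online reference site.
MONTAGE = ["Fz", "Cz", "CPz", "CP1", "CP2", "Pz", "P3", "P4"]

#: Relative LPP projection per channel (peaks at CP1/CP2).
SPATIAL_WEIGHTS = np.array([0.25, 0.6, 0.9, 1.0, 1.0, 0.8, 0.5, 0.5])

EPOCH_START = -1.0   # s
EPOCH_END = 3.0      # s

# hump geometry (seconds, relative to onset)
_RISE_START, _RISE_END = 0.4, 0.6
_FALL_START, _FALL_END = 2.8, 3.0


def lpp_hump(t: np.ndarray) -> np.ndarray:
    """Unit-amplitude LPP time course: half-cosine rise 0.4-0.6 s, plateau,
    half-cosine fall 2.8-3.0 s, zero elsewhere.

    Exposed so tests can integrate the exact shape the generator uses.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= _RISE_START) & (t < _RISE_END)
    out[rising] = 0.5 * (
        1 - np.cos(np.pi * (t[rising] - _RISE_START) / (_RISE_END - _RISE_START))
    )
    out[(t >= _RISE_END) & (t < _FALL_START)] = 1.0
    falling = (t >= _FALL_START) & (t < _FALL_END)
    out[falling] = 0.5 * (
        1 + np.cos(np.pi * (t[falling] - _FALL_START) / (_FALL_END - _FALL_START))
    )
    return out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                sd: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, per-trace normalised to ``sd``."""
    if sd == 0:
        return np.zeros(shape + (n_samples,))
    n_freq = n_samples // 2 + 1
    spec = rng.standard_normal(shape + (n_freq,)) + 1j * rng.standard_normal(
        shape + (n_freq,)
    )
    freqs = np.fft.rfftfreq(n_samples)
    weights = np.zeros(n_freq)
    weights[1:] = 1.0 / np.sqrt(freqs[1:])
    noise = np.fft.irfft(spec * weights, n=n_samples, axis=-1)
    std = noise.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std * sd


def simulate_epochs_study1(
    cfg: SimConfig,
    cells: list[tuple[str, str]] | None = None,
) -> tuple[EpochSet, GroundTruth]:
    """Generate the full factorial epoch set for the picture task.

    Parameters
    ----------
    cfg
        Simulation configuration (``design`` must be ``study1``).
    cells
        Optional subset of ``(tdcs_type, task)`` cells to generate; default
        is the full 2 x 2 within-subject design.  Painful and nonpainful
        trials are always generated for every cell.

    Returns the epochs plus ground truth (per-trial target amplitudes).
    """
    if cfg.design != STUDY1:
        raise ConfigurationError("simulate_epochs_study1 requires design='study1'")
    n_samples = int(round((EPOCH_END - EPOCH_START) * cfg.eeg_fs))
    if n_samples < 4:
        raise ConfigurationError("epoch window incompatible with eeg_fs")
    rng = cfg.rng("epochs_study1")
    times = EPOCH_START + np.arange(n_samples) / cfg.eeg_fs
    hump = lpp_hump(times)
    prestim = times < 0.0

    if cells is None:
        cells = [(tt, task) for tt in TDCS_TYPES for task in TASKS]

    labels: list[dict] = []
    amps: list[float] = []
    blocks: list[np.ndarray] = []
    n_ch = len(MONTAGE)
    for target in TDCS_TARGETS:
        for p in range(cfg.n_participants_per_group):
            pid = f"{target}_{p:03d}"
            for tdcs_type, task in cells:
                for stim in STIM_TYPES:
                    amp = cfg.lpp_amp_pain if stim == "pain" else cfg.lpp_amp_nonpain
                    if stim == "pain" and target == "rtpj" and tdcs_type == "real":
                        amp += cfg.lpp_effect_rtpj
                    n_tr = cfg.n_trials_per_cell
                    noise = _pink_noise(rng, (n_tr, n_ch), n_samples, cfg.eeg_noise_sd)
                    signal = amp * SPATIAL_WEIGHTS[None, :, None] * hump[None, None, :]
                    epochs = noise + signal
                    # enforce ~zero prestimulus mean at generation
                    epochs -= epochs[:, :, prestim].mean(axis=2, keepdims=True)
                    blocks.append(epochs)
                    for trial in range(n_tr):
                        labels.append(
                            {
                                "participant": pid,
                                "tdcs_target": target,
                                "tdcs_type": tdcs_type,
                                "task": task,
                                "stim_type": stim,
                                "trial": trial,
                            }
                        )
                        amps.append(amp)

    data = np.concatenate(blocks, axis=0)
    label_df = pd.DataFrame(labels)
    epoch_set = EpochSet(
        data=data,
        fs=cfg.eeg_fs,
        t_start=EPOCH_START,
        channel_names=list(MONTAGE),
        trial_labels=label_df,
    )
    truth = GroundTruth(
        true_condition_effects={
            "lpp_amp_pain": cfg.lpp_amp_pain,
            "lpp_amp_nonpain": cfg.lpp_amp_nonpain,
            "lpp_effect_rtpj": cfg.lpp_effect_rtpj,
            "trial_amplitudes": amps,
        },
        true_labels=label_df.copy(),
    )
    return epoch_set, truth
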