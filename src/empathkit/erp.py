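"""EEG preprocessing and LPP feature extraction.

The chain mirrors a standard ERP pipeline: zero-phase 0.1-30 Hz band-pass,
stimulus-locked epoching (-1.0 .. 3.0 s), prestimulus baseline correction,
peak-to-peak threshold artifact rejection, common-average re-referencing,
per-condition averaging, and mean-voltage LPP amplitudes at CP1/CP2 in the
early (0.5-1.0 s) and late (1.0-3.0 s) windows, with the painful-minus-
nonpainful difference (ΔLPP) as the neural responsiveness index.

All windows are half-open ``[start, end)`` in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import EpochSet
from .errors import InsufficientDataError, ValidationError

log = logging.getLogger(__name__)

EARLY_WINDOW = (0.5, 1.0)
LATE_WINDOW = (1.0, 3.0)
LPP_CHANNELS = ("CP1", "CP2")
DEFAULT_BAND = (0.1, 30.0)
DEFAULT_REJECT_UV = 100.0


@dataclass
class LppFeatures:
    early_lpp: float  # µV
    late_lpp: float   # µV
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.early_lpp) and np.isfinite(self.late_lpp)):
            raise ValidationError("LPP features must be finite")


@dataclass
class DeltaLpp:
    early_delta: float
    late_delta: float
    labels: dict = field(default_factory=dict)


def bandpass(
    continuous: np.ndarray, fs: float, low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1], order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass over the last axis (forward-backward)."""
    if not (0 < low < high < fs / 2):
        raise ValidationError(f"band ({low}, {high}) invalid for fs={fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(continuous, dtype=float), axis=-1)


def epoch(
    continuous: np.ndarray,
    fs: float,
    onsets_s,
    window: tuple[float, float] = (-1.0, 3.0),
    channel_names: list[str] | None = None,
    trial_labels: pd.DataFrame | None = None,
) -> tuple[EpochSet, int]:
    """Cut stimulus-locked epochs out of a continuous channels x time array.

    Onsets whose window falls outside the recording are excluded; the count
    of excluded onsets is returned alongside the epochs and logged.
    """
    data = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_ch, n_samp = data.shape
    start_off = int(round(window[0] * fs))
    n_epoch_samp = int(round((window[1] - window[0]) * fs))
    rows, kept_idx, n_dropped = [], [], 0
    for i, onset in enumerate(np.atleast_1d(onsets_s)):
        first = int(round(onset * fs)) + start_off
        if first < 0 or first + n_epoch_samp > n_samp:
            n_dropped += 1
            continue
        rows.append(data[:, first : first + n_epoch_samp])
        kept_idx.append(i)
    if n_dropped:
        log.info("epoch: excluded %d out-of-bounds onsets", n_dropped)
    if not rows:
        raise InsufficientDataError("no onset fits inside the recording")
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    if trial_labels is None:
        labels = pd.DataFrame({"trial": kept_idx})
    else:
        labels = trial_labels.iloc[kept_idx].reset_index(drop=True)
    return (
        EpochSet(
            data=np.stack(rows),
            fs=fs,
            t_start=window[0],
            channel_names=channel_names,
            trial_labels=labels,
        ),
        n_dropped,
    )


def _window_mask(times: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    mask = (times >= interval[0]) & (times < interval[1])
    if not mask.any():
        raise ValidationError(f"window {interval} contains no samples")
    return mask


def baseline_correct(
    epochs: EpochSet, interval: tuple[float, float] = (-1.0, 0.0)
) -> EpochSet:
    """Subtract each epoch/channel's mean over the prestimulus interval."""
    times = epochs.times
    if interval[0] < times[0] - 1e-9 or interval[1] > times[-1] + 1e-9:
        raise ValidationError("baseline interval outside the epoch span")
    mask = _window_mask(times, interval)
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_artifacts(epochs: EpochSet, threshold: float = DEFAULT_REJECT_UV) -> EpochSet:
    """Mask epochs whose peak-to-peak amplitude on any channel exceeds threshold."""
    if threshold <= 0:
        raise ValidationError("rejection threshold must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # epochs x channels
    bad = (ptp > threshold).any(axis=1)
    out = epochs.copy()
    out.reject_mask = out.reject_mask | bad
    log.info("reject_artifacts: %d/%d epochs masked", int(bad.sum()), epochs.n_epochs)
    return out


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Common-average reference: subtract the channel mean at every sample."""
    if epochs.data.shape[1] < 2:
        raise ValidationError("average reference needs >= 2 channels")
    out = epochs.copy()
    out.data -= out.data.mean(axis=1, keepdims=True)
    return out


def condition_average(
    epochs: EpochSet, by: list[str] | None = None
) -> dict[tuple, np.ndarray]:
    """Mean waveform (channels x samples) per condition cell over unmasked epochs.

    Cells whose epochs are all masked are flagged by mapping to ``None``.
    """
    if by is None:
        by = [c for c in epochs.trial_labels.columns if c != "trial"]
    out: dict[tuple, np.ndarray] = {}
    for key, idx in epochs.trial_labels.groupby(by, sort=True).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        sel = np.asarray(idx)
        keep = sel[~epochs.reject_mask[sel]]
        if len(keep) == 0:
            log.warning("condition_average: cell %s has no usable epochs", key)
            out[key] = None
            continue
        out[key] = epochs.data[keep].mean(axis=0)
    return out


def extract_lpp(
    mean_waveform: np.ndarray,
    fs: float,
    t_start: float,
    channel_names: list[str],
    channels: tuple[str, ...] = LPP_CHANNELS,
    windows: tuple[tuple[float, float], tuple[float, float]] = (EARLY_WINDOW, LATE_WINDOW),
    labels: dict | None = None,
) -> LppFeatures:
    """Mean voltage over the named channels inside each window.

    The channel average is taken before the time average; for means the
    order is irrelevant, it is fixed for determinism.
    """
    for ch in channels:
        if ch not in channel_names:
            raise ValidationError(f"required channel {ch!r} missing")
    idx = [channel_names.index(ch) for ch in channels]
    times = t_start + np.arange(mean_waveform.shape[-1]) / fs
    if windows[0][0] < times[0] or windows[1][1] > times[-1] + 1.0 / fs + 1e-9:
        raise ValidationError("LPP windows outside the epoch span")
    chan_mean = mean_waveform[idx].mean(axis=0)
    vals = []
    for win in windows:
        vals.append(float(chan_mean[_window_mask(times, win)].mean()))
    return LppFeatures(early_lpp=vals[0], late_lpp=vals[1], labels=labels or {})


def delta_lpp(features_pain: LppFeatures, features_nonpain: LppFeatures) -> DeltaLpp:
    """Painful minus nonpainful LPP amplitudes; cell labels must match."""
    ignore = {"stim_type"}
    lp = {k: v for k, v in features_pain.labels.items() if k not in ignore}
    ln = {k: v for k, v in features_nonpain.labels.items() if k not in ignore}
    if lp != ln:
        raise ValidationError(f"cell label mismatch: {lp} vs {ln}")
    return DeltaLpp(
        early_delta=features_pain.early_lpp - features_nonpain.early_lpp,
        late_delta=features_pain.late_lpp - features_nonpain.late_lpp,
        labels=lp,
    )


def lpp_table(
    epochs: EpochSet,
    by: list[str] = ("participant", "tdcs_target", "tdcs_type", "task", "stim_type"),
) -> pd.DataFrame:
    """Per-cell LPP features over the unmasked condition averages."""
    means = condition_average(epochs, by=list(by))
    rows = []
    for key, wf in means.items():
        rec = dict(zip(by, key))
        if wf is None:
            rec.update(early_lpp=np.nan, late_lpp=np.nan, flag="missing")
        else:
            feats = extract_lpp(
                wf, epochs.fs, epochs.t_start, epochs.channel_names, labels=rec
            )
            rec.update(early_lpp=feats.early_lpp, late_lpp=feats.late_lpp, flag="ok")
        rows.append(rec)
    return pd.DataFrame(rows)


def delta_lpp_table(lpp: pd.DataFrame) -> pd.DataFrame:
    """Painful-minus-nonpainful differences per participant x design cell."""
    keys = [
        c for c in lpp.columns
        if c not in ("stim_type", "early_lpp", "late_lpp", "flag")
    ]
    pain = lpp[lpp["stim_type"] == "pain"].set_index(keys)
    nonpain = lpp[lpp["stim_type"] == "nonpain"].set_index(keys)
    joined = pain.join(nonpain, lsuffix="_pain", rsuffix="_nonpain", how="inner")
    ok = (joined["flag_pain"] == "ok") & (joined["flag_nonpain"] == "ok")
    out = pd.DataFrame(
        {
            "early_delta": joined["early_lpp_pain"] - joined["early_lpp_nonpain"],
            "late_delta": joined["late_lpp_pain"] - joined["late_lpp_nonpain"],
        }
    )[ok]
    return out.reset_index()
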