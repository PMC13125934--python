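"""In-memory containers shared by the generators and the analysis stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class EcgTrace:
    """Continuous single-lead ECG in millivolts."""

    samples: np.ndarray  # (n,) mV
    fs: float            # Hz

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs < 100.0:
            raise ValidationError("ECG sampling rate must be >= 100 Hz")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("ECG trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.samples}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "EcgTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValidationError("trace CSV needs at least two samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        return cls(samples=df["value"].to_numpy(), fs=fs)


@dataclass
class RriSeries:
    """R-peak times and the RR intervals between them, in milliseconds."""

    peak_times: np.ndarray                 # (n,) ms, strictly increasing
    corrected_mask: np.ndarray | None = None  # per-interval flags

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if len(self.peak_times) >= 2 and np.any(np.diff(self.peak_times) <= 0):
            raise ValidationError("peak times must be strictly increasing")
        n_int = max(len(self.peak_times) - 1, 0)
        if self.corrected_mask is None:
            self.corrected_mask = np.zeros(n_int, dtype=bool)
        else:
            self.corrected_mask = np.asarray(self.corrected_mask, dtype=bool)
            if len(self.corrected_mask) != n_int:
                raise ValidationError("corrected_mask length must equal interval count")

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.peak_times)

    @property
    def n_beats(self) -> int:
        return len(self.peak_times)

    @property
    def span_s(self) -> float:
        if self.n_beats < 2:
            return 0.0
        return float(self.peak_times[-1] - self.peak_times[0]) / 1000.0

    def to_csv(self, path: str | Path) -> None:
        rr = np.concatenate([[np.nan], self.rr_intervals])
        corrected = np.concatenate([[False], self.corrected_mask])
        pd.DataFrame(
            {"peak_time_ms": self.peak_times, "rr_ms": rr, "corrected": corrected}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RriSeries":
        df = pd.read_csv(path)
        mask = df["corrected"].to_numpy(dtype=bool)[1:] if "corrected" in df else None
        return cls(peak_times=df["peak_time_ms"].to_numpy(), corrected_mask=mask)


@dataclass
class EpochSet:
    """Stimulus-locked EEG epochs: epochs x channels x samples, in µV."""

    data: np.ndarray                 # (n_epochs, n_channels, n_samples)
    fs: float                        # Hz
    t_start: float                   # s relative to stimulus onset
    channel_names: list[str]
    trial_labels: pd.DataFrame       # one row per epoch (condition tags)
    reject_mask: np.ndarray = field(default=None)  # True = rejected

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be epochs x channels x samples")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if self.data.shape[1] != len(self.channel_names):
            raise ValidationError("channel axis does not match channel_names")
        if len(self.trial_labels) != self.data.shape[0]:
            raise ValidationError("trial_labels rows must match epoch count")
        if self.reject_mask is None:
            self.reject_mask = np.zeros(self.data.shape[0], dtype=bool)
        self.reject_mask = np.asarray(self.reject_mask, dtype=bool)
        if len(self.reject_mask) != self.data.shape[0]:
            raise ValidationError("reject_mask length must match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.data.shape[2]) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ValidationError(f"channel {name!r} not present") from None

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            fs=self.fs,
            t_start=self.t_start,
            channel_names=list(self.channel_names),
            trial_labels=self.trial_labels.copy(),
            reject_mask=self.reject_mask.copy(),
        )

    # array container + JSON sidecar (fs, t0, channels)
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            data=self.data,
            reject_mask=self.reject_mask,
        )
        sidecar = {
            "fs": self.fs,
            "t_start": self.t_start,
            "channel_names": self.channel_names,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        self.trial_labels.to_csv(path.with_suffix(".labels.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        labels = pd.read_csv(path.with_suffix(".labels.csv"))
        return cls(
            data=arrays["data"],
            fs=sidecar["fs"],
            t_start=sidecar["t_start"],
            channel_names=list(sidecar["channel_names"]),
            trial_labels=labels,
            reject_mask=arrays["reject_mask"],
        )


@dataclass
class GroundTruth:
    """Generator-side truth that recovery tests compare against."""

    true_r_peak_times: np.ndarray | None = None  # ms
    true_condition_effects: dict | None = None
    true_labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.true_r_peak_times is not None:
            self.true_r_peak_times = np.asarray(self.true_r_peak_times, dtype=float)
            if len(self.true_r_peak_times) >= 2 and np.any(
                np.diff(self.true_r_peak_times) <= 0
            ):
                raise ValidationError("ground-truth R times must be strictly increasing")
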