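"""Simulation configuration for the synthetic two-study empathy cohorts.

A single :class:`SimConfig` drives every generator.  Effect-size fields are
expressed in the units of the signal they perturb: rating effects in latent
standard-deviation units, LPP amplitudes in microvolts, RR modulation depths
in milliseconds.  One global seed fans out deterministically to named child
streams so individual data modalities can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

STUDY1 = "study1"
STUDY2 = "study2"

#: Study 1 factor levels (target group is between-subjects, rest within).
TDCS_TARGETS = ("ldlpfc", "rtpj")
TDCS_TYPES = ("real", "sham")
TASKS = ("somatic", "affective")
STIM_TYPES = ("pain", "nonpain")

#: Study 2 factor levels (group is between-subjects).
GROUPS_STUDY2 = ("ldlpfc", "rtpj", "sham")
VALENCES = ("positive", "negative", "neutral")
TIMES = ("pre", "post")
SCALES_STUDY2 = ("content", "emotion", "concern", "contagion")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the two study designs: 38 participants per stimulation
    group with 30 trials per task/stimulation cell for the picture task, and
    40 per group with 4 two-minute clips per valence/time cell for the
    narrative task (overridable for smaller runs).
    """

    design: str = STUDY1
    n_participants_per_group: int = 38
    n_trials_per_cell: int = 30

    # --- ordinal rating model (latent-normal, unit residual SD) ---
    rating_effect_pain: float = 1.5     # latent shift, painful vs nonpainful
    rating_effect_rtpj: float = 0.5     # extra shift on other-ratings, real rTPJ
    rating_effect_valence: float = 1.0  # emotional vs neutral clips (study 2)
    participant_sd: float = 0.5         # random intercept SD (latent units)

    # --- ERP / LPP model ---
    lpp_amp_pain: float = 8.0           # µV
    lpp_amp_nonpain: float = 5.0        # µV
    lpp_effect_rtpj: float = 1.5        # µV added to pain trials, real rTPJ
    eeg_fs: float = 250.0               # Hz
    eeg_noise_sd: float = 10.0          # µV, 1/f-shaped background

    # --- ECG / RR model ---
    ecg_fs: float = 500.0               # Hz
    mean_rr: float = 800.0              # ms
    lf_amp: float = 30.0                # ms, 0.10 Hz modulation depth
    hf_amp: float = 25.0                # ms, 0.25 Hz modulation depth
    rr_jitter_sd: float = 15.0          # ms, beat-to-beat Gaussian jitter
    hrv_effect_ldlpfc: float = 1.3      # post-stim multiplier, lDLPFC group
    ecg_noise_sd: float = 0.02          # mV white noise on the trace
    ecg_wander_amp: float = 0.1         # mV baseline wander amplitude
    ecg_wander_hz: float = 0.2          # Hz (< 0.5 by construction)

    # --- study-2 rating scale bounds (methods text: 1-9) ---
    rating_min_study2: int = 1
    rating_max_study2: int = 9

    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in (STUDY1, STUDY2):
            raise ConfigurationError(f"unknown design {self.design!r}")
        if self.n_participants_per_group < 1 or self.n_trials_per_cell < 1:
            raise ConfigurationError("counts must be >= 1")
        if not (400.0 <= self.mean_rr <= 1500.0):
            raise ConfigurationError("mean_rr must lie in [400, 1500] ms")
        if min(self.lf_amp, self.hf_amp, self.rr_jitter_sd) < 0:
            raise ConfigurationError("modulation depths must be >= 0")
        # worst case over the post-lDLPFC boost, which scales depths and jitter
        boost = max(1.0, self.hrv_effect_ldlpfc)
        floor = self.mean_rr - boost * (
            self.lf_amp + self.hf_amp + 3.0 * self.rr_jitter_sd
        )
        if floor <= 250.0:
            raise ConfigurationError(
                "RR floor below 250 ms: reduce modulation depths or jitter"
            )
        if self.eeg_fs < 100.0:
            raise ConfigurationError("eeg_fs must be >= 100 Hz")
        if self.ecg_fs < 100.0:
            raise ConfigurationError("ecg_fs must resolve the QRS (>= 100 Hz)")
        if self.rating_min_study2 >= self.rating_max_study2:
            raise ConfigurationError("study-2 rating bounds inverted")

    # -- deterministic per-stream RNGs -------------------------------------
    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for a named data stream.

        The stream name is hashed (CRC-32) and combined with the global seed
        in a :class:`numpy.random.SeedSequence`, so every stream is
        independent yet fully reproducible from ``seed`` alone.
        """
        key = zlib.crc32(stream.encode("utf8")) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))

    # -- (de)serialisation -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SimConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def study1_config(**kw) -> SimConfig:
    """Picture-based pain-empathy design (2 target x 2 type x 2 task x 2 stim)."""
    kw.setdefault("design", STUDY1)
    kw.setdefault("n_participants_per_group", 38)
    kw.setdefault("n_trials_per_cell", 30)
    return SimConfig(**kw)


def study2_config(**kw) -> SimConfig:
    """Autobiographical-narrative design (3 group x 3 valence x 2 time)."""
    kw.setdefault("design", STUDY2)
    kw.setdefault("n_participants_per_group", 40)
    kw.setdefault("n_trials_per_cell", 4)
    return SimConfig(**kw)
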