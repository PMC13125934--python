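"""Ordinal rating generators for both study designs.

Ratings arise from a latent-normal model: a participant-specific intercept
plus condition shifts plus unit-SD trial noise, discretised onto the bounded
integer scale by rounding (equal-width bins of one latent SD) and clipping.
Effect parameters are therefore interpretable directly as latent shifts in
standard-deviation units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import (
    SCALES_STUDY2,
    STIM_TYPES,
    STUDY1,
    STUDY2,
    TASKS,
    TDCS_TARGETS,
    TDCS_TYPES,
    TIMES,
    VALENCES,
    GROUPS_STUDY2,
    SimConfig,
)
from ..errors import ConfigurationError


def _discretize(latent: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Map latent values (centred on the scale midpoint) to integer ratings."""
    mid = (lo + hi) / 2.0
    return np.clip(np.round(mid + latent), lo, hi).astype(int)


def simulate_ratings_study1(cfg: SimConfig) -> pd.DataFrame:
    """Trial-level 0-10 unpleasantness ratings for the picture-based task.

    Returns a tidy long table with one row per trial x rating scale
    (``self`` = own unpleasantness, ``other`` = protagonist's pain).  The
    painful/nonpainful latent contrast is ``rating_effect_pain``; real rTPJ
    stimulation adds ``rating_effect_rtpj`` to other-ratings on painful
    trials (a pure discriminability boost).
    """
    if cfg.design != STUDY1:
        raise ConfigurationError("simulate_ratings_study1 requires design='study1'")
    rng = cfg.rng("ratings_study1")
    n = cfg.n_participants_per_group
    rows: list[dict] = []
    for gi, target in enumerate(TDCS_TARGETS):
        for p in range(n):
            pid = f"{target}_{p:03d}"
            intercepts = {
                scale: cfg.participant_sd * rng.standard_normal()
                for scale in ("self", "other")
            }
            for tdcs_type in TDCS_TYPES:
                for task in TASKS:
                    for stim in STIM_TYPES:
                        half = cfg.rating_effect_pain / 2.0
                        base_shift = half if stim == "pain" else -half
                        for scale in ("self", "other"):
                            shift = base_shift
                            if (
                                scale == "other"
                                and stim == "pain"
                                and target == "rtpj"
                                and tdcs_type == "real"
                            ):
                                shift += cfg.rating_effect_rtpj
                            latent = (
                                intercepts[scale]
                                + shift
                                + rng.standard_normal(cfg.n_trials_per_cell)
                            )
                            values = _discretize(latent, 0, 10)
                            for trial, v in enumerate(values):
                                rows.append(
                                    {
                                        "participant": pid,
                                        "tdcs_target": target,
                                        "tdcs_type": tdcs_type,
                                        "task": task,
                                        "stim_type": stim,
                                        "trial": trial,
                                        "scale": scale,
                                        "value": int(v),
                                    }
                                )
    return pd.DataFrame(rows)


# generative latent means per scale, relative to the scale midpoint
_VALENCE_PROFILE = {
    # (content, emotion, concern, contagion) multipliers of rating_effect_valence
    "positive": (1.0, 1.0, 0.0, 0.5),
    "negative": (1.0, 1.0, 1.0, 1.0),
    "neutral": (0.0, 0.0, 0.0, 0.0),
}


def simulate_ratings_study2(cfg: SimConfig) -> pd.DataFrame:
    """Per-clip empathy ratings (default 1-9) for the narrative task.

    Four scales per trial: content understanding, emotion understanding,
    empathic concern, emotional contagion.  Emotional (vs neutral) clips
    shift the latent means per :data:`_VALENCE_PROFILE`; after real rTPJ
    stimulation the two cognitive scales gain ``rating_effect_rtpj``.
    """
    if cfg.design != STUDY2:
        raise ConfigurationError("simulate_ratings_study2 requires design='study2'")
    rng = cfg.rng("ratings_study2")
    lo, hi = cfg.rating_min_study2, cfg.rating_max_study2
    rows: list[dict] = []
    for group in GROUPS_STUDY2:
        for p in range(cfg.n_participants_per_group):
            pid = f"{group}_{p:03d}"
            intercepts = {
                scale: cfg.participant_sd * rng.standard_normal()
                for scale in SCALES_STUDY2
            }
            for valence in VALENCES:
                profile = _VALENCE_PROFILE[valence]
                for time in TIMES:
                    for trial in range(cfg.n_trials_per_cell):
                        for scale, mult in zip(SCALES_STUDY2, profile):
                            shift = mult * cfg.rating_effect_valence
                            if (
                                group == "rtpj"
                                and time == "post"
                                and scale in ("content", "emotion")
                            ):
                                shift += cfg.rating_effect_rtpj
                            latent = intercepts[scale] + shift + rng.standard_normal()
                            rows.append(
                                {
                                    "participant": pid,
                                    "group": group,
                                    "valence": valence,
                                    "time": time,
                                    "trial": trial,
                                    "scale": scale,
                                    "value": int(_discretize(np.array([latent]), lo, hi)[0]),
                                }
                            )
    return pd.DataFrame(rows)
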