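"""Rating-based signal detection: criterion sweep, ROC curve, nonparametric AUC.

Ordinal ratings are treated as implicit decision criteria: for every
criterion c on the scale, trials with rating >= c in the signal (painful)
condition count as hits and in the noise (nonpainful) condition as false
alarms.  The trapezoidal area under the resulting hit-vs-false-alarm curve
is a bias-free discrimination index, identical to the rank statistic
P(X > Y) + 0.5 P(X = Y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError


@dataclass
class RocCurve:
    """Hit/false-alarm rates over the full criterion sweep, with anchors."""

    criteria: np.ndarray    # thresholds, descending ("rating >= c")
    hit_rates: np.ndarray
    fa_rates: np.ndarray
    n_signal: int
    n_noise: int

    def __post_init__(self) -> None:
        self.criteria = np.asarray(self.criteria, dtype=float)
        self.hit_rates = np.asarray(self.hit_rates, dtype=float)
        self.fa_rates = np.asarray(self.fa_rates, dtype=float)
        if not (len(self.criteria) == len(self.hit_rates) == len(self.fa_rates)):
            raise ValidationError("ROC curve arrays must have equal length")


@dataclass
class AucResult:
    auc: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"AUC {self.auc} outside [0, 1]")


def _check_ratings(values, name: str, scale_min: int, scale_max: int) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise InsufficientDataError(f"{name} ratings are empty")
    if np.any(arr < scale_min) or np.any(arr > scale_max):
        raise ValidationError(
            f"{name} ratings outside declared scale [{scale_min}, {scale_max}]"
        )
    return arr.astype(float)


def roc_from_ratings(
    signal_ratings,
    noise_ratings,
    scale_min: int = 0,
    scale_max: int = 10,
) -> RocCurve:
    """Sweep every criterion of the declared scale and anchor the curve.

    Criteria run over every scale value (c = scale_min .. scale_max), not
    only observed ratings, so curves are comparable across cells; the AUC is
    unaffected either way (rank equivalence).  The ">= scale_min" criterion
    yields the (1, 1) anchor; a "> scale_max" pseudo-criterion adds (0, 0).
    """
    sig = _check_ratings(signal_ratings, "signal", scale_min, scale_max)
    noi = _check_ratings(noise_ratings, "noise", scale_min, scale_max)
    criteria = np.arange(scale_min, scale_max + 2)  # last one exceeds the scale
    hits = np.array([np.mean(sig >= c) for c in criteria])
    fas = np.array([np.mean(noi >= c) for c in criteria])
    return RocCurve(
        criteria=criteria,
        hit_rates=hits,
        fa_rates=fas,
        n_signal=len(sig),
        n_noise=len(noi),
    )


def auc_trapezoid(curve: RocCurve, labels: dict | None = None) -> AucResult:
    """Trapezoidal area over the fa-sorted curve.

    Points are sorted by (false-alarm rate, hit rate) so ties at a criterion
    contribute the trapezoid over the tied segment, matching the
    0.5 P(X = Y) convention of the rank statistic.
    """
    order = np.lexsort((curve.hit_rates, curve.fa_rates))
    fa = curve.fa_rates[order]
    hit = curve.hit_rates[order]
    if np.any(np.diff(fa) < 0) or np.any(np.diff(hit) < 0):
        raise ValidationError("ROC curve is not monotone after sorting")
    area = float(np.trapezoid(hit, fa))
    return AucResult(auc=area, labels=labels or {})


def auc_rank(signal_ratings, noise_ratings) -> float:
    """Brute-force Mann-Whitney formulation: (Σ 1[x>y] + ½·1[x=y]) / (nm).

    Kept as an independent route; :func:`auc_trapezoid` must agree exactly.
    """
    x = np.asarray(signal_ratings, dtype=float)[:, None]
    y = np.asarray(noise_ratings, dtype=float)[None, :]
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("need both signal and noise ratings")
    return float(((x > y).sum() + 0.5 * (x == y).sum()) / (x.size * y.size))


def auc_by_cell(
    ratings: pd.DataFrame,
    scale: str,
    scale_min: int = 0,
    scale_max: int = 10,
    min_trials: int = 2,
) -> pd.DataFrame:
    """One AUC per participant x tDCS-type x task cell for a rating scale.

    Cells missing either condition, or with fewer than ``min_trials`` trials
    per condition, are flagged ``insufficient`` (AUC = NaN) rather than
    dropped.
    """
    if scale not in set(ratings["scale"]):
        raise ValidationError(f"scale {scale!r} not present in rating table")
    sub = ratings[ratings["scale"] == scale]
    keys = ["participant", "tdcs_target", "tdcs_type", "task"]
    records = []
    for key_vals, cell in sub.groupby(keys, sort=True):
        sig = cell.loc[cell["stim_type"] == "pain", "value"].to_numpy()
        noi = cell.loc[cell["stim_type"] == "nonpain", "value"].to_numpy()
        rec = dict(zip(keys, key_vals))
        rec["scale"] = scale
        if len(sig) < min_trials or len(noi) < min_trials:
            rec.update(auc=np.nan, flag="insufficient")
        else:
            curve = roc_from_ratings(sig, noi, scale_min, scale_max)
            rec.update(auc=auc_trapezoid(curve).auc, flag="ok")
        rec.update(n_signal=len(sig), n_noise=len(noi))
        records.append(rec)
    return pd.DataFrame(records)
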