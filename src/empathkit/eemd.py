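"""Ensemble empirical mode decomposition (EEMD).

Plain EMD sifts intrinsic mode functions (IMFs) out of a signal by
repeatedly subtracting the mean of the cubic-spline envelopes through its
maxima and minima, stopping a sift when the normalised squared change (a
Cauchy-type SD criterion) falls below a threshold.  EEMD runs EMD on an
ensemble of white-noise-perturbed copies and averages IMFs rank-wise, which
stabilises mode mixing; the residue is the ensemble mean of member
residues, so the reconstruction Σimfs + residue = x + mean(added noise)
converges to the input as the ensemble grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ValidationError

DEFAULT_ENSEMBLE = 100
DEFAULT_NOISE_FRACTION = 0.2
DEFAULT_STOP_SD = 0.2
DEFAULT_MAX_SIFTS = 10


@dataclass
class ImfDecomposition:
    imfs: list[np.ndarray]
    residue: np.ndarray
    ensemble_size: int
    noise_sd_fraction: float

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus collapse)."""
    d = np.sign(np.diff(x))
    # carry the last non-zero slope through plateaus
    for i in range(1, len(d)):
        if d[i] == 0:
            d[i] = d[i - 1]
    change = np.diff(d)
    maxima = np.where(change < 0)[0] + 1
    minima = np.where(change > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray | None:
    """Cubic-spline envelope through the extrema, mirror-padded at the ends."""
    n = len(x)
    if len(idx) < 2:
        return None
    k = min(2, len(idx))
    left_t = -idx[:k][::-1]
    left_v = x[idx[:k]][::-1]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    right_v = x[idx[-k:]][::-1]
    t = np.concatenate([left_t, idx, right_t]).astype(float)
    v = np.concatenate([left_v, x[idx], right_v])
    t, uniq = np.unique(t, return_index=True)
    return CubicSpline(t, v[uniq])(np.arange(n))


def _sift_imf(
    x: np.ndarray, stop_sd: float, max_sifts: int
) -> np.ndarray | None:
    """Extract one IMF from ``x``; None when ``x`` has too few extrema."""
    h = x.copy()
    for it in range(max_sifts):
        maxima, minima = _local_extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            return None if it == 0 else h
        upper = _envelope(h, maxima)
        lower = _envelope(h, minima)
        mean_env = 0.5 * (upper + lower)
        h_new = h - mean_env
        denom = float(np.sum(h**2)) + 1e-300
        if float(np.sum(mean_env**2)) / denom < stop_sd:
            return h_new
        h = h_new
    return h


def emd(
    x: np.ndarray,
    max_imfs: int = 10,
    stop_sd: float = DEFAULT_STOP_SD,
    max_sifts: int = DEFAULT_MAX_SIFTS,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Plain EMD: returns (imfs, residue); monotone input gives no IMFs."""
    x = np.asarray(x, dtype=float)
    residue = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residue)
        if len(maxima) < 2 or len(minima) < 2:
            break
        imf = _sift_imf(residue, stop_sd, max_sifts)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
    return imfs, residue


def eemd(
    signal: np.ndarray,
    ensemble_size: int = DEFAULT_ENSEMBLE,
    noise_sd_fraction: float = DEFAULT_NOISE_FRACTION,
    max_imfs: int = 10,
    rng: np.random.Generator | int | None = None,
    stop_sd: float = DEFAULT_STOP_SD,
    max_sifts: int = DEFAULT_MAX_SIFTS,
) -> ImfDecomposition:
    """Rank-wise ensemble average of EMDs of noise-perturbed copies."""
    x = np.asarray(signal, dtype=float)
    if len(x) < 64:
        raise ValidationError("signal too short for EEMD (need >= 64 samples)")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite values")
    if ensemble_size < 1:
        raise ValidationError("ensemble_size must be >= 1")
    if noise_sd_fraction < 0:
        raise ValidationError("noise_sd_fraction must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    noise_sd = noise_sd_fraction * float(np.std(x))
    member_imfs: list[list[np.ndarray]] = []
    member_residues: list[np.ndarray] = []
    for _ in range(ensemble_size):
        noisy = x + noise_sd * rng.standard_normal(len(x)) if noise_sd > 0 else x
        imfs, residue = emd(noisy, max_imfs=max_imfs, stop_sd=stop_sd,
                            max_sifts=max_sifts)
        member_imfs.append(imfs)
        member_residues.append(residue)

    n_ranks = max((len(m) for m in member_imfs), default=0)
    avg_imfs = []
    for rank in range(n_ranks):
        stacked = [
            m[rank] if rank < len(m) else np.zeros(len(x)) for m in member_imfs
        ]
        avg_imfs.append(np.mean(stacked, axis=0))
    avg_residue = np.mean(member_residues, axis=0)
    return ImfDecomposition(
        imfs=avg_imfs,
        residue=avg_residue,
        ensemble_size=ensemble_size,
        noise_sd_fraction=noise_sd_fraction,
    )


def spectral_centroid(component: np.ndarray, fs: float) -> float:
    """Power-weighted mean frequency (Hz) of one component."""
    spectrum = np.abs(np.fft.rfft(component)) ** 2
    freqs = np.fft.rfftfreq(len(component), d=1.0 / fs)
    total = spectrum.sum()
    if total <= 0:
        return 0.0
    return float((freqs * spectrum).sum() / total)
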