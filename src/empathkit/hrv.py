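"""ECG-to-HRV chain: denoising, R-peak detection, RRI correction, indices.

Conventions
-----------
* Population variance (divide by n) everywhere.  Successive RR differences
  are treated as a zero-mean process, so Poincaré SD1 is computed from the
  *uncentred* mean square of the differences — this makes the identity
  SD1 = RMSSD/√2 exact on every profile.
* Frequency-domain powers come from a Welch periodogram of the tachogram
  resampled to an even grid (cubic interpolation, 4 Hz default) after mean
  and linear-trend removal; LF = [0.04, 0.15) Hz, HF = [0.15, 0.40) Hz.
* Sample entropy uses template length m = 2 and tolerance r = 0.2 · SD(rr)
  (Chebyshev distance, self-matches excluded).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import interp1d

from .containers import EcgTrace, RriSeries
from .eemd import ImfDecomposition, spectral_centroid
from .errors import InsufficientDataError, QualityError, ValidationError

log = logging.getLogger(__name__)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

HRV_FIELDS = (
    "hr", "sdnn", "rmssd", "pnn50",
    "lf_power", "hf_power", "lf_hf",
    "sampen", "sd1", "sd2", "sd1_sd2",
)


@dataclass
class HrvProfile:
    """The ten HRV indices for one participant x condition x time cell."""

    hr: float = np.nan          # beats/min
    sdnn: float = np.nan        # ms
    rmssd: float = np.nan       # ms
    pnn50: float = np.nan       # %
    lf_power: float = np.nan    # ms^2
    hf_power: float = np.nan    # ms^2
    lf_hf: float = np.nan       # unitless (NaN when HF = 0)
    sampen: float = np.nan      # unitless
    sd1: float = np.nan         # ms
    sd2: float = np.nan         # ms
    sd1_sd2: float = np.nan     # unitless
    labels: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in HRV_FIELDS}
        out.update(self.labels)
        return out


# ---------------------------------------------------------------- denoising

def denoise_ecg(
    trace: EcgTrace,
    decomposition: ImfDecomposition,
    high_cut_hz: float = 45.0,
    low_cut_hz: float = 0.5,
) -> EcgTrace:
    """Reconstruct the ECG from IMFs, dropping broadband noise and wander.

    Leading IMFs whose spectral centroid exceeds ``high_cut_hz`` are treated
    as noise; the residue and trailing IMFs with centroid below
    ``low_cut_hz`` as baseline wander.  If the selection empties, the
    original trace is returned with a warning.
    """
    keep = [
        imf
        for imf in decomposition.imfs
        if low_cut_hz <= spectral_centroid(imf, trace.fs) <= high_cut_hz
    ]
    if spectral_centroid(decomposition.residue, trace.fs) >= low_cut_hz:
        keep.append(decomposition.residue)
    if not keep:
        warnings.warn("denoise_ecg: every component was removed; returning original")
        return EcgTrace(samples=trace.samples.copy(), fs=trace.fs)
    return EcgTrace(samples=np.sum(keep, axis=0), fs=trace.fs)


# ----------------------------------------------------------- R-peak detection

def detect_r_peaks(
    trace: EcgTrace,
    refractory_ms: float = 250.0,
    threshold_fraction: float = 0.5,
    block_s: float = 2.0,
) -> RriSeries:
    """Extreme-point R-peak search with an adaptive amplitude threshold.

    Local maxima must exceed ``threshold_fraction`` times a rolling
    amplitude level (the 99.9th percentile — essentially the R-wave height —
    over ``block_s`` blocks, interpolated per sample); within the refractory
    period only the larger of two conflicting candidates survives.
    """
    if trace.duration < 5.0:
        raise InsufficientDataError("need at least 5 s of ECG")
    x = trace.samples - np.median(trace.samples)
    fs = trace.fs

    block = max(int(round(block_s * fs)), 2)
    n_blocks = max(len(x) // block, 1)
    centers, levels = [], []
    for b in range(n_blocks):
        seg = x[b * block : (b + 1) * block if b < n_blocks - 1 else len(x)]
        centers.append(b * block + len(seg) / 2)
        levels.append(np.percentile(seg, 99.9))
    if len(centers) == 1:
        height = np.full(len(x), threshold_fraction * levels[0])
    else:
        height = threshold_fraction * np.interp(
            np.arange(len(x)), centers, levels
        )

    distance = max(int(round(refractory_ms / 1000.0 * fs)), 1)
    peaks, _ = sps.find_peaks(x, height=height, distance=distance)
    if len(peaks) == 0:
        raise InsufficientDataError("no R-peaks found")
    return RriSeries(peak_times=peaks / fs * 1000.0)


# ------------------------------------------------------------ RRI correction

def correct_rri(
    rri: RriSeries,
    tolerance_fraction: float = 0.3,
    window_beats: int = 11,
    max_corrected_fraction: float = 0.2,
) -> RriSeries:
    """Replace ectopic/missed-beat intervals by interpolation over neighbours.

    Intervals deviating from the ``window_beats``-beat rolling median by
    more than ``tolerance_fraction`` are cubic-interpolated from the clean
    intervals and flagged.  More than ``max_corrected_fraction`` flagged
    intervals raises :class:`QualityError`.
    """
    rr = rri.rr_intervals
    if len(rr) < 5:
        raise InsufficientDataError("need >= 5 intervals")
    half = window_beats // 2
    med = np.empty(len(rr))
    for i in range(len(rr)):
        lo, hi = max(0, i - half), min(len(rr), i + half + 1)
        med[i] = np.median(rr[lo:hi])
    bad = np.abs(rr - med) > tolerance_fraction * med
    if not bad.any():
        return RriSeries(peak_times=rri.peak_times.copy(),
                         corrected_mask=np.zeros(len(rr), dtype=bool))
    if bad.mean() > max_corrected_fraction:
        raise QualityError(
            f"{bad.mean():.0%} of intervals flagged; series rejected"
        )
    good = np.where(~bad)[0]
    kind = "cubic" if len(good) >= 4 else "linear"
    interp = interp1d(good, rr[good], kind=kind, fill_value="extrapolate")
    rr_fixed = rr.copy()
    rr_fixed[bad] = interp(np.where(bad)[0])
    log.info("correct_rri: corrected %d/%d intervals", int(bad.sum()), len(rr))
    peak_times = rri.peak_times[0] + np.concatenate([[0.0], np.cumsum(rr_fixed)])
    return RriSeries(peak_times=peak_times, corrected_mask=bad)


# ------------------------------------------------------------- time domain

def hrv_time_domain(rri: RriSeries) -> HrvProfile:
    rr = rri.rr_intervals
    if len(rr) < 2:
        raise InsufficientDataError("need >= 2 intervals")
    diff = np.diff(rr)
    return HrvProfile(
        hr=60000.0 / float(np.mean(rr)),
        sdnn=float(np.std(rr)),  # population SD
        rmssd=float(np.sqrt(np.mean(diff**2))),
        pnn50=100.0 * float(np.mean(np.abs(diff) > 50.0)),
    )


# -------------------------------------------------------- frequency domain

def hrv_frequency_domain(
    rri: RriSeries,
    resample_hz: float = 4.0,
    segment_s: float = 120.0,
) -> HrvProfile:
    """Band powers of the evenly resampled, detrended tachogram (Welch)."""
    if rri.span_s < 60.0:
        raise InsufficientDataError("series span must be >= 60 s to resolve 0.04 Hz")
    rr = rri.rr_intervals
    t = rri.peak_times[1:] / 1000.0  # interval timestamped at its ending beat
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = interp1d(t, rr, kind="cubic")(grid)
    tach = sps.detrend(tach, type="linear")

    nperseg = min(len(tach), int(segment_s * resample_hz))
    freqs, psd = sps.welch(
        tach, fs=resample_hz, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    def band_power(band):
        mask = (freqs >= band[0]) & (freqs < band[1])
        if mask.sum() < 2:
            return float(psd[mask].sum() * (freqs[1] - freqs[0]))
        return float(np.trapezoid(psd[mask], freqs[mask]))

    lf = band_power(LF_BAND)
    hf = band_power(HF_BAND)
    profile = HrvProfile(lf_power=lf, hf_power=hf)
    if hf > 0:
        profile.lf_hf = lf / hf
    else:
        profile.notes.append("lf_hf missing: HF power is zero")
    return profile


# --------------------------------------------------------- nonlinear domain

def sample_entropy(rr: np.ndarray, m: int = 2, r_fraction: float = 0.2) -> float:
    """SampEn = -ln(A/B) with Chebyshev tolerance r = r_fraction * SD(rr)."""
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    if n < m + 2:
        raise InsufficientDataError("series too short for sample entropy")
    r = r_fraction * float(np.std(rr))

    def count_matches(length: int) -> int:
        # n - m templates for both lengths, so A and B counts are comparable
        templates = np.lib.stride_tricks.sliding_window_view(rr, length)[: n - m]
        total = 0
        for i in range(len(templates) - 1):
            dist = np.max(np.abs(templates[i + 1 :] - templates[i]), axis=1)
            total += int(np.sum(dist <= r))
        return total

    b = count_matches(m)
    a = count_matches(m + 1)
    if b == 0:
        return np.nan  # no template matches; caller records the reason
    if a == 0:
        # conventional guard: no (m+1)-matches gives an infinite estimate;
        # report the finite upper bound instead
        return float(np.log(b) + np.log(2.0))
    return float(-np.log(a / b))


def hrv_nonlinear(
    rri: RriSeries, m: int = 2, r_fraction: float = 0.2, min_sampen_beats: int = 50
) -> HrvProfile:
    rr = rri.rr_intervals
    if len(rr) < 2:
        raise InsufficientDataError("need >= 2 intervals for Poincaré indices")
    diff = np.diff(rr)
    msd = float(np.mean(diff**2)) if len(diff) else 0.0
    sd1 = float(np.sqrt(msd / 2.0))
    sd2_sq = 2.0 * float(np.var(rr)) - msd / 2.0
    if sd2_sq < 0:
        warnings.warn("hrv_nonlinear: negative SD2^2 clamped to 0")
        sd2_sq = 0.0
    sd2 = float(np.sqrt(sd2_sq))
    profile = HrvProfile(sd1=sd1, sd2=sd2)
    profile.sd1_sd2 = sd1 / sd2 if sd2 > 0 else np.nan

    if len(rr) >= min_sampen_beats:
        if np.std(rr) == 0:
            profile.sampen = 0.0  # constant series: A = B exactly
        else:
            se = sample_entropy(rr, m=m, r_fraction=r_fraction)
            if np.isnan(se):
                profile.notes.append("sampen missing: no template matches (B = 0)")
            profile.sampen = se
    else:
        profile.notes.append(f"sampen missing: < {min_sampen_beats} intervals")
    return profile


# -------------------------------------------------------------- composition

def hrv_profile(
    rri: RriSeries,
    labels: dict | None = None,
    resample_hz: float = 4.0,
    m: int = 2,
    r_fraction: float = 0.2,
) -> HrvProfile:
    """All ten indices for one cell; component failures become missing fields."""
    out = HrvProfile(labels=labels or {})
    rr = rri.rr_intervals
    degenerate = len(rr) >= 2 and np.std(rr) == 0
    try:
        td = hrv_time_domain(rri)
        out.hr, out.sdnn, out.rmssd, out.pnn50 = td.hr, td.sdnn, td.rmssd, td.pnn50
    except InsufficientDataError as exc:
        out.notes.append(f"time domain: {exc}")
    if degenerate:
        out.lf_power = out.hf_power = 0.0
        out.notes.append("lf_hf missing: constant series")
    else:
        try:
            fd = hrv_frequency_domain(rri, resample_hz=resample_hz)
            out.lf_power, out.hf_power, out.lf_hf = fd.lf_power, fd.hf_power, fd.lf_hf
            out.notes.extend(fd.notes)
        except InsufficientDataError as exc:
            out.notes.append(f"frequency domain: {exc}")
    try:
        nl = hrv_nonlinear(rri, m=m, r_fraction=r_fraction)
        out.sampen, out.sd1, out.sd2, out.sd1_sd2 = nl.sampen, nl.sd1, nl.sd2, nl.sd1_sd2
        out.notes.extend(nl.notes)
    except InsufficientDataError as exc:
        out.notes.append(f"nonlinear domain: {exc}")
    return out
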