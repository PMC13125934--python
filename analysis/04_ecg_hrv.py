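"""ECG-to-HRV chain and post-minus-pre change scores for the narrative task.

Part A exercises the full signal chain on one trace: EEMD decomposition and
denoising of a wander+noise-corrupted ECG, extreme-point R-peak detection
against ground truth, and the ten HRV indices.  Part B runs the cohort:
per-cell HRV profiles for all three groups pre/post stimulation and the
change-score table, where only the lDLPFC group should shift.  Writes
results/hrv/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from empathkit.config import study2_config
from empathkit.eemd import eemd
from empathkit.hrv import correct_rri, denoise_ecg, detect_r_peaks, hrv_profile
from empathkit.pipeline import change_scores, hrv_table_study2
from empathkit.synth import simulate_ecg_waveform, simulate_rri

OUT = Path(__file__).resolve().parents[1] / "results" / "hrv"
SEED = 2026


def single_trace_demo(cfg) -> None:
    rri, gt = simulate_rri(cfg, duration_s=120,
                           cell={"group": "sham", "time": "pre"})
    trace, _ = simulate_ecg_waveform(rri, cfg, noise_sd=0.05)
    dec = eemd(trace.samples, ensemble_size=10, noise_sd_fraction=0.2, rng=SEED)
    clean = denoise_ecg(trace, dec)
    det = correct_rri(detect_r_peaks(clean))
    truth = gt.true_r_peak_times
    d = np.abs(det.peak_times[:, None] - truth[None, :])
    sens = float(np.mean(d.min(axis=0) <= 10.0))
    ppv = float(np.mean(d.min(axis=1) <= 10.0))
    prof = hrv_profile(det)
    print(f"single-trace chain: {len(dec.imfs)} IMFs, R-peak sensitivity "
          f"{sens:.1%}, positive predictivity {ppv:.1%} (+-10 ms)")
    print(f"  HR {prof.hr:.1f} bpm, SDNN {prof.sdnn:.1f} ms, RMSSD "
          f"{prof.rmssd:.1f} ms, LF/HF {prof.lf_hf:.2f} "
          f"(analytic {cfg.lf_amp**2 / cfg.hf_amp**2:.2f})")
    pd.DataFrame([prof.as_dict()]).to_csv(OUT / "single_trace_profile.csv",
                                          index=False)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = study2_config(n_participants_per_group=10, n_trials_per_cell=2,
                        seed=SEED)
    single_trace_demo(cfg)

    hrv = hrv_table_study2(cfg)
    hrv.to_csv(OUT / "hrv.csv", index=False)
    delta = change_scores(
        hrv[hrv["time"] == "pre"], hrv[hrv["time"] == "post"],
        keys=["participant", "group", "valence"],
    )
    delta.to_csv(OUT / "delta_hrv.csv", index=False)
    summary = (
        delta.groupby("group")[["sdnn", "rmssd", "sd1"]].agg(["mean", "sem"])
    )
    summary.to_csv(OUT / "delta_hrv_summary.csv")
    print("\nΔHRV (post − pre) by group:")
    print(summary.round(2).to_string())
    print("Only the lDLPFC group carries the generated post-stimulation "
          "variability increase; rTPJ and sham stay near zero.")


if __name__ == "__main__":
    main()
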