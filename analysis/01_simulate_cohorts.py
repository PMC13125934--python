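"""Generate the two synthetic cohorts and write their raw tables.

Produces, under results/cohorts/: the tidy rating tables for both study
designs, the stimulus-locked epoch container for the picture task, and one
example ECG trace + RR series with ground-truth beat times.  Desk-scale
sizes (12 participants per group) keep this a ~1-minute run; every
downstream script regenerates what it needs from the same configs, so this
script is illustrative, not a dependency.
"""

from pathlib import Path

import numpy as np

from empathkit.config import study1_config, study2_config
from empathkit.synth import (
    simulate_ecg_waveform,
    simulate_epochs_study1,
    simulate_ratings_study1,
    simulate_ratings_study2,
    simulate_rri,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"
N_PER_GROUP = 12
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg1 = study1_config(n_participants_per_group=N_PER_GROUP,
                         n_trials_per_cell=15, seed=SEED)
    cfg1.to_json(OUT / "study1_config.json")
    ratings1 = simulate_ratings_study1(cfg1)
    ratings1.to_csv(OUT / "study1_ratings.csv", index=False)
    epochs, truth = simulate_epochs_study1(cfg1)
    scratch = OUT.parents[1] / "scratch"
    scratch.mkdir(exist_ok=True)
    epochs.save(scratch / "study1_epochs")  # large binary container
    print(f"study 1: {len(ratings1)} rating rows, {epochs.n_epochs} epochs "
          f"({epochs.data.shape[1]} channels x {epochs.data.shape[2]} samples; "
          f"array container under scratch/)")

    cfg2 = study2_config(n_participants_per_group=N_PER_GROUP, seed=SEED)
    cfg2.to_json(OUT / "study2_config.json")
    ratings2 = simulate_ratings_study2(cfg2)
    ratings2.to_csv(OUT / "study2_ratings.csv", index=False)
    print(f"study 2: {len(ratings2)} rating rows")

    rri, gt = simulate_rri(cfg2, duration_s=120,
                           cell={"group": "sham", "time": "pre"})
    trace, _ = simulate_ecg_waveform(rri, cfg2, noise_sd=0.05)
    rri.to_csv(OUT / "example_rri.csv")
    # keep results/ small: first 10 s of the trace as an illustration
    head = int(10 * trace.fs)
    from empathkit.containers import EcgTrace
    EcgTrace(samples=trace.samples[:head], fs=trace.fs).to_csv(
        OUT / "example_ecg_10s.csv"
    )
    np.savetxt(OUT / "example_true_r_times_ms.csv", gt.true_r_peak_times,
               header="true_r_time_ms", comments="")
    print(f"example ECG: {trace.duration:.0f} s at {trace.fs:.0f} Hz, "
          f"{rri.n_beats} beats (first 10 s written, ground truth saved)")


if __name__ == "__main__":
    main()
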