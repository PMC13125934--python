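"""Rating-based signal-detection analysis of the picture-task cohort.

Sweeps every rating criterion, builds per-cell ROC curves, and reports the
nonparametric AUC per participant x stimulation cell for both rating
scales.  The headline contrast: real vs sham stimulation of the rTPJ group
on the other-oriented scale, where the generator plants a discriminability
boost.  Writes results/sdt/auc.csv and a cell-mean summary.
"""

from pathlib import Path

import pandas as pd

from empathkit.config import study1_config
from empathkit.sdt import auc_by_cell
from empathkit.synth import simulate_ratings_study1

OUT = Path(__file__).resolve().parents[1] / "results" / "sdt"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = study1_config(n_participants_per_group=12, n_trials_per_cell=15,
                        seed=SEED)
    ratings = simulate_ratings_study1(cfg)
    auc = pd.concat(
        [auc_by_cell(ratings, scale) for scale in ("self", "other")],
        ignore_index=True,
    )
    auc.to_csv(OUT / "auc.csv", index=False)

    ok = auc[auc["flag"] == "ok"]
    summary = (
        ok.groupby(["scale", "tdcs_target", "tdcs_type"])["auc"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    summary.to_csv(OUT / "auc_summary.csv", index=False)
    print(summary.to_string(index=False))

    other = summary[summary["scale"] == "other"].set_index(
        ["tdcs_target", "tdcs_type"]
    )["mean"]
    print(
        f"\nother-scale AUC, rTPJ group: real {other['rtpj', 'real']:.3f} vs "
        f"sham {other['rtpj', 'sham']:.3f} "
        f"(lDLPFC: real {other['ldlpfc', 'real']:.3f} vs "
        f"sham {other['ldlpfc', 'sham']:.3f})"
    )
    print("Real rTPJ stimulation raises other-oriented discriminability; "
          "the lDLPFC contrast stays flat, as generated.")


if __name__ == "__main__":
    main()
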