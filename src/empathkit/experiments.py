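"""Null-calibration and direction-of-effect recovery experiments.

These are the seed-sweep experiments the test suite and the reproduction
script share: chance-level calibration of the decoders under informationless
features, and recovery of the three qualitative target effects (rTPJ
rating/LPP boost, lDLPFC autonomic boost, and the matched null controls).

Problem sizes are deliberately desk-scale (tens of participants, a handful
of trials per cell, ~100 repetitions); the quantities checked — chance
levels and signs of seed-averaged differences — are insensitive to scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig, study1_config, study2_config
from .decoding import (
    FAMILIES,
    STUDY2_FAMILIES,
    FeatureMatrix,
    assemble_features_study1,
    assemble_features_study2,
    ensemble_summary,
    run_families,
)
from .erp import baseline_correct, delta_lpp_table, lpp_table, rereference_average
from .hrv import hrv_profile
from .pipeline import CLIP_DURATION_S
from .sdt import auc_by_cell
from .synth import (
    simulate_epochs_study1,
    simulate_ratings_study1,
    simulate_ratings_study2,
    simulate_rri,
)

#: forest size for the repeated-LOOCV sweeps (chance/recovery behaviour is
#: tree-count-insensitive; a small forest keeps 100-seed sweeps fast)
SWEEP_RF_TREES = 16


def _mean_se(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


def _study1_features(cfg: SimConfig, tdcs_type: str, task: str) -> FeatureMatrix:
    """Assemble the picture-task feature matrix for one within-subject cell."""
    ratings = simulate_ratings_study1(cfg)
    epochs, _ = simulate_epochs_study1(cfg, cells=[(tdcs_type, task)])
    epochs = rereference_average(baseline_correct(epochs))
    lpp = lpp_table(epochs)
    return assemble_features_study1(
        ratings[ratings["task"] == task], lpp, tdcs_type=tdcs_type, task=task
    )


def null_decoding_study1(
    seed: int,
    n_reps: int = 100,
    n_participants: int = 40,
    n_trials: int = 6,
    families: tuple[str, ...] = FAMILIES,
) -> dict:
    """Mean LOOCV accuracy (%) of the binary decoder on informationless data.

    Every effect parameter is zero and labels are additionally permuted per
    repetition, so accuracy should scatter around the 50% chance line.
    ``n_participants`` is the total across the two target groups; rows per
    repetition = participants x 2 stimulation types.
    """
    root = np.random.SeedSequence(seed)
    accs = []
    for rep, child in enumerate(root.spawn(n_reps)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = study1_config(
            n_participants_per_group=n_participants // 2,
            n_trials_per_cell=n_trials,
            rating_effect_pain=0.0,
            rating_effect_rtpj=0.0,
            lpp_amp_pain=5.0,
            lpp_amp_nonpain=5.0,
            lpp_effect_rtpj=0.0,
            seed=rep_seed,
        )
        feats = _study1_features(cfg, tdcs_type="sham", task="somatic")
        rng = np.random.default_rng(rep_seed)
        feats = FeatureMatrix(
            features=feats.features,
            labels=rng.permutation(feats.labels),
            group_ids=feats.group_ids,
        )
        reports = run_families(
            feats, families=families, seed=rep_seed,
            hyperparameters={"RF": {"n_estimators": SWEEP_RF_TREES}},
        )
        accs.append(ensemble_summary(reports)["mean_accuracy_pct"])
    mean, se = _mean_se(accs)
    return {"value": mean, "se": se, "n": n_participants * 2,
            "n_reps": n_reps, "chance_pct": 50.0}


def _study2_features_one_group(
    cfg: SimConfig, group: str, time: str
) -> FeatureMatrix:
    """Ratings + HRV feature rows (participant x valence) for one group/time."""
    ratings = simulate_ratings_study2(cfg)
    hrv_rows = []
    for p in range(cfg.n_participants_per_group):
        pid = f"{group}_{p:03d}"
        for valence in ("positive", "negative", "neutral"):
            profiles = []
            for trial in range(cfg.n_trials_per_cell):
                rri, _ = simulate_rri(
                    cfg, CLIP_DURATION_S, cell={"group": group, "time": time},
                    rng=cfg.rng(f"rri_{pid}_{valence}_{time}_{trial}"),
                )
                profiles.append(hrv_profile(rri).as_dict())
            row = pd.DataFrame(profiles).mean(numeric_only=True).to_dict()
            row.update(participant=pid, group=group, valence=valence, time=time)
            hrv_rows.append(row)
    return assemble_features_study2(
        ratings, pd.DataFrame(hrv_rows), time=time, group=group
    )


def null_decoding_study2(
    seed: int,
    n_reps: int = 100,
    n_participants: int = 15,
    families: tuple[str, ...] = STUDY2_FAMILIES,
) -> dict:
    """Mean LOOCV accuracy (%) of the 3-class valence decoder under the null.

    Valence effects are zero (rating features carry no class signal; HRV
    never depends on valence by construction) and labels are permuted per
    repetition, so accuracy should scatter around 33.3%.
    """
    root = np.random.SeedSequence(seed + 1)
    accs = []
    for rep, child in enumerate(root.spawn(n_reps)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = study2_config(
            n_participants_per_group=n_participants,
            n_trials_per_cell=1,
            rating_effect_valence=0.0,
            rating_effect_rtpj=0.0,
            hrv_effect_ldlpfc=1.0,
            seed=rep_seed,
        )
        feats = _study2_features_one_group(cfg, group="sham", time="pre")
        rng = np.random.default_rng(rep_seed)
        feats = FeatureMatrix(
            features=feats.features,
            labels=rng.permutation(feats.labels),
            group_ids=feats.group_ids,
        )
        reports = run_families(
            feats, families=families, seed=rep_seed,
            hyperparameters={"RF": {"n_estimators": SWEEP_RF_TREES}},
        )
        accs.append(ensemble_summary(reports)["mean_accuracy_pct"])
    mean, se = _mean_se(accs)
    return {"value": mean, "se": se, "n": n_participants * 3,
            "n_reps": n_reps, "chance_pct": 100.0 / 3.0}


def recovery_study1(
    seed: int,
    n_seeds: int = 100,
    n_participants: int = 10,
    n_trials: int = 8,
    null: bool = False,
    decode_families: tuple[str, ...] = ("LR", "NB"),
) -> dict:
    """Real-vs-sham differences in the rTPJ group, averaged over seeds.

    With the rTPJ boosts on (``null=False``) the other-rating AUC, the late
    ΔLPP and the decoding accuracy should all be higher after real than
    after sham stimulation; with the boosts zeroed every difference should
    vanish.  Painful-vs-nonpainful base effects stay on in both variants so
    the null is a genuine false-positive control.
    """
    root = np.random.SeedSequence(seed + 2)
    d_auc, d_late, d_early, d_acc = [], [], [], []
    for child in root.spawn(n_seeds):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = study1_config(
            n_participants_per_group=n_participants,
            n_trials_per_cell=n_trials,
            rating_effect_rtpj=0.0 if null else 0.5,
            lpp_effect_rtpj=0.0 if null else 1.5,
            seed=rep_seed,
        )
        ratings = simulate_ratings_study1(cfg)
        epochs, _ = simulate_epochs_study1(
            cfg, cells=[("real", "somatic"), ("sham", "somatic")]
        )
        epochs = rereference_average(baseline_correct(epochs))
        lpp = lpp_table(epochs)

        auc = auc_by_cell(ratings, "other")
        auc = auc[(auc["tdcs_target"] == "rtpj") & (auc["flag"] == "ok")]
        cell = auc.groupby("tdcs_type")["auc"].mean()
        d_auc.append(cell["real"] - cell["sham"])

        dlpp = delta_lpp_table(lpp)
        dlpp = dlpp[dlpp["tdcs_target"] == "rtpj"]
        by_type = dlpp.groupby("tdcs_type")[["early_delta", "late_delta"]].mean()
        d_early.append(by_type.loc["real", "early_delta"]
                       - by_type.loc["sham", "early_delta"])
        d_late.append(by_type.loc["real", "late_delta"]
                      - by_type.loc["sham", "late_delta"])

        acc = {}
        for tdcs_type in ("real", "sham"):
            feats = assemble_features_study1(
                ratings[ratings["task"] == "somatic"], lpp,
                tdcs_target="rtpj", tdcs_type=tdcs_type, task="somatic",
            )
            reports = run_families(feats, families=decode_families, seed=rep_seed)
            acc[tdcs_type] = ensemble_summary(reports)["mean_accuracy_pct"]
        d_acc.append(acc["real"] - acc["sham"])

    out = {}
    for name, vals in (
        ("d_other_auc", d_auc),
        ("d_early_delta_lpp", d_early),
        ("d_late_delta_lpp", d_late),
        ("d_accuracy_pct", d_acc),
    ):
        mean, se = _mean_se(vals)
        out[name] = {"mean": mean, "se": se}
    out["n_seeds"] = n_seeds
    return out


def recovery_study2(
    seed: int,
    n_seeds: int = 100,
    n_participants: int = 8,
    null: bool = False,
) -> dict:
    """lDLPFC-vs-sham change-score differences, averaged over seeds.

    With ``hrv_effect_ldlpfc`` > 1 the lDLPFC group should show positive
    Δsdnn/Δrmssd/Δsd1 relative to sham, with no rating change (the generator
    never couples the autonomic boost to ratings); with the boost at 1 every
    difference should vanish.
    """
    root = np.random.SeedSequence(seed + 3)
    d_sdnn, d_rmssd, d_sd1, d_rating = [], [], [], []
    for child in root.spawn(n_seeds):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = study2_config(
            n_participants_per_group=n_participants,
            n_trials_per_cell=1,
            hrv_effect_ldlpfc=1.0 if null else 1.3,
            seed=rep_seed,
        )
        deltas = {}
        for group in ("ldlpfc", "sham"):
            rows = []
            for p in range(n_participants):
                prof = {}
                for time in ("pre", "post"):
                    rri, _ = simulate_rri(
                        cfg, CLIP_DURATION_S, cell={"group": group, "time": time},
                        rng=cfg.rng(f"rec_rri_{group}_{p}_{time}"),
                    )
                    prof[time] = hrv_profile(rri)
                rows.append(
                    {
                        "sdnn": prof["post"].sdnn - prof["pre"].sdnn,
                        "rmssd": prof["post"].rmssd - prof["pre"].rmssd,
                        "sd1": prof["post"].sd1 - prof["pre"].sd1,
                    }
                )
            deltas[group] = pd.DataFrame(rows).mean()
        d_sdnn.append(deltas["ldlpfc"]["sdnn"] - deltas["sham"]["sdnn"])
        d_rmssd.append(deltas["ldlpfc"]["rmssd"] - deltas["sham"]["rmssd"])
        d_sd1.append(deltas["ldlpfc"]["sd1"] - deltas["sham"]["sd1"])

        ratings = simulate_ratings_study2(cfg)
        cells = (
            ratings[ratings["scale"] == "content"]
            .groupby(["group", "time"])["value"]
            .mean()
        )
        d_rating.append(
            (cells["ldlpfc", "post"] - cells["ldlpfc", "pre"])
            - (cells["sham", "post"] - cells["sham", "pre"])
        )

    out = {}
    for name, vals in (
        ("d_sdnn", d_sdnn),
        ("d_rmssd", d_rmssd),
        ("d_sd1", d_sd1),
        ("d_content_rating", d_rating),
    ):
        mean, se = _mean_se(vals)
        out[name] = {"mean": mean, "se": se}
    out["n_seeds"] = n_seeds
    return out
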