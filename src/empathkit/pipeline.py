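"""End-to-end orchestration of the two synthetic study pipelines.

``run_study1``: ratings + ERP epochs → preprocessing → LPP/ΔLPP + SDT AUC →
binary painful/nonpainful decoding per stimulation cell.

``run_study2``: ratings + RR series (optionally rendered to continuous ECG
and re-detected) → HRV profiles → post-minus-pre change scores → three-class
valence decoding per group and time point.

Every run writes tidy CSV/JSON artifacts plus a manifest (config hash, seed,
versions, rejection/correction counts) and is bit-identical under a fixed
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GROUPS_STUDY2, TDCS_TARGETS, TDCS_TYPES, TIMES, VALENCES, SimConfig
from .decoding import (
    FAMILIES,
    STUDY2_FAMILIES,
    assemble_features_study1,
    assemble_features_study2,
    ensemble_summary,
    run_families,
)
from .erp import baseline_correct, delta_lpp_table, lpp_table, reject_artifacts, rereference_average
from .hrv import HRV_FIELDS, correct_rri, denoise_ecg, detect_r_peaks, hrv_profile
from .eemd import eemd
from .sdt import auc_by_cell
from .synth import (
    simulate_ecg_waveform,
    simulate_epochs_study1,
    simulate_ratings_study1,
    simulate_ratings_study2,
    simulate_rri,
)

log = logging.getLogger(__name__)

CLIP_DURATION_S = 120.0  # one autobiographical clip


def _manifest(cfg: SimConfig, counts: dict) -> dict:
    cfg_json = cfg.to_json()
    return {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "empathkit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "counts": counts,
    }


def _write(df: pd.DataFrame, out_dir: Path | None, name: str) -> None:
    if out_dir is not None:
        df.to_csv(out_dir / name, index=False)


# ------------------------------------------------------------------ study 1

def run_study1(
    cfg: SimConfig,
    out_dir: str | Path | None = None,
    families: tuple[str, ...] = FAMILIES,
    decode_seed: int = 0,
    reject_threshold_uv: float = 100.0,
    rf_trees: int = 300,
) -> dict:
    """Simulate → preprocess → SDT/LPP features → decode, returning the bundle."""
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    ratings = simulate_ratings_study1(cfg)
    epochs, _truth = simulate_epochs_study1(cfg)
    epochs = baseline_correct(epochs)
    epochs = reject_artifacts(epochs, threshold=reject_threshold_uv)
    epochs = rereference_average(epochs)
    n_rejected = int(epochs.reject_mask.sum())

    lpp = lpp_table(epochs)
    dlpp = delta_lpp_table(lpp)
    auc = pd.concat(
        [auc_by_cell(ratings, scale) for scale in ("self", "other")],
        ignore_index=True,
    )

    hyper = {"RF": {"n_estimators": rf_trees}}
    decode = {}
    feature_rows = []
    for target in TDCS_TARGETS:
        for tdcs_type in TDCS_TYPES:
            feats = assemble_features_study1(
                ratings, lpp, tdcs_target=target, tdcs_type=tdcs_type
            )
            reports = run_families(
                feats, families=families, seed=decode_seed, hyperparameters=hyper
            )
            decode[(target, tdcs_type)] = {
                "reports": reports,
                "summary": ensemble_summary(reports),
                "n_rows": feats.n_samples,
            }
            fdf = feats.features.copy()
            fdf["label"] = feats.labels
            fdf["participant"] = feats.group_ids
            fdf["tdcs_target"], fdf["tdcs_type"] = target, tdcs_type
            feature_rows.append(fdf)

    counts = {
        "epochs_total": epochs.n_epochs,
        "epochs_rejected": n_rejected,
        "rating_trials": int(len(ratings) / 2),
    }
    bundle = {
        "ratings": ratings,
        "lpp": lpp,
        "delta_lpp": dlpp,
        "auc": auc,
        "features": pd.concat(feature_rows, ignore_index=True),
        "decode": decode,
        "manifest": _manifest(cfg, counts),
    }
    if out_dir is not None:
        _write(ratings, out_dir, "ratings.csv")
        _write(lpp, out_dir, "lpp.csv")
        _write(dlpp, out_dir, "delta_lpp.csv")
        _write(auc, out_dir, "auc.csv")
        _write(bundle["features"], out_dir, "features.csv")
        decode_out = {
            f"{t}_{tt}": {
                "summary": d["summary"],
                "per_family": [r.summary_row() for r in d["reports"]],
                "n_rows": d["n_rows"],
            }
            for (t, tt), d in decode.items()
        }
        (out_dir / "decode.json").write_text(json.dumps(decode_out, indent=2))
        (out_dir / "manifest.json").write_text(
            json.dumps(bundle["manifest"], indent=2)
        )
    return bundle


# ------------------------------------------------------------------ study 2

def hrv_table_study2(
    cfg: SimConfig,
    ecg_chain: bool = False,
    eemd_denoise: bool = False,
    eemd_ensemble: int = 20,
) -> pd.DataFrame:
    """Per participant x valence x time HRV profile (trial-wise, cell-averaged).

    With ``ecg_chain`` the RR series is rendered to a continuous ECG and the
    R-peaks re-detected (optionally after EEMD denoising); otherwise the
    generator's RR series feeds the HRV stage directly.
    """
    rows = []
    n_corrected = 0
    for group in GROUPS_STUDY2:
        for p in range(cfg.n_participants_per_group):
            pid = f"{group}_{p:03d}"
            for valence in VALENCES:
                for time in TIMES:
                    cell = {"group": group, "time": time}
                    trial_profiles = []
                    for trial in range(cfg.n_trials_per_cell):
                        rng = cfg.rng(f"rri_{pid}_{valence}_{time}_{trial}")
                        rri, _ = simulate_rri(
                            cfg, CLIP_DURATION_S, cell=cell, rng=rng
                        )
                        if ecg_chain:
                            trace, _ = simulate_ecg_waveform(
                                rri, cfg,
                                rng=cfg.rng(f"ecg_{pid}_{valence}_{time}_{trial}"),
                            )
                            if eemd_denoise:
                                dec = eemd(
                                    trace.samples,
                                    ensemble_size=eemd_ensemble,
                                    rng=cfg.rng(f"eemd_{pid}_{valence}_{time}_{trial}"),
                                )
                                trace = denoise_ecg(trace, dec)
                            rri = detect_r_peaks(trace)
                        rri = correct_rri(rri)
                        n_corrected += int(rri.corrected_mask.sum())
                        trial_profiles.append(hrv_profile(rri).as_dict())
                    cell_mean = (
                        pd.DataFrame(trial_profiles)[list(HRV_FIELDS)]
                        .mean()
                        .to_dict()
                    )
                    cell_mean.update(
                        participant=pid, group=group, valence=valence, time=time
                    )
                    rows.append(cell_mean)
    df = pd.DataFrame(rows)
    df.attrs["n_corrected_intervals"] = n_corrected
    return df


def change_scores(pre: pd.DataFrame, post: pd.DataFrame,
                  keys: list[str] | None = None) -> pd.DataFrame:
    """Elementwise post − pre on the shared numeric columns.

    Cells present in only one time point are flagged missing (dropped from
    the Δ table, reported in the ``n_unmatched`` attribute).
    """
    if keys is None:
        keys = [
            c for c in pre.columns
            if c in post.columns and not pd.api.types.is_numeric_dtype(pre[c])
            and c != "time"
        ]
    numeric = [
        c for c in pre.columns
        if c in post.columns and pd.api.types.is_numeric_dtype(pre[c])
    ]
    p = pre.set_index(keys)[numeric]
    q = post.set_index(keys)[numeric]
    shared = p.index.intersection(q.index)
    n_unmatched = (len(p) - len(shared)) + (len(q) - len(shared))
    if n_unmatched:
        log.warning("change_scores: %d unmatched cells flagged missing", n_unmatched)
    delta = (q.loc[shared] - p.loc[shared]).reset_index()
    delta.attrs["n_unmatched"] = n_unmatched
    return delta


def run_study2(
    cfg: SimConfig,
    out_dir: str | Path | None = None,
    families: tuple[str, ...] = STUDY2_FAMILIES,
    decode_seed: int = 0,
    ecg_chain: bool = False,
    rf_trees: int = 300,
) -> dict:
    """Simulate → HRV → change scores → valence decoding, returning the bundle."""
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    ratings = simulate_ratings_study2(cfg)
    hrv = hrv_table_study2(cfg, ecg_chain=ecg_chain)

    rating_cells = (
        ratings.groupby(["participant", "group", "valence", "time", "scale"])["value"]
        .mean()
        .unstack("scale")
        .add_prefix("rating_")
        .reset_index()
    )
    keys = ["participant", "group", "valence"]
    delta_ratings = change_scores(
        rating_cells[rating_cells["time"] == "pre"],
        rating_cells[rating_cells["time"] == "post"],
        keys=keys,
    )
    delta_hrv = change_scores(
        hrv[hrv["time"] == "pre"], hrv[hrv["time"] == "post"], keys=keys
    )

    hyper = {"RF": {"n_estimators": rf_trees}}
    decode = {}
    for group in GROUPS_STUDY2:
        for time in TIMES:
            feats = assemble_features_study2(ratings, hrv, time=time, group=group)
            reports = run_families(
                feats, families=families, seed=decode_seed, hyperparameters=hyper
            )
            decode[(group, time)] = {
                "reports": reports,
                "summary": ensemble_summary(reports),
                "n_rows": feats.n_samples,
            }

    counts = {
        "rri_intervals_corrected": hrv.attrs.get("n_corrected_intervals", 0),
        "rating_trials": int(len(ratings) / 4),
    }
    bundle = {
        "ratings": ratings,
        "hrv": hrv,
        "delta_ratings": delta_ratings,
        "delta_hrv": delta_hrv,
        "decode": decode,
        "manifest": _manifest(cfg, counts),
    }
    if out_dir is not None:
        _write(ratings, out_dir, "ratings.csv")
        _write(hrv, out_dir, "hrv.csv")
        _write(delta_ratings, out_dir, "delta_ratings.csv")
        _write(delta_hrv, out_dir, "delta_hrv.csv")
        decode_out = {
            f"{g}_{t}": {
                "summary": d["summary"],
                "per_family": [r.summary_row() for r in d["reports"]],
                "n_rows": d["n_rows"],
            }
            for (g, t), d in decode.items()
        }
        (out_dir / "decode.json").write_text(json.dumps(decode_out, indent=2))
        (out_dir / "manifest.json").write_text(
            json.dumps(bundle["manifest"], indent=2)
        )
    return bundle


# ------------------------------------------------------------------ summary

def summarize(bundle: dict) -> str:
    """Human-readable cell-mean ± SEM report for a study bundle."""
    lines: list[str] = []

    def sem(x):
        x = np.asarray(x, dtype=float)
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    if "auc" in bundle:  # study 1
        lines.append("== Study 1 synthetic pipeline ==")
        auc = bundle["auc"]
        lines.append("-- SDT AUC by scale x target x type (mean ± SEM) --")
        g = auc[auc["flag"] == "ok"].groupby(["scale", "tdcs_target", "tdcs_type"])
        for key, cell in g:
            lines.append(
                f"  {key}: {cell['auc'].mean():.3f} ± {sem(cell['auc']):.3f}"
            )
        lines.append("-- ΔLPP (pain − nonpain, µV) --")
        for key, cell in bundle["delta_lpp"].groupby(["tdcs_target", "tdcs_type"]):
            lines.append(
                f"  {key}: early {cell['early_delta'].mean():.2f} ± "
                f"{sem(cell['early_delta']):.2f}, late {cell['late_delta'].mean():.2f}"
                f" ± {sem(cell['late_delta']):.2f}"
            )
        lines.append("-- decoding accuracy (%), chance = 50.0 --")
        for key, d in bundle["decode"].items():
            lines.append(
                f"  {key}: {d['summary']['mean_accuracy_pct']:.1f} "
                f"(kappa {d['summary']['mean_kappa']:.2f}, n={d['n_rows']})"
            )
    else:  # study 2
        lines.append("== Study 2 synthetic pipeline ==")
        lines.append("-- Δ ratings (post − pre) by group --")
        rating_cols = [c for c in bundle["delta_ratings"].columns
                       if c.startswith("rating_")]
        for key, cell in bundle["delta_ratings"].groupby("group"):
            parts = ", ".join(
                f"{c.removeprefix('rating_')} {cell[c].mean():+.2f}"
                for c in rating_cols
            )
            lines.append(f"  {key}: {parts}")
        lines.append("-- Δ HRV (post − pre) by group --")
        for key, cell in bundle["delta_hrv"].groupby("group"):
            lines.append(
                f"  {key}: Δsdnn {cell['sdnn'].mean():+.2f} ms, "
                f"Δrmssd {cell['rmssd'].mean():+.2f} ms, "
                f"Δsd1 {cell['sd1'].mean():+.2f} ms"
            )
        lines.append("-- decoding accuracy (%), chance = 33.3 --")
        for key, d in bundle["decode"].items():
            lines.append(
                f"  {key}: {d['summary']['mean_accuracy_pct']:.1f} "
                f"(kappa {d['summary']['mean_kappa']:.2f}, n={d['n_rows']})"
            )
    counts = bundle["manifest"]["counts"]
    lines.append(f"-- counts: {counts} --")
    return "\n".join(lines)
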